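# trajsig

Path-signature features of longitudinal brain-volume trajectories, with
L1-penalised logistic regression for converter-vs-stable classification.

A subject's visits (whole-brain, hippocampus and ventricle volumes at
irregular months) are interpolated piecewise-linearly, time-augmented, and
summarised by the degree-2 path signature or log signature — a fixed-length,
reparameterisation-invariant feature vector whatever the visit schedule.
Features are selected by Lasso logistic regression with 10-fold
cross-validated deviance and the one-standard-error rule, thresholded on the
training ROC (Youden's J), and evaluated as confusion matrices on a held-out
cohort. A synthetic cohort generator with planted group structure stands in
for clinical data, so the whole pipeline runs offline.

## Layout

| module | contents |
| --- | --- |
| `trajsig.sigcore` | signatures/log signatures of piecewise-linear paths (tensor exponential of segments + Chen concatenation) |
| `trajsig.features` | volume scaling, window extraction, time augmentation, named feature vectors |
| `trajsig.cohort` | longitudinal CSV parsing, trajectory labelling, inclusion filters, greedy 1:1:1 age matching |
| `trajsig.classify` | Lasso-logistic coordinate-descent path, cross-validated penalty selection, thresholding, confusion matrices |
| `trajsig.synthetic` | cohort generator (three diagnostic groups, planted acceleration and co-movement effects) |
| `trajsig.pipeline` / `trajsig.cli` | end-to-end orchestration and the `sig` command line |

## Command line

```bash
sig simulate --seed 1 --out visits.csv                    # synthetic cohort
sig simulate --seed 2 --style test --out test_visits.csv
sig cohort --input visits.csv --train-out train.csv       # filters + matching
sig featurize --input train.csv --window 0:24 --rep signature --out features.csv
sig train --features features.csv --folds 10 --seed 1 --out model.json
sig test --model model.json --features test_features.csv --out report.json
sig compute --csv path.csv --degree 2 [--log]             # named coefficients
sig run --config examples/run.yaml --out-dir run_output   # everything at once
```

`sig run` executes both classification tasks (converters vs stable-NL and vs
stable-MCI) for both representations and writes `report.json` plus a rendered
`report.txt` with the selected-feature lists and confusion matrices. Every
random draw derives from the config seed; identical configs give
byte-identical reports. Generator defaults are documented in
`examples/params.yaml`.

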