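"""End-to-end orchestration: simulate -> cohort -> featurize -> train -> test.

A :class:`RunConfig` fully determines a run; every random draw is traced to
``config.seed`` (simulation and cross-validation use separate spawned seeds),
so identical configs produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, cohort, features, synthetic
from .errors import TrajsigError

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_report"]

TASKS = {"AD_vs_NL": "stable_NL", "AD_vs_MCI": "stable_MCI"}
_SHORT = {"converter": "AD", "stable_NL": "NL", "stable_MCI": "MCI"}


class PipelineError(TrajsigError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Settings for one reproducible run; every field has a default."""

    seed: int = 0
    representation: str = "signature"
    n_train_per_group: int = 21
    n_test: dict = field(
        default_factory=lambda: {"stable_NL": 20, "converter": 10, "stable_MCI": 6}
    )
    folds: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    age_tolerance: float = 5.0
    train_window: tuple[float, float] = (0.0, 24.0)
    train_min_points: int = 4
    test_window: tuple[float, float] = (12.0, 36.0)
    test_min_points: int = 3
    train_conversion_month: float = 36.0
    train_stability_months: float = 72.0
    test_conversion_month: float = 48.0
    test_stability_months: float = 84.0
    #: optional pre-existing longitudinal tables; simulated when absent
    train_csv: str | None = None
    test_csv: str | None = None
    effect_factor: float = 1.0
    null_effects: bool = False
    #: which feature representations to run (both by default)
    representations: tuple[str, ...] = ("signature", "log_signature")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"stage config: unknown option(s) {sorted(unknown)}")
        for key in ("train_window", "test_window", "representations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["train_window"] = list(self.train_window)
        out["test_window"] = list(self.test_window)
        out["representations"] = list(self.representations)
        return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _load_or_simulate(config: RunConfig):
    if config.train_csv and config.test_csv:
        train_records = cohort.read_longitudinal_table(config.train_csv)
        test_records = cohort.read_longitudinal_table(config.test_csv)
        return train_records, test_records
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    train_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    test_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    tr = synthetic.default_params(
        seed=train_seed,
        n_per_group={g: config.n_train_per_group for g in synthetic.GROUPS},
        conversion_month=config.train_conversion_month,
        stability_months=config.train_stability_months,
    )
    te = synthetic.test_params(
        seed=test_seed,
        n_per_group=dict(config.n_test),
        conversion_month=config.test_conversion_month,
        stability_months=config.test_stability_months,
    )
    if config.effect_factor != 1.0:
        tr = synthetic.scale_effects(tr, config.effect_factor)
        te = synthetic.scale_effects(te, config.effect_factor)
    if config.null_effects:
        tr, te = synthetic.null_params(tr), synthetic.null_params(te)
    train_records, _ = synthetic.generate_cohort(tr)
    test_records, _ = synthetic.generate_cohort(te)
    return train_records, test_records


@_stage("cohort")
def _select_training(config: RunConfig, records):
    start, end = config.train_window
    groups = {g: [] for g in synthetic.GROUPS}
    for record in records:
        group = cohort.classify_trajectory(
            record, config.train_conversion_month, config.train_stability_months
        )
        if group == "other":
            continue
        window = features.extract_window(
            record, start, end, config.train_min_points, require_endpoint=True
        )
        if window.accepted:
            groups[group].append(record)
    triples = cohort.match_controls(
        groups["converter"],
        groups["stable_NL"],
        groups["stable_MCI"],
        config.age_tolerance,
    )
    return {
        "converter": [t.ad_subject for t in triples],
        "stable_NL": [t.nl_subject for t in triples],
        "stable_MCI": [t.mci_subject for t in triples],
    }


@_stage("cohort")
def _select_test(config: RunConfig, records, train_ids):
    groups = cohort.build_test_sets(
        records,
        train_ids,
        conversion_month=config.test_conversion_month,
        stability_months=config.test_stability_months,
    )
    start, end = config.test_window
    out = {}
    for group, members in groups.items():
        kept = []
        for record in members:
            window = features.extract_window(
                record, start, end, config.test_min_points, require_endpoint=True
            )
            if window.accepted:
                kept.append(record)
        out[group] = kept
    return out


@_stage("featurize")
def _feature_frames(config: RunConfig, selected, window, min_points):
    labels = {
        r.subject_id: _SHORT[g] for g, members in selected.items() for r in members
    }
    records = [r for members in selected.values() for r in members]
    frames = {}
    for rep in config.representations:
        frame, rejected = features.featurize_records(
            records, labels, rep, window[0], window[1], min_points
        )
        if rejected:
            raise PipelineError(
                f"stage featurize: {len(rejected)} selected subject(s) lost their window"
            )
        frames[rep] = frame
    return frames


def _task_matrix(frame, control_label):
    sub = frame[frame["label"].isin(["AD", control_label])]
    names = [c for c in frame.columns if c not in ("subject_id", "label")]
    X = sub[names].to_numpy(dtype=float)
    y = (sub["label"] == "AD").to_numpy(dtype=float)
    return X, y, names, sub["subject_id"].tolist()


@_stage("train")
def _train_task(config: RunConfig, frame, control_label, cv_seed):
    X, y, names, _ = _task_matrix(frame, control_label)
    lambdas = classify.lambda_grid(X, y, config.n_lambdas, config.lambda_min_ratio)
    result = classify.cross_validate(
        X, y, lambdas, folds=config.folds, seed=cv_seed, feature_names=names
    )
    model = classify.fit_final_model(X, y, result.lambda_1se, names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        threshold = classify.choose_threshold(model.predict_proba(X), y)
    return result, model, threshold


@_stage("test")
def _evaluate_task(model, threshold, test_frame, control_label):
    X, y, names, ids = _task_matrix(test_frame, control_label)
    matrix = classify.evaluate(
        model,
        threshold,
        X,
        y,
        feature_names=names,
        pos_label="AD",
        neg_label=_control_short(control_label),
    )
    probs = model.predict_proba(X)
    predictions = {
        sid: {"probability": float(p), "predicted": "AD" if p >= threshold else _control_short(control_label)}
        for sid, p in zip(ids, probs)
    }
    return matrix, predictions


def _control_short(control_label: str) -> str:
    return control_label if control_label in ("NL", "MCI") else _SHORT[control_label]


def _matrix_dict(matrix: classify.ConfusionMatrix) -> dict:
    acc = matrix.per_class_accuracy
    return {
        "labels": [matrix.pos_label, matrix.neg_label],
        "counts": matrix.counts.tolist(),
        "per_class_accuracy": [round(acc[0], 6), round(acc[1], 6)],
        "accuracy": round(matrix.accuracy, 6),
        "balanced_accuracy": round(matrix.balanced_accuracy, 6),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute both classification tasks for both representations.

    Returns the full run report: per task and representation the chosen
    penalties, the selected-feature lists (min and 1-SE), the test confusion
    matrix, per-subject predictions, and whether the two representations
    agree on every test prediction.
    """
    train_records, test_records = _load_or_simulate(config)
    train_selected = _select_training(config, train_records)
    train_ids = {r.subject_id for members in train_selected.values() for r in members}
    test_selected = _select_test(config, test_records, train_ids)

    train_frames = _feature_frames(
        config, train_selected, config.train_window, config.train_min_points
    )
    test_frames = _feature_frames(
        config, test_selected, config.test_window, config.test_min_points
    )

    cv_seeds = np.random.SeedSequence(config.seed).spawn(3)[2].generate_state(4)
    report: dict = {
        "config": config.to_dict(),
        "n_train": {_SHORT[g]: len(m) for g, m in train_selected.items()},
        "n_test": {_SHORT[g]: len(m) for g, m in test_selected.items()},
        "tasks": {},
    }
    for t, (task, control_group) in enumerate(TASKS.items()):
        control = _SHORT[control_group]
        task_report: dict = {}
        agree = None
        for rep in config.representations:
            # CV seed index is fixed per (task, representation) so a run
            # restricted to one representation reproduces the full run's fits
            r = features.REPRESENTATIONS.index(rep)
            cv_seed = int(cv_seeds[2 * t + r] % (2**31))
            result, model, threshold = _train_task(
                config, train_frames[rep], control, cv_seed
            )
            matrix, predictions = _evaluate_task(
                model, threshold, test_frames[rep], control
            )
            task_report[rep] = {
                "lambda_min": result.lambda_min,
                "lambda_1se": result.lambda_1se,
                "selected_min": [n for n, _ in classify.selected_features(result, "min")],
                "selected_1se": [n for n, _ in classify.selected_features(result, "1se")],
                "threshold": threshold,
                "confusion": _matrix_dict(matrix),
                "predictions": predictions,
            }
            preds = {s: p["predicted"] for s, p in predictions.items()}
            agree = preds if agree is None else (agree == preds)
        if len(config.representations) > 1:
            task_report["representations_agree"] = bool(agree)
        report["tasks"][task] = task_report
    return report


def render_report(report: dict) -> str:
    """Text rendering: selected-feature lists and confusion matrices."""
    reps = report["config"].get("representations", list(features.REPRESENTATIONS))
    rep = report["config"]["representation"]
    if rep not in reps:
        rep = reps[0]
    lines = ["Selected features (lambda min+1SE)", "=" * 40]
    for task, task_report in report["tasks"].items():
        for r in reps:
            lines.append(f"\n{task} [{r}]:")
            chosen = task_report[r]["selected_1se"]
            if chosen:
                lines.extend(f"  {name}" for name in chosen)
            else:
                lines.append("  (none)")
    lines += ["", "Test confusion matrices", "=" * 40]
    for task, task_report in report["tasks"].items():
        conf = task_report[rep]["confusion"]
        matrix = classify.ConfusionMatrix(
            pos_label=conf["labels"][0],
            neg_label=conf["labels"][1],
            counts=np.array(conf["counts"]),
        )
        lines += [f"\n{task} [{rep}]:", matrix.render()]
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    (out_dir / "report.txt").write_text(render_report(report))
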