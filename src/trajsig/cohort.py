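"""Longitudinal table I/O, diagnosis-trajectory labelling and age matching.

Subjects are grouped by the shape of their diagnosis series (converters with
a planted conversion month vs. diagnostically stable controls), filtered by
measurement availability inside an analysis window, and — for the training
design — matched 1:1:1 on baseline age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "DIAGNOSES",
    "SubjectRecord",
    "MatchedTriple",
    "read_longitudinal_table",
    "classify_trajectory",
    "match_controls",
    "build_test_sets",
]

DIAGNOSES = ("NL", "MCI", "AD")

#: default column layout of the flat longitudinal CSV
DEFAULT_COLUMNS = {
    "subject_id": "subject_id",
    "month": "month",
    "dx": "dx",
    "wholebrain": "wholebrain",
    "hippocampus": "hippocampus",
    "ventricles": "ventricles",
    "age": "age",
    "gender": "gender",
    "apoe4": "apoe4",
}


@dataclass
class SubjectRecord:
    """One subject's diagnosis trajectory, visit measurements and demographics.

    ``diagnoses`` is an ordered list of ``(month, label)`` pairs with labels in
    ``{"NL", "MCI", "AD"}``; ``measurements`` is an ordered list of
    ``(month, wholebrain, hippocampus, ventricles)`` tuples where any volume
    may be ``nan`` (missing).  Volumes are raw (mm^3-scale) values.
    """

    subject_id: str
    baseline_age: float
    gender: str
    apoe4: int
    diagnoses: list[tuple[float, str]] = field(default_factory=list)
    measurements: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for series_name in ("diagnoses", "measurements"):
            months = [entry[0] for entry in getattr(self, series_name)]
            if any(m < 0 for m in months):
                raise ContractError(f"{self.subject_id}: negative month in {series_name}")
            if any(b <= a for a, b in zip(months, months[1:])):
                raise ContractError(
                    f"{self.subject_id}: months in {series_name} must be strictly increasing"
                )
        for _, label in self.diagnoses:
            if label not in DIAGNOSES:
                raise ContractError(f"{self.subject_id}: unknown diagnosis {label!r}")

    def diagnosis_months(self) -> list[float]:
        return [m for m, _ in self.diagnoses]

    def first_month_with(self, label: str) -> float | None:
        for month, dx in self.diagnoses:
            if dx == label:
                return month
        return None


@dataclass(frozen=True)
class MatchedTriple:
    """A training case with its age-matched NL and MCI counterparts."""

    ad_subject: SubjectRecord
    nl_subject: SubjectRecord
    mci_subject: SubjectRecord


def read_longitudinal_table(
    csv_source, columns: dict[str, str] | None = None
) -> list[SubjectRecord]:
    """Read a flat subject-visit CSV into one :class:`SubjectRecord` per subject.

    Rows with unparseable months are dropped with a warning; duplicated
    ``(subject, month)`` rows keep the last occurrence.  Demographics are taken
    from the subject's first row.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    try:
        frame = pd.read_csv(csv_source)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("input table is empty") from exc
    missing = [c for c in cols.values() if c not in frame.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if frame.empty:
        raise FormatError("input table has no data rows")

    months = pd.to_numeric(frame[cols["month"]], errors="coerce")
    bad = months.isna()
    if bad.any():
        logger.warning("dropping %d row(s) with unparseable month", int(bad.sum()))
        frame = frame.loc[~bad].copy()
        months = months[~bad]
    frame["_month"] = months.astype(float)

    dupes = frame.duplicated(subset=[cols["subject_id"], "_month"], keep="last")
    if dupes.any():
        logger.warning(
            "dropping %d duplicated (subject, month) row(s), keeping last",
            int(dupes.sum()),
        )
        frame = frame.loc[~dupes]

    records: list[SubjectRecord] = []
    for subject_id, chunk in frame.groupby(cols["subject_id"], sort=True):
        chunk = chunk.sort_values("_month")
        first = chunk.iloc[0]
        diagnoses = [
            (float(m), str(dx))
            for m, dx in zip(chunk["_month"], chunk[cols["dx"]])
            if isinstance(dx, str) and dx in DIAGNOSES
        ]
        measurements = []
        for _, row in chunk.iterrows():
            volumes = [
                float(row[cols[v]]) if pd.notna(row[cols[v]]) else float("nan")
                for v in ("wholebrain", "hippocampus", "ventricles")
            ]
            if all(np.isnan(v) for v in volumes):
                continue
            measurements.append((float(row["_month"]), *volumes))
        records.append(
            SubjectRecord(
                subject_id=str(subject_id),
                baseline_age=float(first[cols["age"]]),
                gender=str(first[cols["gender"]]),
                apoe4=int(first[cols["apoe4"]]),
                diagnoses=diagnoses,
                measurements=measurements,
            )
        )
    return records


def classify_trajectory(
    record: SubjectRecord, conversion_month: float, stability_months: float
) -> str:
    """Label a diagnosis trajectory.

    Returns ``"converter"`` when the first AD diagnosis falls exactly at
    ``conversion_month`` (all earlier diagnoses non-AD), ``"stable_NL"`` /
    ``"stable_MCI"`` when every diagnosis in ``[0, stability_months]`` carries
    the same non-AD label and the series actually reaches
    ``stability_months``, and ``"other"`` otherwise.
    """
    if not record.diagnoses:
        raise ContractError(f"{record.subject_id}: record has no diagnoses")
    first_ad = record.first_month_with("AD")
    if first_ad is not None:
        return "converter" if first_ad == conversion_month else "other"
    in_window = [dx for m, dx in record.diagnoses if m <= stability_months]
    span = max(record.diagnosis_months())
    if span < stability_months or not in_window:
        return "other"
    labels = set(in_window)
    if labels == {"NL"}:
        return "stable_NL"
    if labels == {"MCI"}:
        return "stable_MCI"
    return "other"


def _take_nearest(
    case: SubjectRecord, pool: list[SubjectRecord], age_tolerance: float
) -> SubjectRecord | None:
    best = None
    for cand in pool:
        delta = abs(cand.baseline_age - case.baseline_age)
        if delta > age_tolerance:
            continue
        if best is None or (delta, cand.subject_id) < (
            abs(best.baseline_age - case.baseline_age),
            best.subject_id,
        ):
            best = cand
    return best


def match_controls(
    cases: Sequence[SubjectRecord],
    pool_nl: Iterable[SubjectRecord],
    pool_mci: Iterable[SubjectRecord],
    age_tolerance: float = 5.0,
) -> list[MatchedTriple]:
    """Greedy 1:1:1 age matching of cases to NL and MCI controls.

    Cases are processed in ascending subject-id order; for each, the
    nearest-age unused candidate within ``age_tolerance`` years is taken from
    each pool (ties broken by smaller subject id).  A case lacking an eligible
    candidate in either pool is dropped with a logged reason.  Deterministic
    and seed-free.
    """
    nl_left = sorted(pool_nl, key=lambda r: r.subject_id)
    mci_left = sorted(pool_mci, key=lambda r: r.subject_id)
    triples: list[MatchedTriple] = []
    for case in sorted(cases, key=lambda r: r.subject_id):
        nl = _take_nearest(case, nl_left, age_tolerance)
        mci = _take_nearest(case, mci_left, age_tolerance)
        if nl is None or mci is None:
            which = "NL" if nl is None else "MCI"
            logger.info(
                "case %s (age %.1f) dropped: no %s control within %.1f years",
                case.subject_id,
                case.baseline_age,
                which,
                age_tolerance,
            )
            continue
        nl_left.remove(nl)
        mci_left.remove(mci)
        triples.append(MatchedTriple(ad_subject=case, nl_subject=nl, mci_subject=mci))
    return triples


def build_test_sets(
    records: Iterable[SubjectRecord],
    train_ids: Iterable[str] = (),
    conversion_month: float = 48.0,
    stability_months: float = 84.0,
) -> dict[str, list[SubjectRecord]]:
    """Partition held-out subjects into test groups; no age matching applied.

    Test cases are converters at ``conversion_month``; controls must hold
    their NL/MCI diagnosis for at least ``stability_months``.  A subject that
    also appears in ``train_ids`` triggers a :class:`ContractError` — the two
    designs must not share participants.
    """
    train_ids = set(train_ids)
    groups: dict[str, list[SubjectRecord]] = {
        "converter": [],
        "stable_NL": [],
        "stable_MCI": [],
    }
    for record in sorted(records, key=lambda r: r.subject_id):
        group = classify_trajectory(record, conversion_month, stability_months)
        if group == "other":
            logger.info("test candidate %s excluded: trajectory 'other'", record.subject_id)
            continue
        if record.subject_id in train_ids:
            raise ContractError(
                f"subject {record.subject_id} appears in both training and test tables"
            )
        groups[group].append(record)
    return groups
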