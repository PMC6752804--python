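"""Synthetic longitudinal cohorts with group-structured volume trajectories.

Three diagnostic groups are generated: stable healthy (NL), stable MCI, and
converters whose diagnosis switches to AD at a planted visit month.  Baseline
volumes are drawn per group on the published scale; latent trajectories are
piecewise-linear in months.  Converters carry an *accelerated* decline of
hippocampus and whole-brain volume that switches on part-way through the
observation window — a deliberate modelling choice: a trajectory whose
channels all change at constant rates is a straight line and has zero signed
area, so curvature (staggered rate changes) is what plants a second-order
signature signal for the classifier to find.

All volume parameters are in scaled units (whole brain / 1e6 mm^3,
hippocampus and ventricles / 1e3 mm^3); generated tables carry raw volumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .errors import ContractError
from .features import SCALE_DIVISORS

__all__ = [
    "GROUPS",
    "CohortParams",
    "default_params",
    "test_params",
    "null_params",
    "scale_effects",
    "generate_subject",
    "generate_cohort",
    "cohort_to_frame",
    "write_cohort",
]

GROUPS = ("stable_NL", "converter", "stable_MCI")

_VOLUMES = ("wholebrain", "hippocampus", "ventricles")

# Baseline group medians / IQRs on the scaled analysis scale; locations follow
# the published training-cohort characteristics, spreads are IQR / 1.349.
_BASELINE_LOCATION = {
    "stable_NL": (1.02, 7.21, 28.53),
    "converter": (1.00, 6.14, 34.34),
    "stable_MCI": (1.00, 7.10, 33.88),
}
_BASELINE_SPREAD = {
    "stable_NL": (0.096, 0.91, 13.8),
    "converter": (0.089, 1.05, 15.7),
    "stable_MCI": (0.089, 0.66, 19.9),
}

# Base linear rates (scaled units / month).  Stable groups decline steadily;
# converters start flat on hippocampus and whole brain and pick up the planted
# staggered acceleration (hippocampus first, whole brain later), which curves
# their trajectory in the (Hippocampus, Wholebrain) and (Hippocampus, Time)
# planes while stable paths stay straight.
_ATROPHY_RATE = {
    "stable_NL": (-0.002, -0.0229, 0.125),
    "converter": (-0.002, 0.0, 0.125),
    "stable_MCI": (-0.002, -0.0229, 0.130),
}

_APOE4_PROBS = {
    "stable_NL": (0.81, 0.19, 0.0),
    "converter": (0.29, 0.52, 0.19),
    "stable_MCI": (0.71, 0.29, 0.0),
}


@dataclass(frozen=True)
class CohortParams:
    """Everything the generator needs; every field has a documented default."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {g: 21 for g in GROUPS}
    )
    baseline_location: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_BASELINE_LOCATION)
    )
    baseline_spread: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_BASELINE_SPREAD)
    )
    atrophy_rate: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_ATROPHY_RATE)
    )
    #: extra decline rate (scaled units / month) for converters, switched on
    #: at ``conversion_month - accel_onset_before_conversion[volume]``
    ad_acceleration: Mapping[str, float] = field(
        default_factory=lambda: {"hippocampus": 0.0375}
    )
    accel_onset_before_conversion: Mapping[str, float] = field(
        default_factory=lambda: {"hippocampus": 24.0}
    )
    #: amplitude of the converters' zero-mean whole-brain transient (scaled
    #: units): above trend early in the pre-conversion window, below trend
    #: late, returning to trend — net increment zero and zero (time, volume)
    #: area, but a systematic co-movement with the hippocampus decline
    wb_transient: float = 0.05
    visit_months: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0, 18.0, 24.0, 36.0, 48.0)
    visit_missing_prob: Mapping[float, float] = field(
        default_factory=lambda: {3.0: 0.6, 6.0: 0.05, 12.0: 0.05, 18.0: 0.1, 48.0: 0.1}
    )
    #: visits that are never dropped (analysis-window endpoints)
    never_missing_months: tuple[float, ...] = (0.0, 24.0, 36.0)
    measurement_noise_sd: tuple[float, float, float] = (0.006, 0.045, 1.2)
    #: per-subject relative spread of trajectory rates (random-slope noise)
    rate_jitter: float = 0.15
    age_range: tuple[float, float] = (60.0, 90.0)
    conversion_month: float = 36.0
    stability_months: float = 72.0
    dx_interval: float = 6.0
    converter_pre_mci_prob: float = 19.0 / 21.0
    male_prob: float = 0.5
    id_prefix: str = "TR"
    seed: int = 0

    def __post_init__(self) -> None:
        for group in GROUPS:
            if any(s < 0 for s in self.baseline_spread[group]):
                raise ContractError("baseline spreads must be non-negative")
        if any(s < 0 for s in self.measurement_noise_sd):
            raise ContractError("noise SDs must be non-negative")
        if any(not 0 <= p <= 1 for p in self.visit_missing_prob.values()):
            raise ContractError("missing probabilities must be in [0, 1]")
        if any(
            b <= a for a, b in zip(self.visit_months, self.visit_months[1:])
        ):
            raise ContractError("visit months must be strictly increasing")


def default_params(seed: int = 0, **overrides) -> CohortParams:
    """Training-style defaults: conversion at 36 months, 72-month stability."""
    return CohortParams(seed=seed, **overrides)


def test_params(seed: int = 0, **overrides) -> CohortParams:
    """Held-out-style defaults: conversion at 48 months, 84-month stability."""
    overrides.setdefault("conversion_month", 48.0)
    overrides.setdefault("stability_months", 84.0)
    overrides.setdefault("id_prefix", "TE")
    overrides.setdefault(
        "n_per_group", {"stable_NL": 20, "converter": 10, "stable_MCI": 6}
    )
    return CohortParams(seed=seed, **overrides)


def null_params(base: CohortParams) -> CohortParams:
    """Remove every group difference: shared baselines and rates, no
    acceleration.  Diagnosis labels keep their planted structure, so any
    classification signal left is pure chance (null-calibration setting)."""
    shared_loc = {g: base.baseline_location["stable_NL"] for g in GROUPS}
    shared_spread = {g: base.baseline_spread["stable_NL"] for g in GROUPS}
    shared_rate = {g: base.atrophy_rate["stable_NL"] for g in GROUPS}
    return dataclasses.replace(
        base,
        baseline_location=shared_loc,
        baseline_spread=shared_spread,
        atrophy_rate=shared_rate,
        ad_acceleration={"hippocampus": 0.0},
        wb_transient=0.0,
    )


def scale_effects(base: CohortParams, factor: float) -> CohortParams:
    """Interpolate every planted converter *trajectory* effect by ``factor``.

    At 0 converters follow the stable-NL trajectory model exactly (baseline
    distributions are untouched); at 1 the defaults are recovered; the
    acceleration, the whole-brain transient and the converter-vs-stable base
    rate differences all scale together so the planted signal grows
    monotonically with ``factor``.
    """
    ref = base.atrophy_rate["stable_NL"]
    conv = base.atrophy_rate["converter"]
    blended = tuple(r + factor * (c - r) for r, c in zip(ref, conv))
    rates = dict(base.atrophy_rate)
    rates["converter"] = blended
    return dataclasses.replace(
        base,
        atrophy_rate=rates,
        ad_acceleration={k: v * factor for k, v in base.ad_acceleration.items()},
        wb_transient=base.wb_transient * factor,
    )


def _latent_value(
    params: CohortParams,
    group: str,
    volume_idx: int,
    baseline: float,
    month: float,
    rate_mult: float,
) -> float:
    volume = _VOLUMES[volume_idx]
    value = baseline + rate_mult * params.atrophy_rate[group][volume_idx] * month
    if group == "converter" and volume in params.ad_acceleration:
        onset = params.conversion_month - params.accel_onset_before_conversion[volume]
        value -= rate_mult * params.ad_acceleration[volume] * max(0.0, month - onset)
    if group == "converter" and volume == "wholebrain" and params.wb_transient:
        # antisymmetric S-shape over the 24 months before conversion at 36:
        # nodes (0, +1, 0, -1, 0) at 6-month steps, zero outside
        t_rel = month - (params.conversion_month - 36.0)
        shape = np.interp(t_rel, [0.0, 6.0, 12.0, 18.0, 24.0], [0, 1, 0, -1, 0])
        if not 0.0 <= t_rel <= 24.0:
            shape = 0.0
        value += rate_mult * params.wb_transient * shape
    return value


def generate_subject(
    group: str,
    params: CohortParams,
    rng: np.random.Generator,
    subject_id: str = "S000",
    age_range: tuple[float, float] | None = None,
) -> SubjectRecord:
    """Draw one subject: demographics, diagnosis series and noisy visits."""
    if group not in GROUPS:
        raise ContractError(f"unknown group {group!r}")
    lo, hi = age_range if age_range is not None else params.age_range
    age = float(rng.uniform(lo, hi))
    gender = "M" if rng.random() < params.male_prob else "F"
    apoe4 = int(rng.choice(3, p=_APOE4_PROBS[group]))

    baselines = [
        max(loc + spread * rng.standard_normal(), 0.01)
        for loc, spread in zip(
            params.baseline_location[group], params.baseline_spread[group]
        )
    ]

    if group == "converter":
        pre = "MCI" if rng.random() < params.converter_pre_mci_prob else "NL"
    else:
        pre = "NL" if group == "stable_NL" else "MCI"
    dx_horizon = max(params.stability_months, params.conversion_month)
    dx_months = np.arange(0.0, dx_horizon + params.dx_interval / 2, params.dx_interval)
    diagnoses = []
    for month in dx_months:
        if group == "converter" and month >= params.conversion_month:
            diagnoses.append((float(month), "AD"))
        else:
            diagnoses.append((float(month), pre))

    rate_mults = 1.0 + rng.uniform(-params.rate_jitter, params.rate_jitter, 3)
    measurements = []
    for month in params.visit_months:
        missing_prob = params.visit_missing_prob.get(float(month), 0.0)
        if float(month) in params.never_missing_months:
            missing_prob = 0.0
        dropped = rng.random() < missing_prob
        noise = rng.standard_normal(3) * np.asarray(params.measurement_noise_sd)
        if dropped:
            continue
        scaled = [
            max(
                _latent_value(params, group, i, baselines[i], month, rate_mults[i])
                + noise[i],
                0.01,
            )
            for i in range(3)
        ]
        raw = tuple(v * s for v, s in zip(scaled, SCALE_DIVISORS))
        measurements.append((float(month), *raw))

    return SubjectRecord(
        subject_id=subject_id,
        baseline_age=age,
        gender=gender,
        apoe4=apoe4,
        diagnoses=diagnoses,
        measurements=measurements,
    )


def generate_cohort(
    params: CohortParams,
) -> tuple[list[SubjectRecord], dict[str, str]]:
    """Deterministically generate a full cohort and its ground-truth labels.

    Subjects with the same within-group index share an age "anchor" drawn once
    per index (each age lands within +-2.5 years of its anchor), so that
    equal-sized groups always admit a complete 1:1:1 age matching within the
    5-year tolerance.
    """
    rng = np.random.default_rng(params.seed)
    n_max = max(params.n_per_group[g] for g in GROUPS)
    lo, hi = params.age_range
    anchors = rng.uniform(lo + 2.5, hi - 2.5, size=n_max)
    group_code = {"stable_NL": "NL", "converter": "AD", "stable_MCI": "MCI"}
    records: list[SubjectRecord] = []
    truth: dict[str, str] = {}
    for group in GROUPS:
        for i in range(params.n_per_group[group]):
            subject_id = f"{params.id_prefix}-{group_code[group]}-{i + 1:03d}"
            record = generate_subject(
                group,
                params,
                rng,
                subject_id=subject_id,
                age_range=(anchors[i] - 2.5, anchors[i] + 2.5),
            )
            records.append(record)
            truth[subject_id] = group
    return records, truth


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten records to the standard longitudinal table (one row per month)."""
    rows = []
    for record in records:
        dx_by_month = {m: dx for m, dx in record.diagnoses}
        meas_by_month = {m: vols for m, *vols in record.measurements}
        for month in sorted(set(dx_by_month) | set(meas_by_month)):
            vols = meas_by_month.get(month, (np.nan, np.nan, np.nan))
            rows.append(
                {
                    "subject_id": record.subject_id,
                    "month": month,
                    "dx": dx_by_month.get(month, ""),
                    "wholebrain": vols[0],
                    "hippocampus": vols[1],
                    "ventricles": vols[2],
                    "age": record.baseline_age,
                    "gender": record.gender,
                    "apoe4": record.apoe4,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(records: list[SubjectRecord], path) -> None:
    """Write the flat longitudinal CSV (byte-stable for a fixed cohort)."""
    cohort_to_frame(records).to_csv(path, index=False)
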