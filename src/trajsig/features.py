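"""Feature vectors: baseline volumes plus (log-)signature terms.

A subject's measurement window is turned into a time-augmented 4-channel path
(Wholebrain, Hippocampus, Ventricles, Time) and summarised by its degree-2
signature or log signature.  The exported vector has a fixed length and fixed
names irrespective of how many visits fall in the window or when they occur:

* entries 1-3: scaled baseline volumes (suffix ``_BL``);
* entry 4: the time increment (months spanned by the window);
* entries 5-7: the volume increments;
* remaining entries: the second-level signature terms (16 area/product terms
  for the signature, 6 signed areas for the log signature) in lexicographic
  channel order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .errors import ContractError, InvalidInputError
from .sigcore import (
    LabeledPath,
    compute_log_signature,
    compute_signature,
    log_signature_to_named_features,
    signature_to_named_features,
)

__all__ = [
    "VOLUME_CHANNELS",
    "TIME_CHANNEL",
    "SCALE_DIVISORS",
    "REPRESENTATIONS",
    "FeatureVector",
    "WindowResult",
    "scale_volumes",
    "extract_window",
    "time_augment",
    "build_feature_vector",
    "feature_names",
    "featurize_records",
]

VOLUME_CHANNELS = ("Wholebrain", "Hippocampus", "Ventricles")
TIME_CHANNEL = "Time"
#: raw mm^3 volumes are divided by these to land on the reported scale
SCALE_DIVISORS = (1e6, 1e3, 1e3)
REPRESENTATIONS = ("signature", "log_signature")


def scale_volumes(
    raw_wholebrain: float, raw_hippocampus: float, raw_ventricles: float
) -> tuple[float, float, float]:
    """Scale raw mm^3 volumes to the analysis scale (1e6, 1e3, 1e3 divisors)."""
    raw = (raw_wholebrain, raw_hippocampus, raw_ventricles)
    if any(not np.isfinite(v) or v <= 0 for v in raw):
        raise InvalidInputError(f"volumes must be positive and finite, got {raw}")
    return tuple(v / s for v, s in zip(raw, SCALE_DIVISORS))


@dataclass(frozen=True)
class WindowResult:
    """Outcome of window extraction: a path, or a rejection with its reason."""

    subject_id: str
    path: LabeledPath | None
    reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.path is not None


def extract_window(
    record: SubjectRecord,
    start_month: float,
    end_month: float,
    min_points: int = 4,
    require_endpoint: bool = True,
    exclude_months: Sequence[float] = (3.0,),
) -> WindowResult:
    """Select complete visits inside ``[start_month, end_month]`` as a path.

    Only visits with all three volumes present survive; months listed in
    ``exclude_months`` are dropped up front (the sparsely sampled month-3
    visit by default).  The window is rejected — a typed outcome, not an
    exception — when fewer than ``min_points`` visits remain or, if
    ``require_endpoint``, when there is no visit exactly at ``end_month``.
    Volumes are returned on the scaled analysis scale.
    """
    if not record.measurements:
        raise ContractError(f"{record.subject_id}: record has no measurements")
    excluded = {float(m) for m in exclude_months}
    months: list[float] = []
    rows: list[tuple[float, float, float]] = []
    for month, wb, hipp, vent in record.measurements:
        if month in excluded or not (start_month <= month <= end_month):
            continue
        if any(np.isnan(v) for v in (wb, hipp, vent)):
            continue
        months.append(month)
        rows.append(scale_volumes(wb, hipp, vent))
    if len(months) < min_points:
        return WindowResult(
            record.subject_id,
            None,
            f"only {len(months)} complete visit(s) in [{start_month}, {end_month}], "
            f"need {min_points}",
        )
    if require_endpoint and end_month not in months:
        return WindowResult(
            record.subject_id, None, f"no complete visit at month {end_month}"
        )
    path = LabeledPath(
        times=np.array(months), values=np.array(rows), channel_names=VOLUME_CHANNELS
    )
    return WindowResult(record.subject_id, path)


def time_augment(path: LabeledPath) -> LabeledPath:
    """Append the visit month (raw months) as an extra ``Time`` channel."""
    values = np.column_stack([path.values, path.times])
    return LabeledPath(
        times=path.times,
        values=values,
        channel_names=path.channel_names + (TIME_CHANNEL,),
    )


@dataclass(frozen=True)
class FeatureVector:
    subject_id: str
    names: tuple[str, ...]
    values: np.ndarray
    representation: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) != values.size:
            raise ContractError("feature names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ContractError("feature names must be unique")


_AUGMENTED = VOLUME_CHANNELS + (TIME_CHANNEL,)


def feature_names(representation: str) -> tuple[str, ...]:
    """The fixed, window-independent name sequence for a representation."""
    if representation not in REPRESENTATIONS:
        raise ContractError(f"unknown representation {representation!r}")
    names = [f"{c}_BL" for c in VOLUME_CHANNELS]
    open_, close = ("(", ")") if representation == "signature" else ("[", "]")
    names.append(f"{open_}Incr. {TIME_CHANNEL}{close}")
    names.extend(f"{open_}Incr. {c}{close}" for c in VOLUME_CHANNELS)
    if representation == "signature":
        names.extend(f"({a}, {b})" for a in _AUGMENTED for b in _AUGMENTED)
    else:
        names.extend(
            f"[{_AUGMENTED[i]}, {_AUGMENTED[j]}]"
            for i in range(4)
            for j in range(i + 1, 4)
        )
    return tuple(names)


def build_feature_vector(
    path: LabeledPath, representation: str, subject_id: str = ""
) -> FeatureVector:
    """Assemble the classifier input for one time-augmented path.

    The constant signature term is dropped and the first-level terms are
    reordered so the time increment is entry 4 and the three volume
    increments are entries 5-7; second-level terms keep their lexicographic
    enumeration order.
    """
    if path.channel_names != _AUGMENTED:
        raise ContractError(
            f"path channels must be {_AUGMENTED}, got {path.channel_names}"
        )
    if representation not in REPRESENTATIONS:
        raise ContractError(f"unknown representation {representation!r}")
    baselines = path.values[0, :3]
    if representation == "signature":
        terms = signature_to_named_features(
            compute_signature(path, degree=2), path.channel_names
        )
    else:
        terms = log_signature_to_named_features(
            compute_log_signature(path), path.channel_names
        )
    # level-1 terms come first in either listing: Time increment then volumes
    level1 = dict(terms[:4])
    increments = [level1[f"({TIME_CHANNEL})"]] + [level1[f"({c})"] for c in VOLUME_CHANNELS]
    higher = [value for _, value in terms[4:]]
    values = np.concatenate([baselines, increments, higher])
    return FeatureVector(
        subject_id=subject_id,
        names=feature_names(representation),
        values=values,
        representation=representation,
    )


def featurize_records(
    records: Sequence[SubjectRecord],
    labels: dict[str, str],
    representation: str,
    start_month: float = 0.0,
    end_month: float = 24.0,
    min_points: int = 4,
    require_endpoint: bool = True,
) -> tuple[pd.DataFrame, list[WindowResult]]:
    """Feature table for a set of subjects; rejected windows are reported.

    Returns a frame with ``subject_id`` and ``label`` columns followed by one
    column per feature, plus the list of rejections.
    """
    rows, rejected = [], []
    for record in records:
        result = extract_window(
            record, start_month, end_month, min_points, require_endpoint
        )
        if not result.accepted:
            rejected.append(result)
            continue
        fv = build_feature_vector(
            time_augment(result.path), representation, subject_id=record.subject_id
        )
        rows.append(
            {
                "subject_id": record.subject_id,
                "label": labels.get(record.subject_id, ""),
                **dict(zip(fv.names, fv.values)),
            }
        )
    columns = ["subject_id", "label", *feature_names(representation)]
    frame = pd.DataFrame(rows, columns=columns)
    return frame, rejected
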