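"""Truncated path signatures and log signatures of piecewise-linear paths.

A multivariate trajectory sampled at a finite set of parameter values is
interpolated piecewise-linearly and summarised by its signature: the graded
sequence of iterated integrals up to a chosen degree.  The degree-2 log
signature reduces to the channel increments plus one signed (Levy) area per
unordered channel pair.

Coefficients are stored densely: level ``k`` is a flat array of ``d**k``
values ordered lexicographically by multi-index, so the coefficient for
multi-index ``(i1, ..., ik)`` (1-based channels) sits at flat position
``sum((i-1) * d**(k-pos))``.  The dimensions used here are tiny (d <= 4,
degree 2 in the analysis), so no sparse or Lyndon-basis machinery is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError, InvalidInputError

__all__ = [
    "LabeledPath",
    "SignatureTensor",
    "LogSignature",
    "identity_signature",
    "segment_signature",
    "chen_concat",
    "compute_signature",
    "compute_log_signature",
    "signature_to_named_features",
    "log_signature_to_named_features",
]


@dataclass(frozen=True)
class LabeledPath:
    """An ordered, time-stamped multivariate trajectory.

    Parameters
    ----------
    times
        Strictly increasing sample parameters (months in the application).
    values
        Array of shape ``(n_samples, dim)`` with one row per sample.
    channel_names
        One label per channel.
    """

    times: np.ndarray
    values: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if times.ndim != 1 or times.size < 1:
            raise InvalidInputError("path needs at least one sample time")
        if values.shape != (times.size, len(self.channel_names)):
            raise InvalidInputError(
                f"values shape {values.shape} does not match "
                f"{times.size} samples x {len(self.channel_names)} channels"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise InvalidInputError("path samples must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("sample times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def dim(self) -> int:
        return len(self.channel_names)

    def increments(self) -> np.ndarray:
        """Per-segment channel deltas, shape ``(n_samples - 1, dim)``."""
        return np.diff(self.values, axis=0)


@dataclass(frozen=True)
class SignatureTensor:
    """Graded iterated-integral coefficients of a path, levels 0..degree."""

    dim: int
    degree: int
    levels: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if self.degree < 0 or self.dim < 1:
            raise ContractError("degree must be >= 0 and dim >= 1")
        if len(self.levels) != self.degree + 1:
            raise ContractError("need one coefficient table per level 0..degree")
        levels = tuple(np.asarray(lev, dtype=float).ravel() for lev in self.levels)
        for k, lev in enumerate(levels):
            if lev.size != self.dim**k:
                raise ContractError(f"level {k} must hold {self.dim ** k} coefficients")
        object.__setattr__(self, "levels", levels)

    def level(self, k: int) -> np.ndarray:
        return self.levels[k]

    def coeff(self, index: Sequence[int]) -> float:
        """Coefficient for a 1-based multi-index, e.g. ``(1, 2)`` for S^(1,2)."""
        index = tuple(index)
        if any(i < 1 or i > self.dim for i in index):
            raise ContractError(f"multi-index {index} out of range for dim {self.dim}")
        flat = 0
        for i in index:
            flat = flat * self.dim + (i - 1)
        return float(self.levels[len(index)][flat])

    def flatten(self) -> np.ndarray:
        """All coefficients, levels concatenated in order 0..degree."""
        return np.concatenate(self.levels)

    def allclose(self, other: "SignatureTensor", atol: float = 1e-10) -> bool:
        return (
            self.dim == other.dim
            and self.degree == other.degree
            and all(
                np.allclose(a, b, atol=atol, rtol=0.0)
                for a, b in zip(self.levels, other.levels)
            )
        )


@dataclass(frozen=True)
class LogSignature:
    """Degree-2 log signature: channel increments plus pairwise signed areas.

    ``areas[m]`` is the Levy area for the channel pair ``area_pairs[m]``
    (1-based, i < j), equal to ``(S^(i,j) - S^(j,i)) / 2``.
    """

    dim: int
    increments: np.ndarray
    areas: np.ndarray
    degree: int = 2

    def __post_init__(self) -> None:
        increments = np.asarray(self.increments, dtype=float)
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "increments", increments)
        object.__setattr__(self, "areas", areas)
        if increments.size != self.dim:
            raise ContractError("need one increment per channel")
        if areas.size != self.dim * (self.dim - 1) // 2:
            raise ContractError("need one area per unordered channel pair")

    @property
    def area_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (i, j) for i in range(1, self.dim + 1) for j in range(i + 1, self.dim + 1)
        )

    def area(self, i: int, j: int) -> float:
        """Signed area for the (1-based) channel pair ``i < j``."""
        try:
            pos = self.area_pairs.index((i, j))
        except ValueError as exc:
            raise ContractError(f"no area term for pair ({i}, {j})") from exc
        return float(self.areas[pos])


def identity_signature(dim: int, degree: int) -> SignatureTensor:
    """Signature of a constant path: level 0 equals 1, everything else 0."""
    levels = [np.zeros(dim**k) for k in range(degree + 1)]
    levels[0][0] = 1.0
    return SignatureTensor(dim=dim, degree=degree, levels=tuple(levels))


def segment_signature(increment: Sequence[float], degree: int) -> SignatureTensor:
    """Signature of a single straight segment with the given channel deltas.

    The level-k table is the k-fold tensor power of the increment divided by
    ``k!`` (truncated tensor exponential), so e.g. ``S^(i,j) = di * dj / 2``.
    """
    if degree < 1:
        raise InvalidInputError("degree must be a positive integer")
    increment = np.asarray(increment, dtype=float).ravel()
    if increment.size < 1 or not np.all(np.isfinite(increment)):
        raise InvalidInputError("increment must be a non-empty finite vector")
    levels: list[np.ndarray] = [np.ones(1)]
    for k in range(1, degree + 1):
        levels.append(np.kron(levels[-1], increment) / k)
    return SignatureTensor(dim=increment.size, degree=degree, levels=tuple(levels))


def chen_concat(a: SignatureTensor, b: SignatureTensor) -> SignatureTensor:
    """Signature of the concatenated path via Chen's identity.

    The result's level-k table is the truncated tensor-product convolution
    ``sum_p a_p (x) b_(k-p)``; the operation is associative with
    :func:`identity_signature` as the neutral element.
    """
    if a.dim != b.dim or a.degree != b.degree:
        raise ContractError(
            f"cannot concatenate signatures with dim/degree "
            f"({a.dim},{a.degree}) vs ({b.dim},{b.degree})"
        )
    levels = []
    for k in range(a.degree + 1):
        out = np.zeros(a.dim**k)
        for p in range(k + 1):
            out += np.kron(a.level(p), b.level(k - p))
        levels.append(out)
    return SignatureTensor(dim=a.dim, degree=a.degree, levels=tuple(levels))


def compute_signature(path: LabeledPath, degree: int) -> SignatureTensor:
    """Truncated signature of the piecewise-linear interpolant of ``path``."""
    if degree < 1:
        raise InvalidInputError("degree must be a positive integer")
    sig = identity_signature(path.dim, degree)
    for delta in path.increments():
        sig = chen_concat(sig, segment_signature(delta, degree))
    return sig


def compute_log_signature(path: LabeledPath, degree: int = 2) -> LogSignature:
    """Degree-2 log signature: increments and pairwise Levy areas.

    Only degree 2 is supported; at this truncation the log signature has the
    closed form ``increments[i] = S^(i)`` and
    ``areas[i, j] = (S^(i,j) - S^(j,i)) / 2``.
    """
    if degree != 2:
        raise InvalidInputError("log signature is only supported at degree 2")
    sig = compute_signature(path, degree=2)
    d = sig.dim
    level2 = sig.level(2).reshape(d, d)
    areas = [
        0.5 * (level2[i, j] - level2[j, i]) for i in range(d) for j in range(i + 1, d)
    ]
    return LogSignature(dim=d, increments=sig.level(1).copy(), areas=np.array(areas))


def _render_name(channels: Iterable[str], open_: str, close: str) -> str:
    return open_ + ", ".join(channels) + close


def signature_to_named_features(
    sig: SignatureTensor, channel_names: Sequence[str]
) -> list[tuple[str, float]]:
    """Signature coefficients as ``(name, value)`` pairs, constant term dropped.

    Terms appear level by level, multi-indexes in lexicographic order, named
    like ``"(Hippocampus, Time)"``.  The leading constant 1 is excluded: it
    carries no information beyond a model intercept.
    """
    if len(channel_names) != sig.dim:
        raise ContractError(
            f"{len(channel_names)} channel names for a dim-{sig.dim} signature"
        )
    out: list[tuple[str, float]] = []
    for k in range(1, sig.degree + 1):
        level = sig.level(k)
        for flat, index in enumerate(product(range(sig.dim), repeat=k)):
            name = _render_name((channel_names[i] for i in index), "(", ")")
            out.append((name, float(level[flat])))
    return out


def log_signature_to_named_features(
    logsig: LogSignature, channel_names: Sequence[str]
) -> list[tuple[str, float]]:
    """Log-signature terms as ``(name, value)`` pairs.

    Increments are named ``"(Hippocampus)"``; areas use square brackets,
    ``"[Hippocampus, Time]"``, one per pair i < j.
    """
    if len(channel_names) != logsig.dim:
        raise ContractError(
            f"{len(channel_names)} channel names for a dim-{logsig.dim} log signature"
        )
    out = [
        (f"({name})", float(v)) for name, v in zip(channel_names, logsig.increments)
    ]
    for (i, j), area in zip(logsig.area_pairs, logsig.areas):
        name = _render_name((channel_names[i - 1], channel_names[j - 1]), "[", "]")
        out.append((name, float(area)))
    return out
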