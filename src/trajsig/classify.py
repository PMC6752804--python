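"""L1-penalised logistic regression with cross-validated penalty selection.

The path solver minimises, for each penalty ``lam`` on a descending grid,

    (1/n) * sum_i log(1 + exp(-eta_i * y_i^{+-}))  +  lam * sum_j |beta_j|

with an unpenalised intercept, via iteratively reweighted least squares with
cyclic coordinate descent and soft thresholding (the standard penalised-GLM
strategy), warm-starting each penalty from the previous solution.  Features
are standardised to zero mean / unit variance internally and coefficients are
reported on both scales.

Penalty selection uses K-fold cross-validated binomial deviance: ``lambda_min``
minimises the mean held-out deviance and ``lambda_1se`` is the largest penalty
whose deviance stays within one standard error of that minimum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numba
import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import ContractError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "PathFit",
    "LassoCvResult",
    "ConfusionMatrix",
    "LogisticModel",
    "lambda_max",
    "lambda_grid",
    "fit_l1_logistic_path",
    "cross_validate",
    "selected_features",
    "fit_final_model",
    "choose_threshold",
    "evaluate",
]

_P_CLIP = 1e-12
_W_FLOOR = 1e-6


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns stay centred zeros
    return (X - mean) / scale, mean, scale


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ContractError(f"X shape {X.shape} incompatible with {y.size} labels")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("feature matrix contains non-finite entries")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ContractError("y must contain both classes coded 0/1")
    return X, y


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every slope is exactly zero.

    Equals the largest absolute gradient of the mean log-likelihood at the
    intercept-only solution, computed on standardised columns.
    """
    X, y = _validate_xy(X, y)
    Xs, _, _ = _standardize(X)
    return float(np.abs(Xs.T @ (y - y.mean())).max() / y.size)


def lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 100, min_ratio: float = 1e-3
) -> np.ndarray:
    """Descending log-spaced penalty grid from ``lambda_max`` down."""
    lmax = lambda_max(X, y)
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


@dataclass(frozen=True)
class PathFit:
    """Solutions along a descending penalty grid."""

    lambdas: np.ndarray
    intercepts: np.ndarray  # original scale, (n_lambdas,)
    coefs: np.ndarray  # original scale, (n_lambdas, p)
    std_coefs: np.ndarray  # standardised scale, (n_lambdas, p)

    def predict_proba(self, X: np.ndarray, idx: int) -> np.ndarray:
        eta = self.intercepts[idx] + np.asarray(X, dtype=float) @ self.coefs[idx]
        return 1.0 / (1.0 + np.exp(-eta))


@numba.njit(cache=True)
def _cd_path_kernel(Xs, y, lambdas, max_outer, max_inner, tol):  # pragma: no cover
    """Warm-started IRLS/coordinate-descent sweep along a descending grid.

    Returns intercepts and coefficients on the standardised scale plus a
    per-penalty convergence flag; a fit is flagged unconverged when the
    iteration budget runs out or the coefficients blow up (separable data at
    a vanishing penalty).
    """
    n, p = Xs.shape
    nlam = lambdas.shape[0]
    intercepts = np.zeros(nlam)
    betas = np.zeros((nlam, p))
    ok = np.ones(nlam, numba.boolean)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    eta = np.full(n, b0)
    w = np.empty(n)
    r = np.empty(n)
    denom = np.empty(p)
    for li in range(nlam):
        lam = lambdas[li]
        good = False
        for _outer in range(max_outer):
            wsum = 0.0
            for i in range(n):
                e = b0
                for j in range(p):
                    e += Xs[i, j] * beta[j]
                eta[i] = e
                prob = 1.0 / (1.0 + np.exp(-e))
                wi = prob * (1.0 - prob)
                if wi < 1e-6:
                    wi = 1e-6
                w[i] = wi
                wsum += wi
                r[i] = (y[i] - prob) / wi  # working residual z - eta
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * Xs[i, j] * Xs[i, j]
                denom[j] = s / n
            for _inner in range(max_inner):
                delta = 0.0
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                d0 = num / wsum
                b0 += d0
                for i in range(n):
                    r[i] -= d0
                if abs(d0) > delta:
                    delta = abs(d0)
                for j in range(p):
                    if denom[j] <= 0.0:  # constant column: stays at zero
                        continue
                    rho = 0.0
                    for i in range(n):
                        rho += w[i] * Xs[i, j] * r[i]
                    rho = rho / n + denom[j] * beta[j]
                    if rho > lam:
                        bnew = (rho - lam) / denom[j]
                    elif rho < -lam:
                        bnew = (rho + lam) / denom[j]
                    else:
                        bnew = 0.0
                    diff = bnew - beta[j]
                    if diff != 0.0:
                        for i in range(n):
                            r[i] -= Xs[i, j] * diff
                        beta[j] = bnew
                        if abs(diff) > delta:
                            delta = abs(diff)
                if delta < tol:
                    break
            maxch = 0.0
            bmax = abs(b0)
            for j in range(p):
                if abs(beta[j]) > bmax:
                    bmax = abs(beta[j])
            for i in range(n):
                e = b0
                for j in range(p):
                    e += Xs[i, j] * beta[j]
                if abs(e - eta[i]) > maxch:
                    maxch = abs(e - eta[i])
            if maxch < 1e-8:
                good = True
                break
            if bmax > 30.0:  # effectively infinite log-odds: separable
                break
        intercepts[li] = b0
        betas[li] = beta
        ok[li] = good
    return intercepts, betas, ok


def fit_l1_logistic_path(
    X: np.ndarray, y: np.ndarray, lambdas: Sequence[float]
) -> PathFit:
    """Fit the Lasso-logistic coefficient path along a descending grid."""
    X, y = _validate_xy(X, y)
    lambdas = np.asarray(lambdas, dtype=float)
    Xs, mean, scale = _standardize(X)
    intercepts, std_coefs, ok = _cd_path_kernel(
        Xs, y, lambdas, 50, 200, 1e-9
    )
    if not ok.all():
        lam = lambdas[np.flatnonzero(~ok)[0]]
        warnings.warn(
            f"coordinate descent did not converge at lambda={lam:.3g} "
            "(data may be separable); coefficients capped at iteration limit",
            RuntimeWarning,
            stacklevel=2,
        )
    coefs = std_coefs / scale
    orig_intercepts = intercepts - coefs @ mean
    return PathFit(
        lambdas=lambdas,
        intercepts=orig_intercepts,
        coefs=coefs,
        std_coefs=std_coefs,
    )


def _binomial_deviance(prob: np.ndarray, y: np.ndarray) -> float:
    prob = np.clip(prob, _P_CLIP, 1.0 - _P_CLIP)
    return float(-2.0 * np.mean(y * np.log(prob) + (1.0 - y) * np.log(1.0 - prob)))


@dataclass
class LassoCvResult:
    """Cross-validated Lasso path with the two standard penalty choices."""

    lambdas: np.ndarray
    path: PathFit  # full-data fit along the grid
    cv_deviance: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    fold_assignment: np.ndarray
    seed: int
    feature_names: tuple[str, ...] = ()

    def index_of(self, which: str) -> int:
        lam = {"min": self.lambda_min, "1se": self.lambda_1se}[which]
        return int(np.argmin(np.abs(self.lambdas - lam)))


def _draw_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    try:
        for k, (_, test_idx) in enumerate(splitter.split(np.zeros_like(y), y)):
            assignment[test_idx] = k
    except ValueError as exc:  # both classes smaller than the fold count
        raise ContractError(f"cannot stratify {folds} folds: {exc}") from exc
    return assignment


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    feature_names: Sequence[str] = (),
) -> LassoCvResult:
    """K-fold cross-validated deviance along the penalty grid.

    Folds are stratified and drawn from ``seed``; should a training fold lose
    a class the folds are re-drawn once before erroring.  ``lambda_min``
    minimises the mean held-out deviance, ``lambda_1se`` is the largest
    penalty within one standard error of that minimum.
    """
    X, y = _validate_xy(X, y)
    if y.size < folds:
        raise ContractError(f"need at least {folds} samples for {folds}-fold CV")
    if lambdas is None:
        lambdas = lambda_grid(X, y)
    lambdas = np.asarray(lambdas, dtype=float)

    assignment = _draw_folds(y, folds, seed)
    for attempt in (0, 1):
        ok = all(
            len(np.unique(y[assignment != k])) == 2 for k in range(folds)
        )
        if ok:
            break
        if attempt == 1:
            raise ContractError("a CV training fold lost a class even after re-draw")
        logger.warning("re-drawing CV folds: a training fold lost a class")
        assignment = _draw_folds(y, folds, seed + 1)

    fold_dev = np.empty((folds, lambdas.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # capped fold fits are fine
        for k in range(folds):
            train, held = assignment != k, assignment == k
            fit = fit_l1_logistic_path(X[train], y[train], lambdas)
            for i in range(lambdas.size):
                fold_dev[k, i] = _binomial_deviance(
                    fit.predict_proba(X[held], i), y[held]
                )
    cv_deviance = fold_dev.mean(axis=0)
    cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(folds)

    i_min = int(np.argmin(cv_deviance))
    cutoff = cv_deviance[i_min] + cv_se[i_min]
    i_1se = int(np.flatnonzero(cv_deviance <= cutoff)[0])  # grid is descending

    full = fit_l1_logistic_path(X, y, lambdas)
    return LassoCvResult(
        lambdas=lambdas,
        path=full,
        cv_deviance=cv_deviance,
        cv_se=cv_se,
        lambda_min=float(lambdas[i_min]),
        lambda_1se=float(lambdas[i_1se]),
        fold_assignment=assignment,
        seed=seed,
        feature_names=tuple(feature_names),
    )


def selected_features(result: LassoCvResult, which: str = "1se") -> list[tuple[str, float]]:
    """Nonzero-coefficient features at the chosen penalty.

    Ordered by decreasing absolute standardised coefficient; each entry is
    ``(name, standardised coefficient)``.
    """
    idx = result.index_of(which)
    std = result.path.std_coefs[idx]
    names = result.feature_names or tuple(f"x{j}" for j in range(std.size))
    active = [(names[j], float(std[j])) for j in np.flatnonzero(std != 0.0)]
    return sorted(active, key=lambda item: -abs(item[1]))


@dataclass(frozen=True)
class LogisticModel:
    """A single fitted logistic model (one point on the path)."""

    feature_names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    lam: float

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coefficients.size:
            raise ContractError(
                f"model expects {self.coefficients.size} columns, got {X.shape[1]}"
            )
        eta = self.intercept + X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def fit_final_model(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    feature_names: Sequence[str] = (),
) -> LogisticModel:
    """Refit on all training data at one penalty (the reporting model)."""
    fit = fit_l1_logistic_path(X, y, [lam])
    names = tuple(feature_names) or tuple(f"x{j}" for j in range(fit.coefs.shape[1]))
    return LogisticModel(
        feature_names=names,
        intercept=float(fit.intercepts[0]),
        coefficients=fit.coefs[0],
        lam=float(lam),
    )


def choose_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability cut maximising Youden's J on the supplied (training) scores.

    Candidate thresholds are midpoints between consecutive distinct scores;
    ties are broken towards the smallest threshold.  Degenerate score vectors
    (all equal) fall back to 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if set(np.unique(labels)) != {0.0, 1.0}:
        raise ContractError("labels must contain both classes coded 0/1")
    distinct = np.unique(scores)
    if distinct.size == 1:
        warnings.warn(
            "all scores identical; falling back to threshold 0.5",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.5
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos, n_neg = labels.sum(), (1.0 - labels).sum()
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        j = (pred @ labels) / n_pos + ((~pred) @ (1.0 - labels)) / n_neg - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    if best_j <= 1e-12:
        warnings.warn(
            "scores carry no class information (max Youden J ~ 0)",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(best_t)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion table with the positive class (AD) on the first row."""

    pos_label: str
    neg_label: str
    counts: np.ndarray  # rows: actual (pos, neg); cols: predicted (pos, neg)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (2, 2) or (counts < 0).any():
            raise ContractError("counts must be a non-negative 2x2 table")

    @classmethod
    def from_counts(
        cls, tp: int, fn: int, fp: int, tn: int, pos_label: str = "AD", neg_label: str = "NL"
    ) -> "ConfusionMatrix":
        return cls(pos_label, neg_label, np.array([[tp, fn], [fp, tn]]))

    @property
    def per_class_accuracy(self) -> tuple[float, float]:
        row_totals = self.counts.sum(axis=1)
        return (
            float(self.counts[0, 0] / row_totals[0]) if row_totals[0] else float("nan"),
            float(self.counts[1, 1] / row_totals[1]) if row_totals[1] else float("nan"),
        )

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def balanced_accuracy(self) -> float:
        a, b = self.per_class_accuracy
        return (a + b) / 2.0

    def render(self) -> str:
        """Plain-text table in the published confusion-matrix layout."""
        acc = self.per_class_accuracy
        rows = [
            f"{'':10s}{'Predicted':>20s}",
            f"{'Actual':10s}{self.pos_label:>10s}{self.neg_label:>10s}{'Total':>8s}{'Accuracy':>10s}",
        ]
        for r, label in enumerate((self.pos_label, self.neg_label)):
            rows.append(
                f"{label:10s}{self.counts[r, 0]:>10d}{self.counts[r, 1]:>10d}"
                f"{self.counts[r].sum():>8d}{acc[r]:>10.2f}"
            )
        return "\n".join(rows)


def evaluate(
    model: LogisticModel,
    threshold: float,
    X_test: np.ndarray,
    y_test: np.ndarray,
    feature_names: Sequence[str] = (),
    pos_label: str = "AD",
    neg_label: str = "NL",
) -> ConfusionMatrix:
    """Threshold the model's test probabilities into a confusion matrix.

    When ``feature_names`` is given it must match the model's training columns
    exactly (same names, same order).
    """
    if feature_names and tuple(feature_names) != model.feature_names:
        extra = set(feature_names) - set(model.feature_names)
        missing = set(model.feature_names) - set(feature_names)
        raise ContractError(
            "test feature columns do not align with the model: "
            f"missing {sorted(missing)}, unexpected {sorted(extra)}"
        )
    y_test = np.asarray(y_test, dtype=float).ravel()
    pred = model.predict_proba(X_test) >= threshold
    actual = y_test == 1.0
    counts = np.array(
        [
            [int(np.sum(pred & actual)), int(np.sum(~pred & actual))],
            [int(np.sum(pred & ~actual)), int(np.sum(~pred & ~actual))],
        ]
    )
    return ConfusionMatrix(pos_label=pos_label, neg_label=neg_label, counts=counts)
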