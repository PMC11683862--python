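"""Resampling-based model validation for LFER regressions.

Implements the standard QSPR validation battery: a single hold-out split,
k-fold and repeated k-fold cross-validation, leave-one-out cross-validation
(with the exact hat-value shortcut for PRESS and Q^2), bootstrap
validation, and Bland-Altman agreement analysis between two measurement
series.

All schemes are deterministic given a seed and invariant to the input
record order: ids are sorted canonically before the seeded shuffle, so the
same seed yields the same membership regardless of how the table was
assembled.  The cross-validation "score" is the predictive R^2 on the
held-out records (1 - SSE/SST around the held-out mean), the same
convention as Q^2 — not a squared correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .fit import fit_ols_arrays, _design_matrix
from .tables import ChemicalTable

__all__ = [
    "ValidationResult",
    "BlandAltmanResult",
    "holdout_split",
    "kfold_cv",
    "loocv",
    "bootstrap_validation",
    "bland_altman",
]


@dataclass(frozen=True)
class ValidationResult:
    scheme: str
    scores: tuple[float, ...]
    rmse_scores: tuple[float, ...]
    mean_score: float
    sd_score: float
    seed: int | None = None
    q2: float | None = None
    press: float | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        assert abs(self.mean_score - scores.mean()) < 1e-12
        expected_sd = scores.std(ddof=1) if scores.size > 1 else 0.0
        assert abs(self.sd_score - expected_sd) < 1e-12


def _round_half_away(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _canonical_shuffled_ids(table: ChemicalTable, seed: int | None) -> list[str]:
    ids = sorted(table.ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    return ids


def _r2_score(observed: np.ndarray, predicted: np.ndarray) -> float:
    sse = float(np.sum((observed - predicted) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0.0:
        return 1.0 if sse == 0.0 else -math.inf
    return 1.0 - sse / sst


def holdout_split(
    table: ChemicalTable, test_fraction: float, seed: int | None = None
) -> tuple[ChemicalTable, ChemicalTable]:
    """Split a table into disjoint train/test tables.

    The test size is round-half-away-from-zero of n*test_fraction; the
    split is deterministic given the seed and independent of record order.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n = len(table)
    n_test = _round_half_away(n * test_fraction)
    if n_test < 1 or n - n_test < 1:
        raise ValueError(f"degenerate split: n={n}, test_fraction={test_fraction}")
    shuffled = _canonical_shuffled_ids(table, seed)
    test_ids = set(shuffled[:n_test])
    order = table.ids
    train = table.subset([i for i in order if i not in test_ids])
    test = table.subset([i for i in order if i in test_ids])
    return train, test


def _fold_assignment(ids: Sequence[str], k: int) -> list[list[str]]:
    """Deal shuffled ids round-robin into k folds."""
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, chem_id in enumerate(ids):
        folds[i % k].append(chem_id)
    return folds


def _fit_predict(
    X_train, y_train, X_test, include_intercept: bool
) -> np.ndarray:
    design = sm.add_constant(X_train, has_constant="add") if include_intercept else X_train
    beta, *_ = np.linalg.lstsq(design, y_train, rcond=None)
    test_design = sm.add_constant(X_test, has_constant="add") if include_intercept else X_test
    return test_design @ beta


def kfold_cv(
    table: ChemicalTable,
    response: str,
    predictors: Sequence[str] = ("logKow", "logKaw"),
    k: int = 5,
    repeats: int = 1,
    include_intercept: bool = True,
    seed: int | None = None,
) -> ValidationResult:
    """k-fold (optionally repeated) cross-validation of the OLS model.

    Folds are re-randomized each repeat; the per-fold score is the
    predictive R^2 on that fold's held-out observations.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    X, y, ids = _design_matrix(table, response, predictors)
    index = {chem_id: i for i, chem_id in enumerate(ids)}
    p = X.shape[1]

    root = np.random.default_rng(seed)
    scores: list[float] = []
    rmses: list[float] = []
    for _ in range(repeats):
        shuffled = sorted(ids)
        root_seed = root.integers(0, 2**31)
        np.random.default_rng(root_seed).shuffle(shuffled)
        for fold in _fold_assignment(shuffled, k):
            if len(fold) < 2:
                raise ValueError(
                    f"a fold has {len(fold)} test record(s); use a smaller k"
                )
            test_idx = np.array([index[i] for i in fold])
            train_mask = np.ones(len(ids), dtype=bool)
            train_mask[test_idx] = False
            if train_mask.sum() < p + 2:
                raise ValueError("training fold too small for the model")
            predicted = _fit_predict(
                X[train_mask], y[train_mask], X[test_idx], include_intercept
            )
            scores.append(_r2_score(y[test_idx], predicted))
            rmses.append(float(np.sqrt(np.mean((y[test_idx] - predicted) ** 2))))

    scores_arr = np.array(scores)
    return ValidationResult(
        scheme="repeated_kfold" if repeats > 1 else "kfold",
        scores=tuple(scores),
        rmse_scores=tuple(rmses),
        mean_score=float(scores_arr.mean()),
        sd_score=float(scores_arr.std(ddof=1)) if len(scores) > 1 else 0.0,
        seed=seed,
    )


def loocv(
    table: ChemicalTable,
    response: str,
    predictors: Sequence[str] = ("logKow", "logKaw"),
    include_intercept: bool = True,
    method: str = "hat",
) -> ValidationResult:
    """Leave-one-out cross-validation: PRESS and predictive Q^2.

    ``method="hat"`` uses the exact algebraic shortcut
    PRESS = sum((e_i/(1-h_ii))^2) from a single fit; ``method="refit"``
    runs the explicit n-fold refit loop.  Both agree to numerical
    precision; the shortcut is the default.
    """
    X, y, ids = _design_matrix(table, response, predictors)
    n, p = X.shape
    if n < p + 3:
        raise ValueError("LOOCV needs at least p + 3 records")

    fit = fit_ols_arrays(y, X, predictors, include_intercept=include_intercept)
    if np.any(fit.leverage >= 1.0 - 1e-12):
        raise ValueError("a record has leverage 1 (exact interpolation); "
                         "LOOCV predictions are undefined for it")
    if method == "hat":
        press_residuals = fit.residuals / (1.0 - fit.leverage)
    elif method == "refit":
        press_residuals = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            predicted = _fit_predict(X[mask], y[mask], X[i:i + 1], include_intercept)
            press_residuals[i] = y[i] - predicted[0]
    else:
        raise ValueError("method must be 'hat' or 'refit'")

    press = float(np.sum(press_residuals**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / sst
    score = q2
    return ValidationResult(
        scheme="loocv",
        scores=(score,),
        rmse_scores=(float(np.sqrt(press / n)),),
        mean_score=score,
        sd_score=0.0,
        q2=q2,
        press=press,
    )


def bootstrap_validation(
    table: ChemicalTable,
    response: str,
    predictors: Sequence[str] = ("logKow", "logKaw"),
    replicates: int = 1000,
    sample_fraction: float = 0.5,
    include_intercept: bool = True,
    seed: int | None = None,
) -> ValidationResult:
    """Bootstrap validation: refit on resamples, score on the full table.

    Each replicate draws round(n*sample_fraction) records with
    replacement, refits, and scores R^2 of the refitted model's
    predictions over the complete table.  Rank-deficient replicates are
    redrawn (at most 10% of the requested replicates).
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    X, y, _ = _design_matrix(table, response, predictors)
    n, p = X.shape
    m = _round_half_away(n * sample_fraction)
    if m < p + 2:
        raise ValueError("resample size too small for the model")

    rng = np.random.default_rng(seed)
    scores: list[float] = []
    rmses: list[float] = []
    redraws = 0
    max_redraws = max(1, replicates // 10)
    while len(scores) < replicates:
        idx = rng.integers(0, n, size=m)
        design = sm.add_constant(X[idx], has_constant="add") if include_intercept else X[idx]
        if np.linalg.matrix_rank(design) < design.shape[1]:
            redraws += 1
            if redraws > max_redraws:
                raise ValueError("too many rank-deficient bootstrap replicates")
            continue
        predicted = _fit_predict(X[idx], y[idx], X, include_intercept)
        scores.append(_r2_score(y, predicted))
        rmses.append(float(np.sqrt(np.mean((y - predicted) ** 2))))

    scores_arr = np.array(scores)
    return ValidationResult(
        scheme="bootstrap",
        scores=tuple(scores),
        rmse_scores=tuple(rmses),
        mean_score=float(scores_arr.mean()),
        sd_score=float(scores_arr.std(ddof=1)),
        seed=seed,
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    outliers: tuple[int, ...]

    def __post_init__(self) -> None:
        assert self.lower_limit <= self.bias <= self.upper_limit


def bland_altman(
    pairs: Iterable[tuple[float, float]], limit_multiplier: float = 1.96
) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of two paired measurement series.

    Differences are a - b; the limits of agreement are
    bias +/- 1.96*SD(differences) (sample SD).  Returns the indices of
    pairs falling strictly outside the limits.
    """
    diffs = np.array([a - b for a, b in pairs], dtype=float)
    if diffs.size < 3:
        raise ValueError("Bland-Altman analysis needs at least 3 pairs")
    if not np.all(np.isfinite(diffs)):
        raise ValueError("all pairs must be finite")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lower, upper = bias - limit_multiplier * sd, bias + limit_multiplier * sd
    outliers = tuple(
        int(i) for i, d in enumerate(diffs) if d < lower or d > upper
    )
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, lower_limit=lower, upper_limit=upper,
        outliers=outliers,
    )
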