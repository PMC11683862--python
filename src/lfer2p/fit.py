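"""Ordinary least squares fitting of 2p-LFER models and coefficient inference.

Fits a log K response against logKow/logKaw (or any numeric columns) by
multiple linear regression, reporting the regression statistics used in
the LFER literature: R^2, adjusted R^2, F statistic, RMSE, analytic
coefficient standard errors, per-record residuals and leverage (hat)
values.  Coefficient SEs can also be obtained by a case bootstrap, terms
can be eliminated backwards by t-test significance, and coefficient sets
from two fits can be compared with a two-sample z statistic.

RMSE defaults to sqrt(SSE/n); ``rmse_denominator="residual_df"`` switches
to the sqrt(SSE/(n-p-1)) convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .tables import ChemicalTable

__all__ = [
    "FitResult",
    "CoefficientComparison",
    "fit_ols",
    "fit_ols_arrays",
    "bootstrap_coefficient_se",
    "drop_insignificant_terms",
    "compare_coefficients_z",
]


@dataclass
class FitResult:
    """A fitted linear model with its diagnostics.

    ``coefficients`` maps each original term name (predictors plus
    ``"intercept"`` when requested) to its estimate; terms removed by
    backward elimination stay present with coefficient exactly 0.0 and no
    standard error.
    """

    response: str
    predictors: tuple[str, ...]
    include_intercept: bool
    coefficients: dict[str, float]
    analytic_se: dict[str, float]
    bootstrap_se: dict[str, float] | None
    dropped_terms: tuple[str, ...]
    n: int
    p: int
    r2: float
    adj_r2: float
    rmse: float
    f_stat: float
    residuals: np.ndarray
    fitted: np.ndarray
    leverage: np.ndarray
    ids: tuple[str, ...]
    rmse_denominator: str = "n"
    # retained design/response so refits (term dropping, studentization)
    # do not need the original table
    _X: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    _y: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def active_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.coefficients if t not in self.dropped_terms)

    @property
    def residual_df(self) -> int:
        return self.n - len(self.active_terms)

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))

    def coefficient_tuple(self) -> tuple[float, ...]:
        return tuple(self.coefficients.values())

    def t_pvalues(self) -> dict[str, float]:
        """Two-sided t-test p-values of the active terms against zero."""
        df = self.residual_df
        out = {}
        for term in self.active_terms:
            t = self.coefficients[term] / self.analytic_se[term]
            out[term] = 2.0 * stats.t.sf(abs(t), df)
        return out


def _design_matrix(
    table: ChemicalTable, response: str, predictors: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    frame = table.to_frame()
    response_col = response if response in frame.columns else f"logK_{response}"
    if response_col not in frame.columns:
        raise ValueError(f"response column {response!r} not found in table")
    missing = [p for p in predictors if p not in frame.columns]
    if missing:
        raise ValueError(f"predictor column(s) not in table: {', '.join(missing)}")
    sub = frame[["id", *predictors, response_col]].dropna()
    y = sub[response_col].to_numpy(dtype=float)
    X = sub[list(predictors)].to_numpy(dtype=float)
    return X, y, sub["id"].astype(str).tolist()


def fit_ols_arrays(
    y: np.ndarray,
    X: np.ndarray,
    predictors: Sequence[str],
    include_intercept: bool = True,
    response: str = "y",
    ids: Sequence[str] | None = None,
    rmse_denominator: str = "n",
) -> FitResult:
    """Fit OLS on raw arrays; the array-level core behind :func:`fit_ols`."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} records to fit {p} predictors, got {n}")
    design = sm.add_constant(X, has_constant="add") if include_intercept else X
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; check for collinear columns among "
            + ", ".join(predictors)
        )
    model = sm.OLS(y, design)
    res = model.fit()

    names = (["intercept"] if include_intercept else []) + list(predictors)
    coefficients = dict(zip(names, (float(b) for b in res.params)))
    analytic_se = dict(zip(names, (float(s) for s in res.bse)))
    # reorder so predictors come first, intercept last (lambda1, lambda2, lambda3)
    order = list(predictors) + (["intercept"] if include_intercept else [])
    coefficients = {k: coefficients[k] for k in order}
    analytic_se = {k: analytic_se[k] for k in order}

    residuals = np.asarray(res.resid, dtype=float)
    sse = float(residuals @ residuals)
    if include_intercept:
        r2 = float(res.rsquared)
        adj_r2 = float(res.rsquared_adj)
        f_stat = float(res.fvalue)
    else:
        # centred (total-sum-of-squares) conventions even without intercept,
        # so statistics stay comparable across the two model forms
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - sse / sst
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
        f_stat = (r2 / p) / ((1.0 - r2) / (n - p)) if r2 < 1.0 else math.inf
    denom = n if rmse_denominator == "n" else (n - design.shape[1])
    rmse = math.sqrt(sse / denom)
    leverage = np.asarray(res.get_influence().hat_matrix_diag, dtype=float)

    return FitResult(
        response=response,
        predictors=tuple(predictors),
        include_intercept=include_intercept,
        coefficients=coefficients,
        analytic_se=analytic_se,
        bootstrap_se=None,
        dropped_terms=(),
        n=n,
        p=p,
        r2=r2,
        adj_r2=adj_r2,
        rmse=rmse,
        f_stat=f_stat,
        residuals=residuals,
        fitted=np.asarray(res.fittedvalues, dtype=float),
        leverage=leverage,
        ids=tuple(ids) if ids is not None else tuple(str(i) for i in range(n)),
        rmse_denominator=rmse_denominator,
        _X=X,
        _y=y,
    )


def fit_ols(
    table: ChemicalTable,
    response: str,
    predictors: Sequence[str] = ("logKow", "logKaw"),
    include_intercept: bool = True,
    rmse_denominator: str = "n",
) -> FitResult:
    """Regress an observed log K column on descriptor columns by OLS.

    ``response`` may name an observed phase (``"structural_protein"``) or a
    flattened column (``"logK_structural_protein"``).  Records missing the
    response or any predictor are excluded from the fit.
    """
    X, y, ids = _design_matrix(table, response, predictors)
    return fit_ols_arrays(
        y, X, predictors, include_intercept=include_intercept,
        response=response, ids=ids, rmse_denominator=rmse_denominator,
    )


def bootstrap_coefficient_se(
    table: ChemicalTable,
    response: str,
    predictors: Sequence[str] = ("logKow", "logKaw"),
    include_intercept: bool = True,
    replicates: int = 1000,
    seed: int | None = None,
) -> dict[str, float]:
    """Case-bootstrap standard errors of the OLS coefficients.

    Records are resampled with replacement at full n, the model refitted,
    and the SD of each coefficient across replicates reported.  A
    rank-deficient replicate is redrawn (counted); more than 10% redraws
    aborts.
    """
    if replicates < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    X, y, _ = _design_matrix(table, response, predictors)
    n = len(y)
    rng = np.random.default_rng(seed)
    names = list(predictors) + (["intercept"] if include_intercept else [])

    draws = np.empty((replicates, len(names)))
    redraws = 0
    max_redraws = max(1, replicates // 10)
    i = 0
    while i < replicates:
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        design = sm.add_constant(Xb, has_constant="add") if include_intercept else Xb
        if np.linalg.matrix_rank(design) < design.shape[1]:
            redraws += 1
            if redraws > max_redraws:
                raise ValueError(
                    f"more than {max_redraws} rank-deficient bootstrap replicates"
                )
            continue
        beta, *_ = np.linalg.lstsq(design, yb, rcond=None)
        if include_intercept:
            beta = np.concatenate([beta[1:], beta[:1]])
        draws[i] = beta
        i += 1
    sds = draws.std(axis=0, ddof=1)
    return dict(zip(names, (float(s) for s in sds)))


def drop_insignificant_terms(
    fit: FitResult, alpha: float = 0.05, strict: bool = False
) -> FitResult:
    """Backward-eliminate terms not significantly different from zero.

    Repeatedly removes the least significant term whose two-sided t-test
    p-value exceeds ``alpha`` and refits, until every remaining term is
    significant.  Removed terms are reported with coefficient exactly 0.0.
    Idempotent.  With ``strict=True``, eliminating every term raises.
    """
    current = fit
    while True:
        pvalues = current.t_pvalues()
        candidates = {t: p for t, p in pvalues.items() if p > alpha}
        if not candidates:
            return current
        victim = max(candidates, key=candidates.get)
        remaining_predictors = [
            t for t in current.predictors
            if t != victim and t not in current.dropped_terms
        ]
        include_intercept = current.include_intercept and victim != "intercept" \
            and "intercept" not in current.dropped_terms
        if not remaining_predictors and not include_intercept:
            if strict:
                raise ValueError("all terms eliminated; no model remains")
            return current
        cols = [current.predictors.index(t) for t in remaining_predictors]
        refit = fit_ols_arrays(
            current._y, current._X[:, cols], remaining_predictors,
            include_intercept=include_intercept,
            response=current.response, ids=current.ids,
            rmse_denominator=current.rmse_denominator,
        )
        dropped = current.dropped_terms + (victim,)
        coefficients = {}
        analytic_se = {}
        for term in fit.coefficients:
            if term in dropped:
                coefficients[term] = 0.0
            elif term in refit.coefficients:
                coefficients[term] = refit.coefficients[term]
                analytic_se[term] = refit.analytic_se[term]
        current = replace(
            refit,
            predictors=fit.predictors,
            include_intercept=fit.include_intercept,
            coefficients=coefficients,
            analytic_se=analytic_se,
            dropped_terms=dropped,
            _X=current._X,
        )


@dataclass(frozen=True)
class CoefficientComparison:
    """Two-sample z comparison of shared coefficients between two fits."""

    terms: tuple[str, ...]
    z: dict[str, float]
    significant: dict[str, bool]
    critical: float


def compare_coefficients_z(
    fit1: FitResult | Mapping[str, tuple[float, float]],
    fit2: FitResult | Mapping[str, tuple[float, float]],
    critical: float = 1.96,
    se_source: str = "analytic",
) -> CoefficientComparison:
    """Test whether two fits' coefficients differ: z = (b1-b2)/sqrt(SE1^2+SE2^2).

    Inputs may be :class:`FitResult` objects or plain mappings
    ``term -> (coefficient, SE)``.  Only terms present in both fits are
    compared; a coefficient pair is flagged significant when |z| exceeds
    the critical value (1.96 for the 5% level).
    """

    def extract(obj) -> dict[str, tuple[float, float]]:
        if isinstance(obj, FitResult):
            ses = obj.bootstrap_se if (se_source == "bootstrap"
                                       and obj.bootstrap_se) else obj.analytic_se
            return {t: (obj.coefficients[t], ses[t])
                    for t in obj.active_terms if t in ses}
        return {t: (float(b), float(se)) for t, (b, se) in obj.items()}

    a, b = extract(fit1), extract(fit2)
    shared = [t for t in a if t in b]
    if not shared:
        raise ValueError("fits share no coefficient terms")
    z = {}
    for term in shared:
        (b1, se1), (b2, se2) = a[term], b[term]
        z[term] = (b1 - b2) / math.sqrt(se1**2 + se2**2)
    significant = {t: abs(v) > critical for t, v in z.items()}
    return CoefficientComparison(
        terms=tuple(shared), z=z, significant=significant, critical=critical
    )
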