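"""Chemical-space diagnostics: PCA, correlation structure, applicability domain.

Dimensionality analysis of a chemicals-by-variables matrix (observed log K
plus Abraham descriptors plus logKow/logKaw) answers how many orthogonal
dimensions carry the dataset's information and how well each variable is
represented in each principal dimension (the squared cosine, cos2).
Pearson correlation matrices expose pairwise interdependencies.

The applicability domain of a fitted LFER is assessed with the Williams
plot ingredients: leverage (hat values) of each training record against
its studentized residual, with records beyond either threshold flagged as
outside the domain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fit import FitResult

__all__ = [
    "PCAResult",
    "CorrelationMatrix",
    "DomainDiagnostics",
    "pca_analysis",
    "pearson_matrix",
    "leverage_values",
    "williams_classification",
]


@dataclass(frozen=True)
class PCAResult:
    """Eigen-analysis of a standardized (or raw-covariance) variable set.

    ``variable_cos2[j, k]`` is the squared correlation between variable j
    and principal dimension k — the "quality of representation" of the
    variable in that dimension.  For correlation-matrix PCA each
    variable's cos2 values sum to 1 across all dimensions.
    """

    variables: tuple[str, ...]
    eigenvalues: np.ndarray
    variance_proportion: np.ndarray
    cumulative: np.ndarray
    loadings: np.ndarray       # variables x dimensions, variable-PC correlations
    variable_cos2: np.ndarray  # loadings squared


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    r: np.ndarray
    degenerate: tuple[str, ...] = ()

    def get(self, a: str, b: str) -> float:
        return float(self.r[self.variables.index(a), self.variables.index(b)])


@dataclass(frozen=True)
class DomainDiagnostics:
    ids: tuple[str, ...]
    leverage: np.ndarray
    studentized_residuals: np.ndarray
    in_domain: np.ndarray
    leverage_threshold: float
    residual_bound: float

    @property
    def flagged_ids(self) -> tuple[str, ...]:
        return tuple(i for i, ok in zip(self.ids, self.in_domain) if not ok)


def _as_matrix(data, columns: Sequence[str] | None):
    if isinstance(data, pd.DataFrame):
        frame = data if columns is None else data[list(columns)]
        return frame.to_numpy(dtype=float), tuple(str(c) for c in frame.columns)
    arr = np.asarray(data, dtype=float)
    names = tuple(columns) if columns is not None else tuple(
        f"var{i}" for i in range(arr.shape[1])
    )
    return arr, names


def pca_analysis(
    data, columns: Sequence[str] | None = None, standardize: bool = True
) -> PCAResult:
    """Principal component analysis with variance proportions and cos2.

    With ``standardize=True`` (default) the eigen-decomposition is of the
    correlation matrix, appropriate when the variables mix scales (log K
    values alongside Abraham descriptors).  Eigenvector signs follow the
    convention that each component's largest-magnitude loading is
    positive.
    """
    X, names = _as_matrix(data, columns)
    n, m = X.shape
    if n < 3 or m < 2:
        raise ValueError("PCA needs at least 3 rows and 2 columns")
    if np.isnan(X).any():
        rows, cols = np.nonzero(np.isnan(X))
        cells = ", ".join(f"({r}, {names[c]})" for r, c in zip(rows[:5], cols[:5]))
        raise ValueError(f"missing values in PCA input at {cells}")
    sd = X.std(axis=0, ddof=1)
    zero_var = [names[j] for j in range(m) if sd[j] == 0.0]
    if zero_var:
        raise ValueError(f"zero-variance column(s): {', '.join(zero_var)}")

    if standardize:
        S = np.corrcoef(X, rowvar=False)
    else:
        S = np.cov(X, rowvar=False)
    eigenvalues, eigenvectors = np.linalg.eigh(S)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for k in range(m):
        j = np.argmax(np.abs(eigenvectors[:, k]))
        if eigenvectors[j, k] < 0:
            eigenvectors[:, k] *= -1.0

    proportion = eigenvalues / eigenvalues.sum()
    # variable-PC correlation: v_jk * sqrt(lambda_k) / sd_j (sd_j = 1 when standardized)
    scale = np.ones(m) if standardize else np.sqrt(np.diag(S))
    loadings = eigenvectors * np.sqrt(eigenvalues)[np.newaxis, :] / scale[:, np.newaxis]
    return PCAResult(
        variables=names,
        eigenvalues=eigenvalues,
        variance_proportion=proportion,
        cumulative=np.cumsum(proportion),
        loadings=loadings,
        variable_cos2=loadings**2,
    )


def pearson_matrix(
    data, columns: Sequence[str] | None = None, policy: str = "complete"
) -> CorrelationMatrix:
    """Pearson correlation matrix of a chemicals-by-variables matrix.

    ``policy="complete"`` (default) drops rows with any missing value;
    ``"pairwise"`` uses pairwise-complete observations per entry.
    Constant columns yield undefined (NaN) entries and are reported in
    ``degenerate`` rather than silently zeroed.
    """
    if isinstance(data, pd.DataFrame):
        frame = data if columns is None else data[list(columns)]
    else:
        arr = np.asarray(data, dtype=float)
        names = list(columns) if columns is not None else [
            f"var{i}" for i in range(arr.shape[1])
        ]
        frame = pd.DataFrame(arr, columns=names)
    if policy == "complete":
        frame = frame.dropna()
    elif policy != "pairwise":
        raise ValueError("policy must be 'complete' or 'pairwise'")
    if len(frame) < 3:
        raise ValueError("need at least 3 complete rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = frame.corr(method="pearson").to_numpy()
    names = tuple(str(c) for c in frame.columns)
    degenerate = tuple(
        names[j] for j in range(len(names)) if frame.iloc[:, j].nunique() <= 1
    )
    return CorrelationMatrix(variables=names, r=r, degenerate=degenerate)


def leverage_values(design: np.ndarray) -> np.ndarray:
    """Diagonal of the hat matrix X (X'X)^-1 X' for a full-rank design."""
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    Q, _ = np.linalg.qr(X)
    return np.sum(Q**2, axis=1)


def williams_classification(
    fit: FitResult,
    leverage_threshold: float | None = None,
    residual_bound: float = 2.0,
    studentization: str = "internal",
) -> DomainDiagnostics:
    """Classify training records against the Williams-plot domain.

    A record is outside the applicability domain when its leverage h_ii
    exceeds the threshold (default 3(p+1)/n; pass an explicit value such
    as 0.06 to reproduce a fixed published cut) or its studentized
    residual magnitude exceeds ``residual_bound`` (default 2).

    ``studentization="internal"`` uses r_i = e_i/(s*sqrt(1-h_ii)) with
    s^2 = SSE/(n-p-1); ``"external"`` re-estimates s without record i
    (deletion residuals).
    """
    h = np.asarray(fit.leverage, dtype=float)
    e = np.asarray(fit.residuals, dtype=float)
    n = fit.n
    n_params = len(fit.active_terms)
    if leverage_threshold is None:
        leverage_threshold = 3.0 * n_params / n
    df = n - n_params
    s2 = fit.sse / df

    residuals = np.empty(n)
    degenerate = h >= 1.0 - 1e-12
    if degenerate.any():
        warnings.warn("record(s) with leverage ~1; studentized residual infinite")
    with np.errstate(divide="ignore", invalid="ignore"):
        internal = e / np.sqrt(s2 * (1.0 - h))
    if studentization == "internal":
        residuals = internal
    elif studentization == "external":
        # s_(i)^2 = s^2 * (df - r_i^2) / (df - 1)
        s2_i = s2 * (df - internal**2) / (df - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            residuals = e / np.sqrt(s2_i * (1.0 - h))
    else:
        raise ValueError("studentization must be 'internal' or 'external'")
    residuals[degenerate] = np.inf

    in_domain = (np.abs(residuals) <= residual_bound) & (h <= leverage_threshold)
    return DomainDiagnostics(
        ids=fit.ids,
        leverage=h,
        studentized_residuals=residuals,
        in_domain=in_domain,
        leverage_threshold=float(leverage_threshold),
        residual_bound=float(residual_bound),
    )
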