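"""Shrinkage estimation of partial correlations for one sample group.

The sample correlation matrix U is replaced by the regularized estimate

    U* = lambda * T + (1 - lambda) * U,

where the target T is the identity on the correlation scale (unit
diagonal, off-diagonals shrunk toward zero) and the shrinkage intensity
lambda is the analytic Ledoit-Wolf optimum

    lambda* = sum_{i != j} Var_hat(r_ij) / sum_{i != j} r_ij^2,

clipped to [0, 1].  Partial correlations follow from the inverse
Omega = (U*)^-1 as pcor_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj):
the correlation between variables i and j conditioning on all remaining
variables.  With lambda > 0 the estimate exists even when the number of
variables exceeds the sample size, which is what makes the approach
usable for strongly collinear panels such as lipoprotein subclasses.

Variances are not shrunk: shrinkage acts purely on the correlation scale.
Var_hat(r_ij) is the standard small-sample plug-in, n/(n-1)^3 times the
sum of squared deviations of the per-sample products of standardized
values; columns are standardized with the unbiased (n-1) variance
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShrinkagePcorResult",
    "estimate_lambda",
    "shrink_correlation",
    "partial_correlations",
    "pcor_from_data",
    "fit_group",
]


@dataclass(frozen=True)
class ShrinkagePcorResult:
    """Shrinkage partial-correlation fit for one group.

    Attributes
    ----------
    lambda_hat
        Estimated shrinkage intensity in [0, 1].
    regularized_correlation
        U* on the correlation scale: symmetric, unit diagonal, positive
        definite for lambda > 0.
    pcor
        M x M symmetric partial-correlation matrix, unit diagonal.
    n
        Number of samples used.
    variable_names
        Optional column identifiers, in canonical order.
    """

    lambda_hat: float
    regularized_correlation: np.ndarray
    pcor: np.ndarray
    n: int
    variable_names: tuple[str, ...] | None = None


def _check_matrix(data: np.ndarray) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-d samples x variables matrix")
    n, m = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if m < 2:
        raise ValueError(f"need at least 2 variables, got {m}")
    return x


def _standardize(x: np.ndarray, variable_names=None) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = (
            [variable_names[i] for i in zero]
            if variable_names is not None
            else list(zero)
        )
        raise ValueError(f"zero-variance column(s): {names}")
    return (x - x.mean(axis=0)) / sd


def _lambda_terms(xs: np.ndarray) -> tuple[float, float]:
    """Numerator and denominator sums of the optimal-lambda formula."""
    n = xs.shape[0]
    s1 = xs.T @ xs  # sum over samples of products w_kij
    s2 = (xs**2).T @ (xs**2)  # sum of squared products
    r = s1 / (n - 1)
    var_r = n / (n - 1) ** 3 * (s2 - s1**2 / n)
    num = float(var_r.sum() - np.trace(var_r))
    den = float((r**2).sum() - np.trace(r**2))
    return num, den


def estimate_lambda(data: np.ndarray, variable_names=None) -> float:
    """Analytic optimal shrinkage intensity toward the identity target.

    Returns 1.0 when all off-diagonal sample correlations are exactly
    zero (the data are indistinguishable from the target).
    """
    x = _check_matrix(data)
    xs = _standardize(x, variable_names)
    num, den = _lambda_terms(xs)
    if den == 0.0:
        return 1.0
    return float(np.clip(num / den, 0.0, 1.0))


def shrink_correlation(data: np.ndarray, lam: float | str = "auto",
                       variable_names=None) -> np.ndarray:
    """Regularized correlation matrix U* = lambda*I + (1-lambda)*U."""
    x = _check_matrix(data)
    xs = _standardize(x, variable_names)
    n = x.shape[0]
    u = xs.T @ xs / (n - 1)
    u = (u + u.T) / 2.0
    np.fill_diagonal(u, 1.0)
    if lam == "auto":
        num, den = _lambda_terms(xs)
        lam = 1.0 if den == 0.0 else float(np.clip(num / den, 0.0, 1.0))
    else:
        lam = float(lam)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")
    u_star = (1.0 - lam) * u
    np.fill_diagonal(u_star, 1.0)
    return u_star


def partial_correlations(regularized_correlation: np.ndarray) -> np.ndarray:
    """Partial correlations from a symmetric positive-definite correlation.

    pcor_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) with Omega the matrix
    inverse of the input; diagonal set to 1.
    """
    r = np.asarray(regularized_correlation, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    try:
        np.linalg.cholesky(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is numerically singular; use a shrinkage "
            "intensity lambda > 0"
        ) from exc
    omega = np.linalg.inv(r)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    pcor = (pcor + pcor.T) / 2.0
    np.fill_diagonal(pcor, 1.0)
    return pcor


def pcor_from_data(data: np.ndarray, lam: float | str = "auto",
                   variable_names=None) -> ShrinkagePcorResult:
    """Full shrinkage partial-correlation fit on one data matrix."""
    x = _check_matrix(data)
    if lam == "auto":
        lam_val = estimate_lambda(x, variable_names)
    else:
        lam_val = float(lam)
    u_star = shrink_correlation(x, lam_val, variable_names)
    pcor = partial_correlations(u_star)
    return ShrinkagePcorResult(
        lambda_hat=lam_val,
        regularized_correlation=u_star,
        pcor=pcor,
        n=x.shape[0],
        variable_names=tuple(variable_names) if variable_names is not None else None,
    )


def fit_group(data, group: str) -> ShrinkagePcorResult:
    """Fit the shrinkage partial-correlation model to one group of a dataset."""
    x = data.values_for(group)
    return pcor_from_data(x, "auto", data.variable_names)
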