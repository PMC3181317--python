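"""Differential network: permutation test for between-group pcor changes.

For every unordered variable pair the statistic is

    d = | r_A - r_B |,

the absolute difference between the shrinkage partial correlations of the
two physiological groups.  The null distribution is built by pooling all
samples, permuting the group labels while preserving the two group sizes,
re-fitting the full shrinkage partial-correlation model in each
pseudo-group (with the shrinkage intensity lambda re-estimated every
time), and recording d* per pair.  One shared pool of permutations serves
all pairs, exactly as the labels-not-pairs protocol dictates, so per-pair
nulls are dependent across pairs.

The permutation p-value uses the add-one estimator

    p = (1 + #{d* >= d_obs}) / (1 + n_perm),

which can never return 0.  Significant pairs (p <= alpha, uncorrected by
default because power for correlation changes is low relative to
single-variable shifts) are classified relative to the first (reference)
group: ``sign_change`` when the two correlations have opposite signs and
both magnitudes clear ``min_magnitude``, otherwise ``increase`` /
``decrease`` by comparison of |r_B| with |r_A|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import networkx as nx
import numpy as np
import pandas as pd

from .io import GroupedDataset
from .network import bonferroni_threshold
from .shrinkage import fit_group

__all__ = [
    "DifferentialEdgeSet",
    "permutation_null",
    "permutation_pvalues",
    "classify_change",
    "build_differential_network",
]

CATEGORIES = ("increase", "decrease", "sign_change", "none")


@dataclass
class DifferentialEdgeSet:
    """Per-pair differential test results and the significant subset.

    ``table`` has one row per unordered pair: variable_i, variable_j,
    r_A, r_B, d_obs, p_perm, category.  ``category`` is ``"none"`` exactly
    when p_perm > alpha.
    """

    table: pd.DataFrame
    nodes: list[str]
    group_a: str
    group_b: str
    n_permutations: int
    seed: int
    alpha: float
    min_magnitude: float
    lambda_a: float
    lambda_b: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table.loc[self.table["category"] != "none"].reset_index(drop=True)

    @property
    def n_differentially_connected(self) -> int:
        sig = self.significant
        return len(set(sig["variable_i"]) | set(sig["variable_j"]))

    @property
    def n_unconnected(self) -> int:
        return len(self.nodes) - self.n_differentially_connected

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.significant.itertuples(index=False):
            g.add_edge(
                row.variable_i,
                row.variable_j,
                r_A=float(row.r_A),
                r_B=float(row.r_B),
                d_obs=float(row.d_obs),
                p_value=float(row.p_perm),
                category=str(row.category),
            )
        return g


# -- batched shrinkage pcor ----------------------------------------------


def _batch_pcor(x3: np.ndarray) -> np.ndarray:
    """Shrinkage partial correlations for a batch of (B, n, M) matrices.

    Vectorized replica of the single-matrix path in :mod:`.shrinkage`:
    standardize with ddof=1, analytic lambda toward the identity target,
    invert the regularized correlation, scale to partial correlations.
    """
    b, n, m = x3.shape
    xc = x3 - x3.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1, ddof=1, keepdims=True)
    xs = xc / sd
    xt = xs.transpose(0, 2, 1)
    s1 = xt @ xs
    s2 = (xs**2).transpose(0, 2, 1) @ (xs**2)
    r = s1 / (n - 1)
    var_r = n / (n - 1) ** 3 * (s2 - s1**2 / n)
    tr = np.arange(m)
    num = var_r.sum(axis=(1, 2)) - var_r[:, tr, tr].sum(axis=1)
    r2 = r**2
    den = r2.sum(axis=(1, 2)) - r2[:, tr, tr].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(den > 0, np.clip(num / den, 0.0, 1.0), 1.0)
    u_star = (1.0 - lam)[:, None, None] * r
    u_star[:, tr, tr] = 1.0
    omega = np.linalg.inv(u_star)
    d = np.sqrt(omega[:, tr, tr])
    pcor = -omega / (d[:, :, None] * d[:, None, :])
    pcor = (pcor + pcor.transpose(0, 2, 1)) / 2.0
    pcor[:, tr, tr] = 1.0
    return pcor


class _PermutationEngine:
    """Moment-based permutation engine sharing one feature precomputation.

    For a pseudo-group defined by a row-selection vector, the sample
    correlations r_ij and the plug-in variances Var_hat(r_ij) are both
    polynomials in per-sample moments: sums of x_i, x_i^2, x_i x_j,
    x_i^2 x_j and x_i^2 x_j^2 over the selected rows.  Those features
    are computed once per dataset; each permutation then costs a single
    matrix product (selection x features), and the complementary
    pseudo-group's sums are total sums minus the first group's.  Columns
    are globally centered and scaled first, which leaves partial
    correlations invariant and keeps the raw moments well-conditioned.
    """

    def __init__(self, values: np.ndarray):
        x = np.asarray(values, dtype=float)
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        n, m = x.shape
        self.n, self.m = n, m
        x2 = x**2
        t = (x[:, :, None] * x[:, None, :]).reshape(n, m * m)
        t2 = (x2[:, :, None] * x[:, None, :]).reshape(n, m * m)
        t22 = (x2[:, :, None] * x2[:, None, :]).reshape(n, m * m)
        self.features = np.concatenate([x, x2, t, t2, t22], axis=1)
        self.total = self.features.sum(axis=0)

    def _unpack(self, s: np.ndarray):
        m = self.m
        b = s.shape[0]
        sx = s[:, :m]
        sx2 = s[:, m : 2 * m]
        off = 2 * m
        sxx = s[:, off : off + m * m].reshape(b, m, m)
        sx2x = s[:, off + m * m : off + 2 * m * m].reshape(b, m, m)
        sx2x2 = s[:, off + 2 * m * m :].reshape(b, m, m)
        return sx, sx2, sxx, sx2x, sx2x2

    def _pcor_from_moments(self, s: np.ndarray, ng: int) -> np.ndarray:
        m = self.m
        tr = np.arange(m)
        sx, sx2, sxx, sx2x, sx2x2 = self._unpack(s)
        mu = sx / ng
        # centered cross-products C_ij = sum (x_i - mu_i)(x_j - mu_j)
        c = sxx - ng * mu[:, :, None] * mu[:, None, :]
        var = c[:, tr, tr] / (ng - 1)
        sd = np.sqrt(var)
        denom = sd[:, :, None] * sd[:, None, :]
        r = c / ((ng - 1) * denom)
        # Q_ij = sum (x_i - mu_i)^2 (x_j - mu_j)^2 from raw moments
        mi = mu[:, :, None]
        mj = mu[:, None, :]
        q = (
            sx2x2
            + mj**2 * sx2[:, :, None]
            + mi**2 * sx2[:, None, :]
            - 3.0 * ng * mi**2 * mj**2
            - 2.0 * mj * sx2x
            - 2.0 * mi * sx2x.transpose(0, 2, 1)
            + 4.0 * mi * mj * sxx
        )
        w_sum = c / denom  # sum of standardized products w_kij
        w2_sum = q / denom**2
        var_r = ng / (ng - 1) ** 3 * (w2_sum - w_sum**2 / ng)
        num = var_r.sum(axis=(1, 2)) - var_r[:, tr, tr].sum(axis=1)
        r2 = r**2
        den = r2.sum(axis=(1, 2)) - r2[:, tr, tr].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(den > 0, np.clip(num / den, 0.0, 1.0), 1.0)
        u_star = (1.0 - lam)[:, None, None] * r
        u_star[:, tr, tr] = 1.0
        omega = np.linalg.inv(u_star)
        d = np.sqrt(omega[:, tr, tr])
        pcor = -omega / (d[:, :, None] * d[:, None, :])
        pcor = (pcor + pcor.transpose(0, 2, 1)) / 2.0
        pcor[:, tr, tr] = 1.0
        return pcor

    def split_pcor(self, sel: np.ndarray, n_first: int) -> tuple[np.ndarray, np.ndarray]:
        """Pcor matrices of a selected pseudo-group and its complement."""
        s_first = sel @ self.features
        s_second = self.total[None, :] - s_first
        return (
            self._pcor_from_moments(s_first, n_first),
            self._pcor_from_moments(s_second, self.n - n_first),
        )


def _null_chunks(
    values: np.ndarray,
    n_first: int,
    n_second: int,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int,
) -> Iterator[np.ndarray]:
    """Yield (b, K) blocks of permutation null statistics d*.

    The pseudo-group of size ``n_first`` (canonically the smaller group)
    is always the first block of each permuted index vector, which makes
    the draw invariant to swapping the observed group labels.
    """
    n, m = values.shape
    engine = _PermutationEngine(values)
    iu, ju = np.triu_indices(m, k=1)
    done = 0
    base = np.arange(n)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        sel = np.zeros((b, n))
        for row in range(b):
            sel[row, rng.permutation(base)[:n_first]] = 1.0
        pa, pb = engine.split_pcor(sel, n_first)
        dstar = np.abs(pa[:, iu, ju] - pb[:, iu, ju])
        yield dstar
        done += b


def permutation_null(
    data: GroupedDataset,
    n_perm: int,
    seed: int,
    chunk: int = 256,
) -> np.ndarray:
    """Null samples of d* = |r*_A - r*_B| per pair under label permutation.

    Returns an (n_perm, K) array; row order follows the permutation
    stream of ``numpy.random.default_rng(seed)`` (PCG64).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be a positive integer, got {n_perm}")
    sizes = data.group_sizes
    n_a, n_b = (sizes[lab] for lab in data.levels)
    n_first, n_second = min(n_a, n_b), max(n_a, n_b)
    rng = np.random.default_rng(seed)
    blocks = list(
        _null_chunks(data.values, n_first, n_second, n_perm, rng, chunk)
    )
    return np.concatenate(blocks, axis=0)


def permutation_pvalues(d_obs: np.ndarray, null_samples: np.ndarray) -> np.ndarray:
    """Add-one permutation p-values, p = (1 + #{d* >= d_obs}) / (1 + B)."""
    d_obs = np.asarray(d_obs, dtype=float)
    null_samples = np.atleast_2d(np.asarray(null_samples, dtype=float))
    if null_samples.shape[0] < 1:
        raise ValueError("need at least one null sample per pair")
    b = null_samples.shape[0]
    count = (null_samples >= d_obs[None, :]).sum(axis=0)
    return (1.0 + count) / (1.0 + b)


def classify_change(
    r_a: float, r_b: float, significant: bool, min_magnitude: float = 0.05
) -> str:
    """Change category of one pair relative to the reference group A.

    ``sign_change`` requires opposite signs with both magnitudes at least
    ``min_magnitude`` (noise-level sign flips are not sign changes);
    otherwise the magnitude of the correlation increased or decreased.
    """
    if not significant:
        return "none"
    if r_a * r_b < 0 and abs(r_a) >= min_magnitude and abs(r_b) >= min_magnitude:
        return "sign_change"
    return "increase" if abs(r_b) > abs(r_a) else "decrease"


def build_differential_network(
    data: GroupedDataset,
    n_perm: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
    min_magnitude: float = 0.05,
    bonferroni: bool = False,
    chunk: int = 256,
) -> DifferentialEdgeSet:
    """Full differential analysis of one two-group dataset.

    Fits both groups, runs the shared label-permutation null (streaming:
    null draws are counted, not stored), computes add-one p-values and
    classifies each pair.  The significance cut-off is the uncorrected
    ``alpha`` unless ``bonferroni`` is set, in which case alpha / K.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be a positive integer, got {n_perm}")
    group_a, group_b = data.levels
    fit_a = fit_group(data, group_a)
    fit_b = fit_group(data, group_b)
    m = data.n_variables
    iu, ju = np.triu_indices(m, k=1)
    r_a = fit_a.pcor[iu, ju]
    r_b = fit_b.pcor[iu, ju]
    d_obs = np.abs(r_a - r_b)

    sizes = data.group_sizes
    n_a, n_b = (sizes[lab] for lab in data.levels)
    n_first, n_second = min(n_a, n_b), max(n_a, n_b)
    rng = np.random.default_rng(seed)
    count = np.zeros(d_obs.shape[0], dtype=np.int64)
    for dstar in _null_chunks(data.values, n_first, n_second, n_perm, rng, chunk):
        count += (dstar >= d_obs[None, :]).sum(axis=0)
    p_perm = (1.0 + count) / (1.0 + n_perm)

    cutoff = bonferroni_threshold(alpha, len(d_obs)) if bonferroni else alpha
    names = data.variable_names
    categories = [
        classify_change(a, b, p <= cutoff, min_magnitude)
        for a, b, p in zip(r_a, r_b, p_perm)
    ]
    table = pd.DataFrame(
        {
            "variable_i": [names[i] for i in iu],
            "variable_j": [names[j] for j in ju],
            "r_A": r_a,
            "r_B": r_b,
            "d_obs": d_obs,
            "p_perm": p_perm,
            "category": categories,
        }
    )
    return DifferentialEdgeSet(
        table=table,
        nodes=list(names),
        group_a=group_a,
        group_b=group_b,
        n_permutations=n_perm,
        seed=seed,
        alpha=cutoff,
        min_magnitude=min_magnitude,
        lambda_a=fit_a.lambda_hat,
        lambda_b=fit_b.lambda_hat,
    )
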