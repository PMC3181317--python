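"""Two-group Gaussian graphical-model simulator with planted differences.

Generates samples x variables datasets that emulate a lipoprotein-panel
study: variables fall into blocks (subclasses) with a common within-block
partial correlation, optional cross-block edges, and two multivariate-
Gaussian groups whose precision matrices are identical except for a
chosen set of differential entries (increased, decreased or sign-flipped
partial correlations in group B relative to group A).

Partial correlations parameterize the precision matrix directly: with a
unit diagonal, Omega_ij = -pcor_ij.  If the requested pattern is not
positive definite it is repaired by diagonal inflation — the smallest
delta in {0, 0.05, 0.1, ...} with min eigenvalue >= 1e-6 is added to the
diagonal, then the matrix is re-standardized to unit diagonal.  Because
inflation attenuates off-diagonals, the *realized* partial correlations
are recomputed from the final matrix and are what tests should compare
against.  Gaussianity is the modeling assumption under which partial
correlation encodes conditional independence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .io import GroupedDataset

__all__ = [
    "SimulationSpec",
    "lipoprotein_panel_spec",
    "build_precision",
    "realized_partial_correlations",
    "sample_dataset",
]

_EIG_MIN = 1e-6
_DELTA_STEP = 0.05
_DELTA_MAX = 2.0


@dataclass
class SimulationSpec:
    """Declarative description of one two-group simulation.

    ``cross_block_edges`` is a list of ``[i, j, pcor]`` (shared by both
    groups); ``differential_edges`` is a list of ``[i, j, pcor_b,
    category]`` overriding the group-B value for that pair, with
    ``category`` recording the intended kind of change.  Indices are
    0-based variable positions.
    """

    block_sizes: list[int]
    within_block_pcor: float = 0.2
    cross_block_edges: list = field(default_factory=list)
    differential_edges: list = field(default_factory=list)
    n_a: int = 200
    n_b: int = 200
    seed: int = 0
    group_names: tuple[str, str] = ("A", "B")
    variable_names: list[str] | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if abs(self.within_block_pcor) >= 1:
            raise ValueError("|within_block_pcor| must be < 1")
        for entry in list(self.cross_block_edges) + [
            e[:3] for e in self.differential_edges
        ]:
            i, j, v = entry[0], entry[1], entry[2]
            if i == j or not (0 <= i < self.m) or not (0 <= j < self.m):
                raise ValueError(f"invalid pair ({i}, {j}) for M={self.m}")
            if abs(v) >= 1:
                raise ValueError(f"|pcor target| must be < 1, got {v}")
        if self.variable_names is None:
            names = []
            for b, size in enumerate(self.block_sizes):
                for k in range(size):
                    names.append(f"B{b + 1:02d}V{k + 1}")
            self.variable_names = names
        if len(self.variable_names) != self.m:
            raise ValueError("variable_names length must equal M")

    @property
    def m(self) -> int:
        return int(sum(self.block_sizes))

    # -- (de)serialization ------------------------------------------------

    def to_yaml(self, path: str | os.PathLike) -> None:
        payload = {
            "block_sizes": list(self.block_sizes),
            "within_block_pcor": self.within_block_pcor,
            "cross_block_edges": [list(e) for e in self.cross_block_edges],
            "differential_edges": [list(e) for e in self.differential_edges],
            "n_a": self.n_a,
            "n_b": self.n_b,
            "seed": self.seed,
            "group_names": list(self.group_names),
            "variable_names": list(self.variable_names),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["group_names"] = tuple(payload.get("group_names", ("A", "B")))
        return cls(**payload)


def lipoprotein_panel_spec(**overrides) -> SimulationSpec:
    """Default 60-variable panel: 14 blocks of 4-5 correlated measures.

    Mirrors a 14-subclass lipoprotein panel with ~4 measures per
    subclass.  Within-block partial correlation 0.2 keeps every block
    positive definite without repair; a sparse set of cross-block edges
    links adjacent subclasses (the lipoprotein cascade).
    """
    block_sizes = [5, 4, 4, 4, 5, 4, 4, 4, 5, 4, 4, 4, 5, 4]
    starts = np.cumsum([0] + block_sizes[:-1])
    cross = []
    for b in range(len(block_sizes) - 1):
        sign = 1.0 if b % 2 == 0 else -1.0
        cross.append([int(starts[b]), int(starts[b + 1]), sign * 0.15])
    defaults = dict(
        block_sizes=block_sizes,
        within_block_pcor=0.2,
        cross_block_edges=cross,
    )
    defaults.update(overrides)
    return SimulationSpec(**defaults)


def _pcor_pattern(spec: SimulationSpec, group: str) -> np.ndarray:
    if group not in ("A", "B"):
        raise ValueError("group must be 'A' or 'B'")
    m = spec.m
    p = np.zeros((m, m))
    start = 0
    for size in spec.block_sizes:
        p[start : start + size, start : start + size] = spec.within_block_pcor
        start += size
    for i, j, v in spec.cross_block_edges:
        p[i, j] = p[j, i] = v
    if group == "B":
        for entry in spec.differential_edges:
            i, j, v = entry[0], entry[1], entry[2]
            p[i, j] = p[j, i] = v
    np.fill_diagonal(p, 0.0)
    return p


def build_precision(spec: SimulationSpec, group: str) -> np.ndarray:
    """Precision matrix realizing the requested partial-correlation pattern.

    Unit-diagonal start (Omega_ij = -pcor_ij), diagonal inflation until
    positive definite, then re-standardization to unit diagonal.  Raises
    when no inflation up to delta = 2 achieves positive definiteness.
    """
    p = _pcor_pattern(spec, group)
    omega = np.eye(spec.m) - p
    eig_min = float(np.linalg.eigvalsh(omega)[0])
    delta = 0.0
    while eig_min < _EIG_MIN:
        delta += _DELTA_STEP
        if delta > _DELTA_MAX:
            raise ValueError(
                "requested partial-correlation pattern cannot be made "
                f"positive definite (inflation cap delta > {_DELTA_MAX})"
            )
        eig_min = float(
            np.linalg.eigvalsh(omega + delta * np.eye(spec.m))[0]
        )
    omega = omega + delta * np.eye(spec.m)
    d = np.sqrt(np.diag(omega))
    omega = omega / np.outer(d, d)
    return (omega + omega.T) / 2.0


def realized_partial_correlations(spec: SimulationSpec, group: str) -> np.ndarray:
    """Partial correlations actually implied by the constructed precision."""
    omega = build_precision(spec, group)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def sample_dataset(spec: SimulationSpec) -> GroupedDataset:
    """Draw the two-group dataset described by ``spec``.

    Zero-mean Gaussians with covariance = inverse precision; rows are
    group A first then group B; fully reproducible from ``spec.seed``.
    """
    if spec.n_a < 2 or spec.n_b < 2:
        raise ValueError("both group sizes must be at least 2")
    rng = np.random.default_rng(spec.seed)
    blocks = []
    labels = []
    for group, n in zip(("A", "B"), (spec.n_a, spec.n_b)):
        omega = build_precision(spec, group)
        cov = np.linalg.inv(omega)
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((n, spec.m))
        blocks.append(z @ chol.T)
        labels.extend([spec.group_names[0 if group == "A" else 1]] * n)
    return GroupedDataset(
        np.vstack(blocks),
        list(spec.variable_names),
        np.array(labels, dtype=object),
    )
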