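"""Grouped concentration tables and network serialization.

The central container is :class:`GroupedDataset`: a samples x variables
matrix of metabolite (e.g. lipoprotein subclass) concentrations together
with a two-level group label per sample, such as normal vs impaired
fasting glucose.  Networks are serialized as GraphML (via networkx) or as
plain TSV edge tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GroupedDataset",
    "read_grouped_table",
    "write_grouped_table",
    "write_network",
    "read_network_graphml",
    "read_edge_table",
    "PAIR_SEPARATOR",
]

#: Separator used in the "pair" column of TSV edge tables.  Variable names
#: must not contain it.
PAIR_SEPARATOR = "--"


@dataclass
class GroupedDataset:
    """Samples x variables matrix with a binary group label per sample.

    Parameters
    ----------
    values
        Real-valued matrix, one row per sample and one column per variable.
    variable_names
        Unique identifiers for the ``M`` columns; the column order of the
        source file is the canonical node ordering everywhere downstream.
    group_labels
        One label per row, drawn from exactly two levels.  The first level
        in order of appearance is the reference group (group A) for all
        downstream comparisons.
    n_dropped
        Number of raw rows removed for missing values during loading.
    """

    values: np.ndarray
    variable_names: list[str]
    group_labels: np.ndarray
    n_dropped: int = 0
    levels: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        self.variable_names = [str(v) for v in self.variable_names]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d samples x variables matrix")
        n, m = self.values.shape
        if len(self.variable_names) != m:
            raise ValueError(
                f"{len(self.variable_names)} variable names for {m} columns"
            )
        if len(set(self.variable_names)) != m:
            raise ValueError("variable names must be unique")
        if self.group_labels.shape != (n,):
            raise ValueError("one group label required per sample row")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries after loading")
        seen: list[str] = []
        for lab in self.group_labels:
            if lab not in seen:
                seen.append(lab)
        if len(seen) != 2:
            raise ValueError(
                f"expected exactly two groups, found {len(seen)}: {seen}"
            )
        self.levels = (seen[0], seen[1])
        for lab in self.levels:
            if int(np.sum(self.group_labels == lab)) < 2:
                raise ValueError(f"group {lab!r} has fewer than 2 samples")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        """M, the number of measured variables."""
        return self.values.shape[1]

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            lab: int(np.sum(self.group_labels == lab)) for lab in self.levels
        }

    @property
    def n_pairs(self) -> int:
        """K = M(M-1)/2, the number of unordered variable pairs."""
        m = self.n_variables
        return m * (m - 1) // 2

    def values_for(self, group: str) -> np.ndarray:
        if group not in self.levels:
            raise ValueError(
                f"unknown group {group!r}; dataset has groups {self.levels}"
            )
        return self.values[self.group_labels == group]

    def log_transformed(self) -> "GroupedDataset":
        """Natural-log transform of all concentrations (requires positivity)."""
        if np.any(self.values <= 0):
            raise ValueError("log transform requires strictly positive values")
        return GroupedDataset(
            np.log(self.values),
            list(self.variable_names),
            self.group_labels.copy(),
            n_dropped=self.n_dropped,
        )


def read_grouped_table(
    path: str | os.PathLike,
    group_column: str,
    delimiter: str = "\t",
) -> GroupedDataset:
    """Load a delimited text table into a :class:`GroupedDataset`.

    Rows with any missing entry are dropped (complete-case deletion) and
    counted in ``n_dropped``.  All non-group columns must be numeric or
    coercible to numeric.
    """
    df = pd.read_csv(path, sep=delimiter)
    if group_column not in df.columns:
        raise ValueError(f"group column {group_column!r} not found in {path}")
    value_cols = [c for c in df.columns if c != group_column]
    if not value_cols:
        raise ValueError("table has no variable columns besides the group")
    numeric = {}
    for col in value_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        # entries that were non-missing but failed coercion => non-numeric col
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(f"non-numeric values in variable column {col!r}")
        numeric[col] = coerced
    values = pd.DataFrame(numeric)
    keep = ~(values.isna().any(axis=1) | df[group_column].isna())
    n_dropped = int((~keep).sum())
    return GroupedDataset(
        values.loc[keep].to_numpy(dtype=float),
        value_cols,
        df.loc[keep, group_column].astype(str).to_numpy(dtype=object),
        n_dropped=n_dropped,
    )


def write_grouped_table(
    data: GroupedDataset,
    path: str | os.PathLike,
    group_column: str = "group",
    delimiter: str = "\t",
) -> None:
    df = pd.DataFrame(data.values, columns=data.variable_names)
    df.insert(0, group_column, data.group_labels)
    df.to_csv(path, sep=delimiter, index=False)


# -- network serialization ----------------------------------------------


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    if hasattr(network, "to_networkx"):
        return network.to_networkx()
    raise TypeError(f"cannot serialize object of type {type(network).__name__}")


def write_network(network, path: str | os.PathLike, format: str = "graphml") -> None:
    """Write a network as GraphML or as a TSV edge table.

    GraphML preserves isolated nodes and all edge attributes and
    round-trips through :func:`read_network_graphml`.  The edge-table
    format has columns ``pair`` (``"a--b"``), ``statistic``, ``p_value``
    and ``annotation`` plus any extra edge attributes.
    """
    graph = _as_graph(network)
    if len(graph) == 0:
        raise ValueError("refusing to write a network with an empty node set")
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edge-table":
        rows = []
        for u, v, attrs in graph.edges(data=True):
            row = {
                "pair": f"{u}{PAIR_SEPARATOR}{v}",
                "statistic": attrs.get("statistic", attrs.get("pcor", np.nan)),
                "p_value": attrs.get("p_value", np.nan),
                "annotation": attrs.get("annotation", attrs.get("category", "")),
            }
            for key, val in attrs.items():
                if key not in ("statistic", "pcor", "p_value", "annotation", "category"):
                    row[key] = val
            rows.append(row)
        cols = ["pair", "statistic", "p_value", "annotation"]
        table = pd.DataFrame(rows, columns=cols if not rows else None)
        if rows:
            table = table[cols + [c for c in table.columns if c not in cols]]
        table.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path: str | os.PathLike) -> nx.Graph:
    return nx.read_graphml(path)


def read_edge_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV edge table, splitting ``pair`` into variable_i/variable_j."""
    df = pd.read_csv(path, sep="\t")
    if "pair" not in df.columns:
        raise ValueError(f"{path} is not an edge table (no 'pair' column)")
    split = df["pair"].str.split(PAIR_SEPARATOR, n=1, expand=True)
    df.insert(0, "variable_i", split[0])
    df.insert(1, "variable_j", split[1])
    return df
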