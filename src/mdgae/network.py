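"""Bipartite metabolite-disease association networks.

An association network is a two-partition graph: metabolites on one side,
diseases on the other, with an edge wherever a metabolite has been observed
in association with a disease.  It is stored as a dense binary adjacency
matrix ``A`` with one row per metabolite and one column per disease; unknown
pairs are 0 and are the candidate negatives for link prediction.

The on-disk exchange format is a strict two-column TSV edge list with header
``metabolite_id<TAB>disease_id``, one association per row, UTF-8.  Identifiers
are deduplicated and sorted lexicographically on load so matrix indices are
reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssociationNetwork",
    "EmptyNetworkError",
    "EdgeListFormatError",
    "read_edge_list",
    "write_edge_list",
    "node_degrees",
]


class EmptyNetworkError(ValueError):
    """Raised when an edge list contains no associations."""


class EdgeListFormatError(ValueError):
    """Raised when an edge-list file violates the TSV contract."""


@dataclass(frozen=True)
class AssociationNetwork:
    """A binary bipartite association network.

    Parameters
    ----------
    metabolite_ids
        Unique metabolite identifiers; row labels of ``adjacency``.
    disease_ids
        Unique disease identifiers; column labels of ``adjacency``.
    adjacency
        Binary matrix of shape ``(U, V)``; entry ``(i, j)`` is 1 iff
        metabolite ``i`` is associated with disease ``j``.
    """

    metabolite_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2:
            raise ValueError("adjacency must be a 2-D matrix")
        if adj.shape != (len(self.metabolite_ids), len(self.disease_ids)):
            raise ValueError(
                f"adjacency shape {adj.shape} does not match "
                f"({len(self.metabolite_ids)}, {len(self.disease_ids)}) identifiers"
            )
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ValueError("duplicate metabolite identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        object.__setattr__(self, "adjacency", adj.astype(np.int8, copy=False))
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "disease_ids", tuple(self.disease_ids))

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edge_index_pairs(self) -> np.ndarray:
        """Observed edges as an ``(n_edges, 2)`` array of (row, col) indices."""
        return np.argwhere(self.adjacency == 1)

    def with_adjacency(self, adjacency: np.ndarray) -> "AssociationNetwork":
        """A copy of this network with a different adjacency matrix."""
        return AssociationNetwork(self.metabolite_ids, self.disease_ids, adjacency)

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite identifier: {metabolite_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease identifier: {disease_id!r}") from None


def read_edge_list(path) -> AssociationNetwork:
    """Load an association network from a two-column TSV edge list.

    The file must have header columns ``metabolite_id`` and ``disease_id``.
    Identifiers are deduplicated and sorted lexicographically; repeated edges
    collapse to a single association.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    EdgeListFormatError
        If the header is wrong or an identifier field is blank.
    EmptyNetworkError
        If the file contains a header but no associations.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EdgeListFormatError(f"{path}: no header row") from None
    required = ["metabolite_id", "disease_id"]
    if list(frame.columns[:2]) != required:
        raise EdgeListFormatError(
            f"{path}: expected header columns {required}, got {list(frame.columns)}"
        )
    if len(frame) == 0:
        raise EmptyNetworkError(f"{path}: edge list contains no associations")
    if (frame["metabolite_id"].str.strip() == "").any() or (
        frame["disease_id"].str.strip() == ""
    ).any():
        raise EdgeListFormatError(f"{path}: blank identifier field")

    metabolite_ids = tuple(sorted(frame["metabolite_id"].unique()))
    disease_ids = tuple(sorted(frame["disease_id"].unique()))
    m_index = {m: i for i, m in enumerate(metabolite_ids)}
    d_index = {d: j for j, d in enumerate(disease_ids)}
    adjacency = np.zeros((len(metabolite_ids), len(disease_ids)), dtype=np.int8)
    adjacency[
        frame["metabolite_id"].map(m_index).to_numpy(),
        frame["disease_id"].map(d_index).to_numpy(),
    ] = 1
    return AssociationNetwork(metabolite_ids, disease_ids, adjacency)


def write_edge_list(network: AssociationNetwork, path) -> None:
    """Write a network as a TSV edge list; inverse of :func:`read_edge_list`.

    Raises :class:`EmptyNetworkError` for a network with no edges, keeping the
    writer consistent with the reader (a header-only file cannot round-trip).
    """
    edges = network.edge_index_pairs()
    if len(edges) == 0:
        raise EmptyNetworkError("refusing to write a network with no associations")
    frame = pd.DataFrame(
        {
            "metabolite_id": [network.metabolite_ids[i] for i, _ in edges],
            "disease_id": [network.disease_ids[j] for _, j in edges],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def node_degrees(network: AssociationNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-node association counts.

    Returns ``(metabolite_degrees, disease_degrees)``: row sums and column
    sums of the adjacency.  Both vectors sum to the edge count.  These are the
    regression targets of the degree decoder.
    """
    adj = network.adjacency
    return adj.sum(axis=1).astype(np.int64), adj.sum(axis=0).astype(np.int64)
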