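"""Assembly of the heterogeneous miRNA-disease network (RDnet).

The network is an undirected weighted graph over miRNA vertices followed by
disease vertices. Its weight matrix is the symmetric block matrix

    W = [[ MM'  A  ],
         [ A^T  DD' ]]

where MM' and DD' are the similarity matrices with off-diagonals below the
threshold tau zeroed and the diagonal removed (no self-loops), and A is the
binary association matrix: A[i, j] = 1 iff miRNA i is known to be associated
with disease j, 0 otherwise. Association edges carry weight 1; similarity
edges carry their similarity score.

The random walk moves along an edge with probability proportional to its
weight, so the transition operator is the row normalization of W. A vertex
with no surviving edges keeps the walker in place (self-transition 1), which
preserves row-stochasticity without introducing teleportation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationSet, SimilarityMatrix

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class BinaryAssociationMatrix:
    """0/1 matrix of known associations, rows = miRNAs, columns = diseases."""

    values: np.ndarray
    mirna_labels: tuple[str, ...]
    disease_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.mirna_labels), len(self.disease_labels)):
            raise ValueError("association matrix shape does not match labels")
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class HeteroNetwork:
    """The combined weighted graph G = (V, E, W) with its transition operator.

    Vertices are ordered miRNAs first, diseases second. ``transition`` is
    row-stochastic: transition[u, v] = W[u, v] / sum_v' W[u, v'].
    """

    mirna_labels: tuple[str, ...]
    disease_labels: tuple[str, ...]
    weight_matrix: np.ndarray
    transition: np.ndarray
    threshold: float

    @property
    def node_labels(self) -> tuple[str, ...]:
        return self.mirna_labels + self.disease_labels

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_labels)

    @property
    def n_disease(self) -> int:
        return len(self.disease_labels)

    @property
    def n_nodes(self) -> int:
        return self.n_mirna + self.n_disease

    def node_index(self, label: str) -> int:
        """Index of a node label in the combined ordering; raises KeyError."""
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label: {label!r}") from None


def build_association_matrix(
    assoc: AssociationSet,
    mirna_labels: tuple[str, ...] | list[str],
    disease_labels: tuple[str, ...] | list[str],
) -> BinaryAssociationMatrix:
    """Materialize the binary association matrix over the given label orders.

    Every association id must appear in the corresponding label list; an
    unknown id raises a ValueError naming it.
    """
    mirna_labels = tuple(mirna_labels)
    disease_labels = tuple(disease_labels)
    m_index = {m: i for i, m in enumerate(mirna_labels)}
    d_index = {d: j for j, d in enumerate(disease_labels)}
    values = np.zeros((len(mirna_labels), len(disease_labels)))
    for m, d in assoc.pairs:
        if m not in m_index:
            raise ValueError(f"miRNA id {m!r} not in the miRNA label list")
        if d not in d_index:
            raise ValueError(f"disease id {d!r} not in the disease label list")
        values[m_index[m], d_index[d]] = 1.0
    return BinaryAssociationMatrix(values, mirna_labels, disease_labels)


def apply_similarity_threshold(S: SimilarityMatrix, tau: float) -> SimilarityMatrix:
    """Zero off-diagonal similarities strictly below ``tau``.

    Two nodes are linked only if their similarity reaches the threshold; the
    diagonal is untouched here (it is removed later during network assembly).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    values = S.values.copy()
    off = ~np.eye(S.n, dtype=bool)
    values[off & (values < tau)] = 0.0
    return SimilarityMatrix(labels=S.labels, values=values)


def build_hetero_network(
    MM: SimilarityMatrix,
    DD: SimilarityMatrix,
    A: BinaryAssociationMatrix,
    tau: float = 0.0,
) -> HeteroNetwork:
    """Assemble RDnet from the two similarity blocks and the association block.

    Parameters
    ----------
    MM, DD
        miRNA-miRNA functional similarity and disease-disease phenotype
        similarity matrices; their label orders define the vertex order.
    A
        Binary association matrix whose row/column labels must match MM/DD.
    tau
        Similarity threshold in [0, 1]; off-diagonal similarities below tau
        are dropped before the blocks are combined. Default 0 keeps every
        positive similarity edge.
    """
    if A.mirna_labels != MM.labels:
        raise ValueError("association matrix rows do not match miRNA labels")
    if A.disease_labels != DD.labels:
        raise ValueError("association matrix columns do not match disease labels")

    mm = apply_similarity_threshold(MM, tau).values.copy()
    dd = apply_similarity_threshold(DD, tau).values.copy()
    np.fill_diagonal(mm, 0.0)
    np.fill_diagonal(dd, 0.0)

    n_m, n_d = MM.n, DD.n
    W = np.zeros((n_m + n_d, n_m + n_d))
    W[:n_m, :n_m] = mm
    W[n_m:, n_m:] = dd
    W[:n_m, n_m:] = A.values
    W[n_m:, :n_m] = A.values.T

    if not W.any():
        raise ValueError("empty network: no edges survive the threshold")

    row_sums = W.sum(axis=1)
    T = np.zeros_like(W)
    connected = row_sums > 0
    T[connected] = W[connected] / row_sums[connected, None]
    # isolated vertices keep the walker in place
    idx = np.flatnonzero(~connected)
    T[idx, idx] = 1.0
    assert np.allclose(T.sum(axis=1), 1.0, atol=_ROW_SUM_TOL, rtol=0)

    return HeteroNetwork(
        mirna_labels=MM.labels,
        disease_labels=DD.labels,
        weight_matrix=W,
        transition=T,
        threshold=tau,
    )
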