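"""Shared fixtures: small hand-built networks used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from mirdwalk.data_io import AssociationSet, SimilarityMatrix
from mirdwalk.rdnet import build_association_matrix, build_hetero_network


def make_similarity(labels, edges, value=0.8):
    """Similarity matrix with unit diagonal and the given off-diagonal edges."""
    labels = tuple(labels)
    n = len(labels)
    m = np.zeros((n, n))
    np.fill_diagonal(m, 1.0)
    idx = {l: i for i, l in enumerate(labels)}
    for a, b in edges:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = value
    return SimilarityMatrix(labels, m)


def random_network(rng, max_mirna=12, max_disease=8):
    """A random valid heterogeneous network plus its association set."""
    n_m = int(rng.integers(2, max_mirna + 1))
    n_d = int(rng.integers(1, max_disease + 1))
    mir = tuple(f"m{i:02d}" for i in range(n_m))
    dis = tuple(f"d{i:02d}" for i in range(n_d))

    def sym(n):
        v = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
        v = np.triu(v, 1)
        v = v + v.T
        np.fill_diagonal(v, 1.0)
        return v

    MM = SimilarityMatrix(mir, sym(n_m))
    DD = SimilarityMatrix(dis, sym(n_d))
    a = (rng.random((n_m, n_d)) < 0.4).astype(float)
    if not a.any():
        a[0, 0] = 1.0  # guarantee the network has at least one edge
    pairs = frozenset(
        (mir[i], dis[j]) for i, j in zip(*np.nonzero(a))
    )
    assoc = AssociationSet(pairs, mir, dis)
    A = build_association_matrix(assoc, mir, dis)
    return build_hetero_network(MM, DD, A), assoc


TOY_MIRNAS = ("m1", "m2", "m3", "m4", "m5")
TOY_DISEASES = ("d1", "d2", "d3", "d4", "d5")
TOY_ASSOCIATIONS = {("m5", "d1"), ("m3", "d1"), ("m2", "d3"), ("m2", "d4")}
TOY_SIM_EDGES = [
    ("m5", "m1"), ("m5", "m3"), ("m5", "m4"), ("m2", "m1"), ("m2", "m3"),
]


@pytest.fixture(scope="session")
def toy_network():
    """Five-miRNA / five-disease worked example network.

    The miRNA similarity edges and association edges form walk paths from the
    query diseases to their illustrated candidate miRNAs (d1 -> m4 via m5,
    d3 -> m3 via m2).
    """
    MM = make_similarity(TOY_MIRNAS, TOY_SIM_EDGES)
    DD = make_similarity(TOY_DISEASES, [])
    assoc = AssociationSet(frozenset(TOY_ASSOCIATIONS), TOY_MIRNAS, TOY_DISEASES)
    A = build_association_matrix(assoc, TOY_MIRNAS, TOY_DISEASES)
    network = build_hetero_network(MM, DD, A)
    return MM, DD, assoc, network
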