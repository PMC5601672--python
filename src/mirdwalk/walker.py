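"""Random walk with restart over RDnet and candidate ranking.

For a query disease d the walker is seeded uniformly over d's known
associated miRNAs and iterated to its stationary distribution under

    p_{t+1} = (1 - M) * T^T @ p_t + M * p0

where T is the row-stochastic transition matrix of the network and M is the
restart probability. Because T is row-stochastic the update conserves total
probability exactly, and for M > 0 it is a contraction with factor (1 - M)
in the L1 norm, so the fixed point

    p = M * (I - (1 - M) * T^T)^{-1} @ p0

is unique and the iteration converges geometrically. The steady-state
occupancy at each miRNA node not already known to be associated with d is
that candidate's relevancy score; candidates are ranked by score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationSet
from .rdnet import HeteroNetwork

logger = logging.getLogger(__name__)


class NoSeedError(ValueError):
    """Query disease has no known associated miRNA to seed the walk from."""


@dataclass(frozen=True)
class WalkConfig:
    """Tunable parameters of the restart walk.

    M is the restart probability in (0, 1]; the model performs best around
    M = 0.7 and the useful range is 0.1-0.9. epsilon is the L1 tolerance on
    successive iterates; with contraction factor (1 - M) the default budget
    of 1000 iterations is ample for any M >= 0.1.
    """

    M: float = 0.7
    epsilon: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.M <= 1.0:
            raise ValueError(f"M must be in (0, 1], got {self.M}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass(frozen=True)
class ScoreVector:
    """Per-node occupancy probabilities (miRNAs first, then diseases).

    ``residuals`` records the L1 distance between successive iterates, one
    entry per iteration performed.
    """

    values: np.ndarray
    iterations_used: int = 0
    converged: bool = True
    residuals: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v < 0):
            raise ValueError("score vector has negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"score vector sums to {v.sum()}, not 1")


@dataclass(frozen=True)
class RankedList:
    """Ordered (mirna_id, score, rank) triples, scores non-increasing.

    Ties are broken by lexicographic miRNA id so rankings are deterministic.
    """

    entries: tuple[tuple[str, float, int], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s, _ in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranked-list scores must be non-increasing")
        if [r for _, _, r in self.entries] != list(range(1, len(scores) + 1)):
            raise ValueError("ranks must be 1..n")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def scores(self) -> dict[str, float]:
        return {m: s for m, s, _ in self.entries}

    def top(self, k: int) -> list[str]:
        return [m for m, _, _ in self.entries[:k]]


def seed_vector(
    disease_id: str, assoc: AssociationSet, network: HeteroNetwork
) -> ScoreVector:
    """Uniform seed distribution over the query disease's known miRNAs.

    Probability 1/k on each of the k miRNAs known-associated with
    ``disease_id``; zero everywhere else, including all disease nodes.
    Raises :class:`NoSeedError` for a disease with no known miRNA (this
    method does not extend to such diseases).
    """
    if disease_id not in network.disease_labels:
        raise KeyError(f"unknown disease id: {disease_id!r}")
    known = assoc.mirnas_for(disease_id) & set(network.mirna_labels)
    if not known:
        raise NoSeedError(
            f"no seed: disease {disease_id!r} has no known associated miRNA"
        )
    p0 = np.zeros(network.n_nodes)
    for m in known:
        p0[network.node_index(m)] = 1.0 / len(known)
    return ScoreVector(values=p0)


def random_walk(
    network: HeteroNetwork, p0: ScoreVector, config: WalkConfig | None = None
) -> ScoreVector:
    """Iterate the restart walk to its stationary distribution.

    Stops when the L1 distance between successive iterates drops below
    ``config.epsilon`` or after ``config.max_iter`` iterations; in the latter
    case the result is returned with ``converged=False`` and a warning
    rather than an exception (with M > 0 the map is a contraction, so
    non-convergence signals a tolerance/iteration misconfiguration, not an
    invalid state).
    """
    if config is None:
        config = WalkConfig()
    Tt = network.transition.T
    M = config.M
    p = p0.values
    residuals: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        p_next = (1.0 - M) * (Tt @ p) + M * p0.values
        diff = float(np.abs(p_next - p).sum())
        residuals.append(diff)
        p = p_next
        if diff < config.epsilon:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"random walk did not converge in {config.max_iter} iterations "
            f"(last residual {residuals[-1]:.3g})",
            stacklevel=2,
        )
    # guard against float drift before the normalization invariant check
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    return ScoreVector(
        values=p,
        iterations_used=len(residuals),
        converged=converged,
        residuals=tuple(residuals),
    )


def rank_candidates(
    steady: ScoreVector,
    disease_id: str,
    training_assoc: AssociationSet,
    network: HeteroNetwork,
) -> RankedList:
    """Rank unknown miRNAs of the query disease by steady-state score.

    miRNAs already known-associated with ``disease_id`` in the training set
    are excluded; the rest are sorted by score descending, ties broken by
    lexicographic id. Scores are read at miRNA nodes only.
    """
    known = training_assoc.mirnas_for(disease_id)
    mirna_scores = steady.values[: network.n_mirna]
    candidates = [
        (m, float(mirna_scores[i]))
        for i, m in enumerate(network.mirna_labels)
        if m not in known
    ]
    if not candidates:
        warnings.warn(
            f"no candidate miRNAs remain for disease {disease_id!r}",
            stacklevel=2,
        )
        return RankedList(entries=())
    candidates.sort(key=lambda t: (-t[1], t[0]))
    return RankedList(
        entries=tuple((m, s, r) for r, (m, s) in enumerate(candidates, start=1))
    )


def score_disease(
    network: HeteroNetwork,
    disease_id: str,
    assoc: AssociationSet,
    config: WalkConfig | None = None,
) -> RankedList:
    """Seed, walk, and rank in one call for a single query disease."""
    p0 = seed_vector(disease_id, assoc, network)
    steady = random_walk(network, p0, config)
    if not steady.converged:
        logger.warning("walk for %s stopped before convergence", disease_id)
    return rank_candidates(steady, disease_id, assoc, network)


def sweep_M(
    network: HeteroNetwork,
    disease_id: str,
    assoc: AssociationSet,
    grid: list[float] | tuple[float, ...],
    epsilon: float = 1e-10,
    max_iter: int = 1000,
) -> list[tuple[float, RankedList]]:
    """One ranking per restart probability on the grid, same seeds throughout."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty M grid")
    out = []
    for M in grid:
        config = WalkConfig(M=M, epsilon=epsilon, max_iter=max_iter)
        out.append((M, score_disease(network, disease_id, assoc, config)))
    return out
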