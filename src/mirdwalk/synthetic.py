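"""Synthetic heterogeneous networks with planted module structure.

The generator encodes the modeling hypothesis behind the method — miRNAs
with similar functions tend to associate with a common disease — as a
planted block model. miRNAs and diseases are assigned round-robin to
``n_modules`` modules, miRNA module i is matched one-to-one with disease
module i, similarities are drawn from clipped normals with a higher mean
inside modules than between them, and associations are Bernoulli with
probability ``p_in`` for matched module pairs and ``p_out`` otherwise.

Because module membership is the ground truth, the generator makes the
whole pipeline testable offline: a good ranker queried with a disease
should place the unobserved matched-module miRNAs (the discoverable
positives) above cross-module miRNAs.

The default configuration is the benchmark used throughout the test suite:
100 miRNAs, 20 diseases, 4 modules, within/between similarity 0.6/0.1 with
noise sd 0.05, association probabilities 0.5/0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import (
    AssociationSet,
    SimilarityMatrix,
    write_association_table,
    write_similarity_matrix,
)
from .rdnet import BinaryAssociationMatrix


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the planted-module generator.

    ``sim_in``/``sim_out`` are the mean similarities within/between modules
    (must satisfy sim_in >= sim_out; equality gives the signal-free null),
    ``sim_noise`` the sd of the clipped-normal similarity noise, and
    ``p_in``/``p_out`` the association probabilities for matched/unmatched
    module pairs (p_in >= p_out, equality again the null).
    """

    n_mirna: int = 100
    n_disease: int = 20
    n_modules: int = 4
    sim_in: float = 0.6
    sim_out: float = 0.1
    sim_noise: float = 0.05
    p_in: float = 0.5
    p_out: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if min(self.n_mirna, self.n_disease) < self.n_modules:
            raise ValueError(
                f"need at least {self.n_modules} miRNAs and diseases "
                f"for {self.n_modules} modules"
            )
        for name in ("sim_in", "sim_out", "p_in", "p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sim_in < self.sim_out:
            raise ValueError("sim_in must be >= sim_out")
        if self.p_in < self.p_out:
            raise ValueError("p_in must be >= p_out")
        if self.sim_noise < 0:
            raise ValueError("sim_noise must be nonnegative")


def _labels(prefix: str, n: int) -> tuple[str, ...]:
    width = max(len(str(n - 1)), 2)
    return tuple(f"{prefix}{i:0{width}d}" for i in range(n))


def _modules(n: int, n_modules: int) -> np.ndarray:
    return np.arange(n) % n_modules


def _block_similarity(
    rng: np.random.Generator, modules: np.ndarray, cfg: SynthConfig
) -> np.ndarray:
    n = modules.size
    same = modules[:, None] == modules[None, :]
    means = np.where(same, cfg.sim_in, cfg.sim_out)
    values = rng.normal(means, cfg.sim_noise) if cfg.sim_noise > 0 else means.copy()
    values = np.clip(values, 0.0, 1.0)
    upper = np.triu(values, k=1)
    values = upper + upper.T        # exact symmetry from the upper triangle
    np.fill_diagonal(values, 1.0)
    return values


def simulate_rdnet(
    config: SynthConfig,
) -> tuple[SimilarityMatrix, SimilarityMatrix, AssociationSet, BinaryAssociationMatrix]:
    """Generate (MM, DD, observed associations, ground-truth matrix).

    Fully reproducible from ``config.seed``. The truth matrix marks every
    matched-module (miRNA, disease) pair with 1, i.e. the pairs the planted
    structure says are real, whether observed or not.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mirna_labels = _labels("mir-", cfg.n_mirna)
    disease_labels = _labels("dis-", cfg.n_disease)
    m_mod = _modules(cfg.n_mirna, cfg.n_modules)
    d_mod = _modules(cfg.n_disease, cfg.n_modules)

    MM = SimilarityMatrix(mirna_labels, _block_similarity(rng, m_mod, cfg))
    DD = SimilarityMatrix(disease_labels, _block_similarity(rng, d_mod, cfg))

    matched = m_mod[:, None] == d_mod[None, :]
    probs = np.where(matched, cfg.p_in, cfg.p_out)
    observed = rng.random((cfg.n_mirna, cfg.n_disease)) < probs
    pairs = frozenset(
        (mirna_labels[i], disease_labels[j])
        for i, j in zip(*np.nonzero(observed))
    )
    if not pairs:
        raise ValueError(
            "generator produced no associations; raise p_in/p_out or sizes"
        )
    assoc = AssociationSet(
        pairs=pairs, mirna_labels=mirna_labels, disease_labels=disease_labels
    )
    truth = BinaryAssociationMatrix(
        values=matched.astype(float),
        mirna_labels=mirna_labels,
        disease_labels=disease_labels,
    )
    return MM, DD, assoc, truth


def holdout_truth(
    truth: BinaryAssociationMatrix, observed: AssociationSet
) -> dict[str, tuple[frozenset[str], frozenset[str]]]:
    """Per-disease discoverable positives and true negatives.

    For each disease: positives are the matched-module miRNAs whose
    association was *not* observed (what a perfect ranker should surface),
    negatives are the unmatched-module miRNAs not observed either.
    """
    out: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    for j, d in enumerate(truth.disease_labels):
        seen = observed.mirnas_for(d)
        matched = {
            m for i, m in enumerate(truth.mirna_labels) if truth.values[i, j] == 1.0
        }
        pos = frozenset(matched - seen)
        neg = frozenset(set(truth.mirna_labels) - matched - seen)
        out[d] = (pos, neg)
    return out


def write_bundle(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the standard input files plus the module ground truth.

    Produces ``mirna_similarity.tsv``, ``disease_similarity.tsv``,
    ``associations.tsv`` and ``truth.tsv`` (matched-module pairs) in
    ``outdir``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    MM, DD, assoc, truth = simulate_rdnet(config)
    paths = {
        "mirna_similarity": outdir / "mirna_similarity.tsv",
        "disease_similarity": outdir / "disease_similarity.tsv",
        "associations": outdir / "associations.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_similarity_matrix(MM, paths["mirna_similarity"])
    write_similarity_matrix(DD, paths["disease_similarity"])
    write_association_table(assoc, paths["associations"])
    with paths["truth"].open("w") as fh:
        fh.write("# mirna_id\tdisease_id\n")
        for i, m in enumerate(truth.mirna_labels):
            for j, d in enumerate(truth.disease_labels):
                if truth.values[i, j] == 1.0:
                    fh.write(f"{m}\t{d}\n")
    return paths
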