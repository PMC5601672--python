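"""Readers and writers for the three input formats and the ranked output.

Input formats
-------------
Association table
    Two-column TSV or CSV, one ``mirna_id<sep>disease_id`` pair per line.
    Lines starting with ``#`` are comments. Duplicate pairs collapse to one.
Similarity matrix
    (n+1) x (n+1) TSV or CSV with labels in the first row and first column,
    values in [0, 1], symmetric, unit diagonal (MISIM- / MimMiner-style dumps).
Ranked output
    TSV with header ``rank<TAB>mirna<TAB>score``, ranks starting at 1.

The delimiter is auto-detected (tab first, then comma) because both dialects
circulate for these datasets. Labels are case-sensitive and never normalized:
``hsa-mir-9-2`` and ``hsa-mir-9`` are distinct miRNAs and must survive I/O.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SYMMETRIZE_TOL = 1e-6   # asymmetries up to this are averaged away with a warning
_VALUE_TOL = 1e-9        # numeric slack on the [0, 1] range and the unit diagonal


class DataFormatError(ValueError):
    """Raised when an input file violates its schema."""


@dataclass(frozen=True)
class AssociationSet:
    """Known miRNA-disease association pairs.

    Label lists are lexicographically sorted so that the label -> matrix-index
    mapping is deterministic for any line order of the source file.
    """

    pairs: frozenset[tuple[str, str]]
    mirna_labels: tuple[str, ...] = field(default=())
    disease_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        mirnas = {m for m, _ in self.pairs}
        diseases = {d for _, d in self.pairs}
        if not self.mirna_labels and not self.disease_labels:
            object.__setattr__(self, "mirna_labels", tuple(sorted(mirnas)))
            object.__setattr__(self, "disease_labels", tuple(sorted(diseases)))
        missing_m = mirnas - set(self.mirna_labels)
        missing_d = diseases - set(self.disease_labels)
        if missing_m or missing_d:
            raise ValueError(
                f"association ids absent from label lists: "
                f"{sorted(missing_m | missing_d)}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def mirnas_for(self, disease_id: str) -> frozenset[str]:
        """All miRNAs known-associated with ``disease_id``."""
        return frozenset(m for m, d in self.pairs if d == disease_id)

    def diseases_for(self, mirna_id: str) -> frozenset[str]:
        return frozenset(d for m, d in self.pairs if m == mirna_id)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Labeled symmetric matrix of pairwise similarity scores in [0, 1].

    Houses either the miRNA functional-similarity block (MISIM-style) or the
    disease phenotype-similarity block (MimMiner-style) of the heterogeneous
    network.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in similarity matrix")
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=_VALUE_TOL, rtol=0):
            raise ValueError("similarity matrix is not symmetric within 1e-9")
        if np.any(v < -_VALUE_TOL):
            raise ValueError("similarity matrix has negative entries")
        if np.any(v > 1 + _VALUE_TOL):
            raise ValueError("similarity matrix has entries above 1")
        if not np.allclose(np.diag(v), 1.0, atol=_VALUE_TOL, rtol=0):
            raise ValueError("similarity matrix diagonal must equal 1")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_association_table(path: str | Path) -> AssociationSet:
    """Parse a two-column miRNA-disease association file.

    Duplicate pairs are collapsed; whitespace around ids is stripped; ``#``
    lines and blank lines are ignored. Raises :class:`DataFormatError` for a
    file with no valid pairs or for a line that does not have exactly two
    fields (the error names the offending line number).
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    delimiter: str | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is None:
                delimiter = _detect_delimiter(line)
            fields = [f.strip() for f in line.split(delimiter)]
            if len(fields) != 2 or not all(fields):
                raise DataFormatError(
                    f"{path}: line {lineno}: expected exactly two "
                    f"{'tab' if delimiter == chr(9) else 'comma'}-delimited "
                    f"fields, got {len(fields)}"
                )
            pairs.add((fields[0], fields[1]))
    if not pairs:
        raise DataFormatError(f"{path}: no associations found")
    assoc = AssociationSet(pairs=frozenset(pairs))
    logger.info(
        "read %d association pairs (%d miRNAs, %d diseases) from %s",
        assoc.n_pairs, len(assoc.mirna_labels), len(assoc.disease_labels), path,
    )
    return assoc


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Parse a labeled square similarity matrix from TSV/CSV.

    Row and column labels must carry the same label set. Asymmetries up to
    1e-6 are repaired as (S + S^T)/2 with a warning; anything larger is an
    error, as are values outside [0, 1] (within 1e-9 slack).
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    sep = _detect_delimiter(first)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.shape[0] != df.shape[1]:
        raise DataFormatError(f"{path}: matrix is not square: {df.shape}")
    if set(df.index) != set(df.columns):
        raise DataFormatError(f"{path}: row and column labels differ")
    # align columns to the row order, then sort both for a deterministic layout
    df = df.loc[:, df.index]
    order = sorted(df.index)
    df = df.loc[order, order]
    values = df.to_numpy(dtype=float)
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > _SYMMETRIZE_TOL:
        raise DataFormatError(
            f"{path}: matrix asymmetry {asym:.3g} exceeds {_SYMMETRIZE_TOL:g}"
        )
    if asym > _VALUE_TOL:
        warnings.warn(
            f"{path}: symmetrizing asymmetry of {asym:.3g} as (S+S^T)/2",
            stacklevel=2,
        )
        values = (values + values.T) / 2.0
    if np.any(values < -_VALUE_TOL) or np.any(values > 1 + _VALUE_TOL):
        raise DataFormatError(f"{path}: similarity values outside [0, 1]")
    if not np.allclose(np.diag(values), 1.0, atol=_VALUE_TOL, rtol=0):
        raise DataFormatError(f"{path}: diagonal entries must equal 1")
    return SimilarityMatrix(labels=tuple(order), values=values)


def write_association_table(assoc: AssociationSet, path: str | Path) -> None:
    """Write an association set as a two-column TSV (sorted, reproducible)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# mirna_id\tdisease_id\n")
        for m, d in sorted(assoc.pairs):
            fh.write(f"{m}\t{d}\n")


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as labeled TSV, re-readable by this module."""
    df = pd.DataFrame(sim.values, index=list(sim.labels), columns=list(sim.labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_ranked_list(ranking: "Sequence", path: str | Path) -> None:
    """Write a ranked candidate list as TSV ``rank  mirna  score``.

    ``ranking`` is a sequence of (mirna_id, score, rank) triples (the
    :class:`~mirdwalk.walker.RankedList` entries). Scores are printed with 10
    significant digits so a round trip preserves the ranking order exactly.
    """
    entries = list(ranking)
    if not entries:
        raise ValueError("cannot write an empty ranking")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("rank\tmirna\tscore\n")
        for mirna_id, score, rank in entries:
            fh.write(f"{rank}\t{mirna_id}\t{score:.10g}\n")


def read_ranked_list(path: str | Path) -> list[tuple[str, float, int]]:
    """Re-read a ranked list written by :func:`write_ranked_list`."""
    out: list[tuple[str, float, int]] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["rank", "mirna", "score"]:
            raise DataFormatError(f"{path}: unexpected ranked-list header {header}")
        for line in fh:
            rank_s, mirna, score_s = line.rstrip("\n").split("\t")
            out.append((mirna, float(score_s), int(rank_s)))
    return out
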