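"""Pairwise protein divergence.

Orthologous proteins are aligned globally (BLOSUM62, affine gap penalties,
end gaps penalized), identity is computed as matches over aligned residue-pair
columns (alignment length minus gap-containing columns), identities below the
floor are discarded, and divergence is PD% = 100 - identity%.

Gap convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .core_io import OrthologSet, RunConfig

__all__ = [
    "PairwiseAlignment",
    "DivergenceMatrix",
    "global_align",
    "percent_identity",
    "pairwise_divergence",
    "build_divergence_matrix",
]

log = logging.getLogger("clockscape")

GAP = "-"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")
#: residues scoreable under BLOSUM62 ('*' excluded: stop codons are not input)
_ALPHABET = frozenset(str(_BLOSUM62.alphabet)) - {"*"}


@dataclass(frozen=True)
class PairwiseAlignment:
    """One optimal global alignment: two equal-length gapped strings + score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")
        if any(x == GAP and y == GAP for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("column with gaps in both rows")


@dataclass
class DivergenceMatrix:
    """Per-gene x per-pair protein divergence PD% with missing-data mask.

    ``values[g, p]`` is NaN where a sequence was absent or identity fell below
    the floor; the boolean mask is ``included``.
    """

    genes: tuple
    pairs: pd.DataFrame
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.pairs)):
            raise ValueError("divergence matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0.0) < 0 or np.nanmax(self.values, initial=0.0) > 100:
                raise ValueError("PD% must lie in [0, 100]")

    @property
    def included(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=list(self.genes),
                          columns=self.pairs["pair_id"].astype(str))
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, pairs: pd.DataFrame) -> "DivergenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=["NA"])
        cols = [str(p) for p in pairs["pair_id"]]
        return cls(tuple(df.index), pairs, df[cols].to_numpy(dtype=float))


def _make_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.mode = "global"
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _validate(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence ({label})")
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"non-alphabet character {sorted(bad)[0]!r} in {label}")
    return seq


def global_align(seq_a: str, seq_b: str, gap_open: float = 12.0,
                 gap_extend: float = 2.0) -> PairwiseAlignment:
    """Optimal global alignment under BLOSUM62 with affine gap penalties.

    The score is the maximum attainable; among co-optimal alignments the
    reported one follows the aligner's internal tie-breaking, so identity on
    ambiguous inputs may vary between co-optimal paths while the score is
    invariant.
    """
    a = _validate(seq_a, "seq_a")
    b = _validate(seq_b, "seq_b")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = next(iter(aligner.align(a, b)))
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def percent_identity(alignment: PairwiseAlignment) -> float:
    """Identity% = 100 * matches / (alignment length - gap columns).

    A gap column is any column containing the gap symbol; columns pairing X
    with X count as mismatch (X is an unknown residue, not a match).  Returns
    NaN for an alignment with zero ungapped columns (flagged missing; excluded
    downstream).
    """
    matches = 0
    gap_columns = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x == GAP or y == GAP:
            gap_columns += 1
        elif x == y and x != "X":
            matches += 1
    denom = len(alignment.aligned_a) - gap_columns
    if denom == 0:
        return float("nan")
    return 100.0 * matches / denom


def pairwise_divergence(identity: float, identity_floor: float = 30.0) -> float:
    """PD% = 100 - identity%, or NaN (excluded) below the identity floor."""
    if not np.isfinite(identity):
        return float("nan")
    if identity < identity_floor:
        return float("nan")
    return 100.0 - identity


def build_divergence_matrix(orthologs: OrthologSet, pairs: pd.DataFrame,
                            config: RunConfig | None = None) -> DivergenceMatrix:
    """Align every (gene, species pair) with both sequences present.

    Entries are NaN where a species lacks the gene or identity is below the
    floor.  Genes missing from every pair are dropped (count logged).
    """
    config = config or RunConfig()
    genes = orthologs.gene_ids
    values = np.full((len(genes), len(pairs)), np.nan)
    pair_species = list(zip(pairs["species_a"], pairs["species_b"]))
    for gi, gene in enumerate(genes):
        per_species = orthologs.proteins[gene]
        for pi, (sa, sb) in enumerate(pair_species):
            a, b = per_species.get(sa), per_species.get(sb)
            if a is None or b is None:
                continue
            aln = global_align(a, b, config.gap_open, config.gap_extend)
            values[gi, pi] = pairwise_divergence(
                percent_identity(aln), config.identity_floor
            )
    present = np.isfinite(values).any(axis=1)
    if not present.all():
        log.info("dropped %d gene(s) with no usable comparison", (~present).sum())
        genes = [g for g, keep in zip(genes, present) if keep]
        values = values[present]
    return DivergenceMatrix(tuple(genes), pairs, values)
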