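"""Genome orders, per-gene composition metrics and sliding-window landscapes.

A :class:`GenomeOrder` ranks the common gene set along the chromosomes of one
reference genome; every landscape in the pipeline is a per-rank track aligned
to such an order.  The windowed value at rank ``k`` is the mean of the raw
per-gene metric over ranks ``k - h .. k + h`` (``h`` = 50 by default, i.e. a
101-gene window: the centered gene and its 100 neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenomeOrder",
    "Landscape",
    "gc_percent",
    "garp_percent",
    "sliding_window",
    "correlate_landscapes",
    "heatmap_matrix",
]

_GARP = frozenset("GARP")
_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class GenomeOrder:
    """Ranked gene list partitioned into chromosomes.

    ``chromosomes`` maps chromosome name to a half-open ``(start, stop)`` rank
    interval; intervals are contiguous, disjoint and cover ``0..n_genes``.
    Chromosome order is the order of the mapping (file order of first
    appearance, never lexicographic).
    """

    gene_ids: tuple
    chromosomes: dict

    def __post_init__(self):
        stops = [iv for iv in self.chromosomes.values()]
        covered = 0
        for start, stop in stops:
            if start != covered:
                raise ValueError("chromosome intervals must be contiguous")
            if stop <= start:
                raise ValueError("empty chromosome interval")
            covered = stop
        if covered != len(self.gene_ids):
            raise ValueError("chromosome intervals must cover all genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in genome order")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def rank(self) -> dict:
        """gene_id -> rank (cached on first use)."""
        r = self.__dict__.get("_rank")
        if r is None:
            r = {g: i for i, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_rank", r)
        return r

    def chromosome_of(self) -> np.ndarray:
        """Chromosome name per rank."""
        out = np.empty(self.n_genes, dtype=object)
        for name, (start, stop) in self.chromosomes.items():
            out[start:stop] = name
        return out

    def align(self, values: Mapping[str, float]) -> np.ndarray:
        """Arrange a gene_id -> value mapping on this order (NaN if absent)."""
        out = np.full(self.n_genes, np.nan)
        for i, g in enumerate(self.gene_ids):
            v = values.get(g)
            if v is not None:
                out[i] = v
        return out


@dataclass
class Landscape:
    """A windowed (or raw) per-rank track aligned to a GenomeOrder."""

    order: GenomeOrder
    values: np.ndarray
    metric_name: str = ""
    window_half_width: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.order.n_genes,):
            raise ValueError(
                f"landscape length {self.values.shape} does not match order "
                f"({self.order.n_genes} genes)"
            )


def gc_percent(sequence: str) -> float:
    """GC content of a nucleotide sequence, in percent.

    Ambiguous IUPAC bases (anything outside A/C/G/T, e.g. N) are excluded from
    both numerator and denominator; a sequence without any unambiguous base
    yields NaN (missing).
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    total = gc + at
    if total == 0:
        return float("nan")
    return 100.0 * gc / total


def garp_percent(sequence: str) -> float:
    """Relative occurrence of Gly/Ala/Arg/Pro in a protein, in percent.

    Non-standard residues (X, stops, gaps) are excluded from the denominator;
    a sequence without standard residues yields NaN.
    """
    s = sequence.upper()
    garp = sum(1 for c in s if c in _GARP)
    total = sum(1 for c in s if c in _STANDARD_AA)
    if total == 0:
        return float("nan")
    return 100.0 * garp / total


def _windowed_mean(values: np.ndarray, half_width: int) -> np.ndarray:
    """Missing-aware centered moving average; windows truncate at the ends."""
    n = len(values)
    kernel = np.ones(2 * half_width + 1)
    present = np.isfinite(values)
    # full convolution sliced to the centered n values (mode="same" would
    # return kernel-length output when the window is wider than the track)
    window = slice(half_width, half_width + n)
    sums = np.convolve(np.where(present, values, 0.0), kernel)[window]
    counts = np.convolve(present.astype(float), kernel)[window]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def sliding_window(
    values: np.ndarray | Mapping[str, float],
    order: GenomeOrder,
    half_width: int = 50,
    edge_policy: str = "concatenated",
    metric_name: str = "",
) -> Landscape:
    """Average a per-gene metric over each gene and its rank neighbours.

    edge_policy "concatenated" runs windows over the whole ranked list across
    chromosome joins, truncating only at the two genome ends;
    "per-chromosome-truncated" restarts the window at every chromosome
    boundary.  Missing values are dropped from the mean; a window is missing
    only when every contributor is missing.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if isinstance(values, Mapping):
        values = order.align(values)
    values = np.asarray(values, dtype=float)
    if values.shape != (order.n_genes,):
        raise ValueError("values must align with the genome order")

    if edge_policy == "concatenated":
        out = _windowed_mean(values, half_width)
    elif edge_policy == "per-chromosome-truncated":
        out = np.empty_like(values)
        for start, stop in order.chromosomes.values():
            out[start:stop] = _windowed_mean(values[start:stop], half_width)
    else:
        raise ValueError(f"unknown edge_policy: {edge_policy!r}")
    return Landscape(order, out, metric_name, half_width)


def correlate_landscapes(a: Landscape, b: Landscape) -> float:
    """Pearson R over jointly non-missing ranks; NaN when degenerate."""
    if a.order is not b.order and a.order.gene_ids != b.order.gene_ids:
        raise ValueError("landscapes must share one genome order")
    ok = np.isfinite(a.values) & np.isfinite(b.values)
    if ok.sum() < 3:
        return float("nan")
    x, y = a.values[ok], b.values[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def heatmap_matrix(tracks: Sequence[Landscape]) -> np.ndarray:
    """Stack landscapes sharing one order into a (tracks x ranks) matrix."""
    if len(tracks) == 0:
        raise ValueError("empty track list")
    ref = tracks[0].order
    for t in tracks[1:]:
        if t.order is not ref and t.order.gene_ids != ref.gene_ids:
            raise ValueError("all landscapes must share one genome order")
    return np.vstack([t.values for t in tracks])
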