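"""Molecular-clock fit and divergence normalization.

Under a strict clock, PD% = k * t for each protein and PDav% = kav * t for the
genome-wide average, so the origin-anchored regression of PDav% on divergence
time t estimates the average clock constant kav.  Normalizing each protein's
divergence by the pair's genome-wide average, nPD% = PD%/PDav% = k/kav,
removes time and leaves each gene's rate relative to the genome average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import RunConfig
from .divergence import DivergenceMatrix
from .landscape import GenomeOrder, Landscape, sliding_window

__all__ = [
    "ClockFit",
    "NormalizedDivergence",
    "average_divergence",
    "average_divergence_per_pair",
    "clock_regression",
    "normalize_divergence",
    "clade_mean_values",
    "clade_mean_landscape",
]


@dataclass
class ClockFit:
    """Genome-wide average clock constant and regression diagnostics."""

    k_av: float            # % divergence per My
    r2: float
    n_pairs: int
    intercept: float
    fitted: np.ndarray
    residuals: np.ndarray

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("clock fit needs >= 2 pairs")


@dataclass
class NormalizedDivergence:
    """nPD = PD/PDav per (gene, pair); masked entries stay masked.

    By construction the mean of nPD over included genes is exactly 1 for
    every pair.
    """

    genes: tuple
    pairs: pd.DataFrame
    values: np.ndarray
    pd_av: np.ndarray  # PDav% per pair


def average_divergence(matrix: DivergenceMatrix, pair_id: int) -> float:
    """Arithmetic mean PD% over included genes for one pair."""
    (col,) = np.flatnonzero((matrix.pairs["pair_id"] == pair_id).to_numpy())
    column = matrix.values[:, col]
    if not np.isfinite(column).any():
        raise ValueError(f"pair {pair_id}: no included genes")
    return float(np.nanmean(column))


def average_divergence_per_pair(matrix: DivergenceMatrix) -> np.ndarray:
    """PDav% for every pair, in pair-table order."""
    included = matrix.included
    if not included.any(axis=0).all():
        bad = matrix.pairs["pair_id"][~included.any(axis=0)].tolist()
        raise ValueError(f"pair(s) {bad}: no included genes")
    return np.nanmean(matrix.values, axis=0)


def clock_regression(pd_av: np.ndarray, t: np.ndarray,
                     through_origin: bool = True) -> ClockFit:
    """Fit PDav% = kav * t (default) or a free-intercept line.

    Through the origin, kav = sum(t * PDav) / sum(t^2).  R^2 is the squared
    Pearson correlation between observed and fitted values (well behaved for
    origin-anchored fits); it is reported as 1.0 when the fit is exact.
    """
    pd_av = np.asarray(pd_av, dtype=float)
    t = np.asarray(t, dtype=float)
    if pd_av.shape != t.shape or pd_av.ndim != 1:
        raise ValueError("pd_av and t must be equal-length 1-D arrays")
    if len(t) < 2:
        raise ValueError("clock fit needs >= 2 pairs")
    if through_origin:
        k = float(np.dot(t, pd_av) / np.dot(t, t))
        intercept = 0.0
    else:
        if np.ptp(t) == 0:
            raise ValueError("all divergence times equal; cannot fit intercept")
        k, intercept = np.polyfit(t, pd_av, 1)
        k, intercept = float(k), float(intercept)
    fitted = k * t + intercept
    residuals = pd_av - fitted
    if np.allclose(residuals, 0.0) or np.ptp(fitted) == 0:
        r2 = 1.0 if np.allclose(residuals, 0.0) else float("nan")
    else:
        r2 = float(stats.pearsonr(pd_av, fitted).statistic ** 2)
    return ClockFit(k, r2, len(t), intercept, fitted, residuals)


def normalize_divergence(matrix: DivergenceMatrix) -> NormalizedDivergence:
    """nPD(g, p) = PD(g, p) / PDav(p); errors on a degenerate (PDav = 0) pair."""
    pd_av = average_divergence_per_pair(matrix)
    if (pd_av == 0).any():
        bad = matrix.pairs["pair_id"][pd_av == 0].tolist()
        raise ValueError(f"degenerate pair(s) with PDav = 0: {bad}")
    return NormalizedDivergence(
        matrix.genes, matrix.pairs, matrix.values / pd_av, pd_av
    )


def _pair_columns(npd: NormalizedDivergence, pair_class: str) -> np.ndarray:
    cols = np.flatnonzero((npd.pairs["pair_class"] == pair_class).to_numpy())
    if len(cols) == 0:
        raise ValueError(f"no pairs of class {pair_class!r}")
    return cols


def clade_mean_values(npd: NormalizedDivergence, pair_class: str) -> dict:
    """Per-gene mean nPD across all pairs of one class (equal weight per
    pair), as a gene_id -> value mapping; genes missing everywhere omitted."""
    cols = _pair_columns(npd, pair_class)
    sub = npd.values[:, cols]
    present = np.isfinite(sub)
    counts = present.sum(axis=1)
    sums = np.where(present, sub, 0.0).sum(axis=1)
    means = np.divide(sums, counts, out=np.full(len(sums), np.nan),
                      where=counts > 0)
    return {g: float(m) for g, m in zip(npd.genes, means) if np.isfinite(m)}


def clade_mean_landscape(npd: NormalizedDivergence, pair_class: str,
                         order: GenomeOrder,
                         config: RunConfig | None = None) -> Landscape:
    """Mean windowed nPD track across all pairs of one class.

    Each pair's per-gene nPD is ranked on the order and windowed first; the
    per-rank mean across pairs is taken second (equal weight per pair,
    missing-aware).  On missing-free data this equals windowing the per-gene
    clade mean, by linearity of the window.
    """
    config = config or RunConfig()
    cols = _pair_columns(npd, pair_class)
    rank = order.rank
    stack = np.full((len(cols), order.n_genes), np.nan)
    gene_rows = [(rank[g], gi) for gi, g in enumerate(npd.genes) if g in rank]
    if not gene_rows:
        raise ValueError("no genes shared between the matrix and the order")
    ranks = np.array([r for r, _ in gene_rows], dtype=int)
    rows = np.array([gi for _, gi in gene_rows], dtype=int)
    for out_i, col in enumerate(cols):
        aligned = np.full(order.n_genes, np.nan)
        aligned[ranks] = npd.values[rows, col]
        stack[out_i] = sliding_window(
            aligned, order, config.window_half_width, config.edge_policy
        ).values
    present = np.isfinite(stack)
    counts = present.sum(axis=0)
    sums = np.where(present, stack, 0.0).sum(axis=0)
    mean_track = np.divide(sums, counts, out=np.full(order.n_genes, np.nan),
                           where=counts > 0)
    return Landscape(order, mean_track, f"nPD:{pair_class}",
                     config.window_half_width)
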