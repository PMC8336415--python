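"""Randomization-based detection of regionally accelerated divergence.

The observed clade-mean nPD landscape is compared against sliding-window
landscapes computed on randomized gene orders: genes are permuted uniformly
over the same chromosome partition, windows are recomputed, and the pooled
window values across replicates define the acceleration threshold
mean + m * SD (m = 3 by default).  Windows exceeding the threshold mark
accelerated regions; their enrichment in subtelomeres (the first/last
``margin`` genes of each chromosome) quantifies the telomere effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import RunConfig
from .landscape import GenomeOrder, Landscape, sliding_window

__all__ = [
    "NullDistribution",
    "AccelerationResult",
    "random_order_null",
    "exceedance_set",
    "venn_overlap",
    "subtelomere_labels",
    "subtelomere_enrichment",
]


@dataclass
class NullDistribution:
    """Pooled window values from randomized gene orders."""

    n_reps: int
    window_values: np.ndarray  # (n_reps, n_genes)
    mean: float
    sd: float
    sd_multiplier: float

    @property
    def threshold(self) -> float:
        return self.mean + self.sd_multiplier * self.sd


@dataclass
class AccelerationResult:
    """Window ranks (= centered genes) exceeding the null threshold."""

    exceeding_ranks: np.ndarray
    exceeding_genes: frozenset
    threshold: float
    n_windows: int

    @property
    def count(self) -> int:
        return len(self.exceeding_ranks)


def random_order_null(values, order: GenomeOrder,
                      config: RunConfig | None = None,
                      rng: np.random.Generator | None = None,
                      sd_mode: str = "pooled") -> NullDistribution:
    """Null window distribution from uniformly permuted gene values.

    ``values`` is a per-gene track (mapping or array aligned to the order);
    each replicate permutes the value multiset over the ranks (missing values
    permute along) and recomputes the sliding-window landscape on the same
    chromosome partition.  Mean and SD are taken over the pooled window values
    of all replicates ("pooled", default) or as the mean of per-replicate SDs
    ("per-rep").
    """
    config = config or RunConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    if isinstance(values, dict):
        values = order.align(values)
    values = np.asarray(values, dtype=float)
    if values.shape != (order.n_genes,):
        raise ValueError("values must align with the genome order")
    if order.n_genes < 2 * config.window_half_width + 1:
        raise ValueError("genome smaller than one window")

    reps = np.empty((config.n_random_orders, order.n_genes))
    for r in range(config.n_random_orders):
        permuted = rng.permutation(values)
        reps[r] = sliding_window(
            permuted, order, config.window_half_width, config.edge_policy
        ).values
    pooled = reps[np.isfinite(reps)]
    mean = float(pooled.mean())
    if sd_mode == "pooled":
        sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    elif sd_mode == "per-rep":
        sd = float(np.mean([row[np.isfinite(row)].std(ddof=1) for row in reps]))
    else:
        raise ValueError(f"unknown sd_mode: {sd_mode!r}")
    return NullDistribution(config.n_random_orders, reps, mean, sd,
                            config.threshold_sd_multiplier)


def exceedance_set(landscape: Landscape, null: NullDistribution) -> AccelerationResult:
    """Ranks whose windowed value strictly exceeds the null threshold.

    Each gene centers one window, so "genes above threshold" and "windows
    above threshold" are the same set.
    """
    threshold = null.threshold
    with np.errstate(invalid="ignore"):
        above = np.flatnonzero(landscape.values > threshold)
    genes = frozenset(landscape.order.gene_ids[i] for i in above)
    return AccelerationResult(above, genes, threshold, landscape.order.n_genes)


def venn_overlap(set_a, set_b) -> tuple:
    """(|a only|, |b only|, |a and b|)."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    return (len(a - inter), len(b - inter), len(inter))


def subtelomere_labels(order: GenomeOrder, margin: int = 50) -> np.ndarray:
    """Boolean per-rank mask of subtelomeric genes.

    For each chromosome the first and last ``margin`` ranks are subtelomeric;
    chromosomes with <= 2 * margin genes are entirely subtelomeric.
    """
    if margin < 1:
        raise ValueError("subtelomere margin must be >= 1")
    mask = np.zeros(order.n_genes, dtype=bool)
    for start, stop in order.chromosomes.values():
        mask[start:min(start + margin, stop)] = True
        mask[max(stop - margin, start):stop] = True
    return mask


def subtelomere_enrichment(result: AccelerationResult, labels: np.ndarray,
                           n_genes: int) -> tuple:
    """(observed fraction, expected fraction, fold) of subtelomeric windows
    among exceeding windows, versus the genome-wide subtelomeric fraction.

    Returns NaNs (flagged undefined) for an empty exceedance set.
    """
    expected = labels.sum() / n_genes
    if result.count == 0:
        return (float("nan"), float(expected), float("nan"))
    observed = labels[result.exceeding_ranks].sum() / result.count
    return (float(observed), float(expected), float(observed / expected))
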