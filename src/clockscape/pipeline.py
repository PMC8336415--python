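"""High-level orchestration: simulate a study, run the landscape/clock/
acceleration/concordance analyses, collect summary numbers.

This is the glue the CLI and the reproduction script drive; every step is a
thin call into the corresponding module.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acceleration import (AccelerationResult, NullDistribution,
                           exceedance_set, random_order_null,
                           subtelomere_enrichment, subtelomere_labels,
                           venn_overlap)
from .clock import (ClockFit, NormalizedDivergence, average_divergence_per_pair,
                    clade_mean_landscape, clade_mean_values, clock_regression,
                    normalize_divergence)
from .concordance import concordance_summary, map_genes_between_orders
from .core_io import RunConfig
from .divergence import DivergenceMatrix
from .landscape import GenomeOrder, Landscape
from .synthetic_data import (SimulationConfig, SyntheticTruth,
                             default_pair_table, default_species_table,
                             default_pair_times, make_order_b, simulate_divergences,
                             simulate_gc_garp, simulate_rates)
from . import synthetic_data

__all__ = [
    "StudyData",
    "LineageAcceleration",
    "derive_seed",
    "simulate_study",
    "fit_clock",
    "lineage_acceleration",
    "full_analysis",
]

log = logging.getLogger("clockscape")

#: which reference order carries each lineage's own analysis
LINEAGE_ORDER = {"Eutheria": "a", "Metatheria": "b"}
LINEAGE_PAIR_CLASS = {"Eutheria": "intra-Eutherian",
                      "Metatheria": "intra-Metatherian"}


def derive_seed(seed: int, tag: str) -> int:
    """Stable per-analysis seed below 2**31, derived from (seed, tag)."""
    return (int(seed) * 2654435761 + zlib.crc32(tag.encode())) % (2 ** 31)


@dataclass
class StudyData:
    config: SimulationConfig
    species: pd.DataFrame
    pairs: pd.DataFrame
    truth: SyntheticTruth
    divergence: DivergenceMatrix
    gc: pd.DataFrame | None = None
    garp: pd.DataFrame | None = None

    @property
    def order_a(self) -> GenomeOrder:
        return self.truth.order_a

    @property
    def order_b(self) -> GenomeOrder:
        return self.truth.order_b


@dataclass
class LineageAcceleration:
    lineage: str
    order: GenomeOrder
    landscape: Landscape
    null: NullDistribution
    result: AccelerationResult


def simulate_study(config: SimulationConfig | None = None, seed: int = 0,
                   with_gc: bool = False) -> StudyData:
    """Generate the default synthetic cohort (orders, rates, divergences)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(derive_seed(seed, "study"))
    species = default_species_table()
    pairs = synthetic_data.build_pair_table(
        species, default_pair_times(species, config))
    truth = simulate_rates(config, rng)
    matrix = simulate_divergences(truth, pairs, config, rng, species)
    gc = garp = None
    if with_gc:
        gc, garp = simulate_gc_garp(config, truth, rng, species)
    return StudyData(config, species, pairs, truth, matrix, gc, garp)


def fit_clock(matrix: DivergenceMatrix, through_origin: bool = True) -> ClockFit:
    """PDav% vs t regression over all pairs."""
    pd_av = average_divergence_per_pair(matrix)
    return clock_regression(pd_av, matrix.pairs["t"].to_numpy(), through_origin)


def lineage_acceleration(npd: NormalizedDivergence, order: GenomeOrder,
                         lineage: str, run_config: RunConfig | None = None,
                         seed: int | None = None) -> LineageAcceleration:
    """Clade-mean nPD landscape, random-order null and exceedance set for one
    lineage on its reference order."""
    run_config = run_config or RunConfig()
    pair_class = LINEAGE_PAIR_CLASS[lineage]
    seed = run_config.rng_seed if seed is None else seed
    rng = np.random.default_rng(derive_seed(seed, f"null:{lineage}"))
    scape = clade_mean_landscape(npd, pair_class, order, run_config)
    per_gene = clade_mean_values(npd, pair_class)
    null = random_order_null(per_gene, order, run_config, rng)
    result = exceedance_set(scape, null)
    return LineageAcceleration(lineage, order, scape, null, result)


def full_analysis(config: SimulationConfig | None = None,
                  run_config: RunConfig | None = None,
                  seed: int = 0) -> dict:
    """Simulate the default cohort and run every downstream stage.

    Returns a dict with the study data, clock fit, per-lineage acceleration
    results, overlap, subtelomere enrichment and concordance summaries.
    """
    config = config or SimulationConfig()
    run_config = run_config or RunConfig()
    study = simulate_study(config, seed)
    clock_fit = fit_clock(study.divergence)
    npd = normalize_divergence(study.divergence)

    accel = {}
    for lineage, which in LINEAGE_ORDER.items():
        order = study.order_a if which == "a" else study.order_b
        accel[lineage] = lineage_acceleration(npd, order, lineage,
                                              run_config, seed)

    overlap = venn_overlap(accel["Eutheria"].result.exceeding_genes,
                           accel["Metatheria"].result.exceeding_genes)

    margin = run_config.subtelomere_margin
    labels_a = subtelomere_labels(study.order_a, margin)
    enrichment = subtelomere_enrichment(accel["Eutheria"].result, labels_a,
                                        study.order_a.n_genes)

    # human-vs-pig-like concordance: a subtelomere-preserving third order
    rng = np.random.default_rng(derive_seed(seed, "order_c"))
    order_c = make_order_b(study.order_a, "subtelomere-preserving", rng)
    links_ac = map_genes_between_orders(
        accel["Eutheria"].result.exceeding_genes & frozenset(
            study.order_a.gene_ids[r] for r in np.flatnonzero(labels_a)),
        study.order_a, order_c, margin)
    concordance_preserving = concordance_summary(links_ac)
    links_ab = map_genes_between_orders(
        accel["Eutheria"].result.exceeding_genes & frozenset(
            study.order_a.gene_ids[r] for r in np.flatnonzero(labels_a)),
        study.order_a, study.order_b, margin)
    concordance_cross = concordance_summary(links_ab)

    return {
        "study": study,
        "clock": clock_fit,
        "npd": npd,
        "acceleration": accel,
        "venn": overlap,
        "subtelomere_enrichment": enrichment,
        "concordance_preserving": concordance_preserving,
        "concordance_cross": concordance_cross,
    }
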