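"""Synthetic study generator.

Emulates the statistical structure of the 16-mammal / 15,727-gene design so
the whole pipeline is testable without any genome download:

* a fixed dated species design — 12 Eutheria in three clades of four plus
  4 Metatheria, with ultrametric pairwise times built from the study's
  calibration means (Eutheria-Metatheria 158.5 My, Afrotheria split 104 My,
  Euarchontoglires-Laurasiatheria split 96 My);
* two genome orders: a human-like karyotype of 23 chromosomes (order A) and an
  opossum-like karyotype of 8 large autosomes + X (order B), related to A by a
  configurable rearrangement mode;
* heavy-tailed per-gene clock rates (lognormal, roughly two orders of
  magnitude between the 1st and 99th percentile) around a genome-mean clock of
  0.13 %/My, with lineage-specific rate multipliers in subtelomeric blocks;
* pairwise divergences generated linearly in time (PD% = k*t, capped at 95%)
  with binomial site-sampling noise;
* per-species GC% and GARP% tracks with regional structure and a
  within-species gene-level coupling of 0.93;
* optionally, protein sequences evolved along the dated tree for end-to-end
  tests of the alignment path.

Every output is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import core_io
from .core_io import CLADE_LINEAGE, build_pair_table, make_species_table
from .divergence import DivergenceMatrix
from .landscape import GenomeOrder, sliding_window

__all__ = [
    "SPECIES_16",
    "AccelerationBlock",
    "SimulationConfig",
    "SyntheticTruth",
    "default_species_table",
    "default_pair_times",
    "default_pair_table",
    "simulate_orders",
    "make_order_b",
    "simulate_rates",
    "simulate_divergences",
    "simulate_gc_garp",
    "simulate_sequences",
    "write_study",
]

#: the study's species design: 4 species per Eutherian clade + 4 Metatheria.
SPECIES_16 = (
    ("Sus_scrofa", "Laurasiatheria"),
    ("Equus_asinus", "Laurasiatheria"),
    ("Orcinus_orca", "Laurasiatheria"),
    ("Felis_catus", "Laurasiatheria"),
    ("Cricetulus_griseus", "Euarchontoglires"),
    ("Rattus_norvegicus", "Euarchontoglires"),
    ("Oryctolagus_cuniculus", "Euarchontoglires"),
    ("Callithrix_jacchus", "Euarchontoglires"),
    ("Trichechus_manatus", "Afrotheria"),
    ("Loxodonta_africana", "Afrotheria"),
    ("Chrysochloris_asiatica", "Afrotheria"),
    ("Orycteropus_afer", "Afrotheria"),
    ("Vombatus_ursinus", "Metatheria"),
    ("Sarcophilus_harrisii", "Metatheria"),
    ("Phascolarctos_cinereus", "Metatheria"),
    ("Monodelphis_domestica", "Metatheria"),
)

# approximate relative protein-coding gene counts of the human chromosomes
_HUMAN_LIKE_WEIGHTS = (
    2000, 1300, 1100, 800, 900, 1000, 900, 700, 800, 750, 1300, 1000,
    350, 650, 650, 900, 1200, 300, 1400, 550, 250, 450, 850,
)
_HUMAN_LIKE_NAMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)

# opossum-like 2n = 14 karyotype: few large autosomes plus a small X
_OPOSSUM_LIKE_WEIGHTS = (19, 17, 15, 13, 11, 9, 7, 6, 3)
_OPOSSUM_LIKE_NAMES = tuple(f"chr{i}" for i in range(1, 9)) + ("chrX",)


@dataclass(frozen=True)
class AccelerationBlock:
    """A contiguous run of genes with a lineage-specific rate multiplier.

    ``order`` is "a" or "b"; ``side`` is "p" (chromosome start) or "q"
    (chromosome end); ``size`` is the block length in genes.
    """

    order: str
    chromosome: str
    side: str
    size: int
    lineage: str
    multiplier: float

    def __post_init__(self):
        if self.order not in ("a", "b"):
            raise ValueError("block order must be 'a' or 'b'")
        if self.side not in ("p", "q"):
            raise ValueError("block side must be 'p' or 'q'")
        if not self.multiplier > 0:
            raise ValueError("multiplier must be > 0")


def _default_blocks() -> list:
    """Paper-scale acceleration: ~1,800 Eutherian genes in human-order
    subtelomeric blocks and ~1,500 Metatherian genes in opossum-order blocks,
    at 1.75x the baseline rate, giving windowed regional accelerations of
    ~40-60% above the normalized genome mean.

    Accelerated subtelomeres usually flank a chromosome join on both sides
    (mammalian subtelomeres are systematically GC-rich and fast), so blocks
    are paired across joins; a window centered inside a subtelomere then sees
    accelerated genes on both flanks, as in the emulated genomes.
    """
    e_joins = [("chr1", "chr2"), ("chr4", "chr5"), ("chr8", "chr9"),
               ("chr11", "chr12"), ("chr14", "chr15"), ("chr16", "chr17"),
               ("chr19", "chr20"), ("chr21", "chr22")]
    m_joins = [("chr1", "chr2"), ("chr3", "chr4"), ("chr5", "chr6"),
               ("chr7", "chr8")]
    blocks = []
    for left, right in e_joins:
        blocks.append(AccelerationBlock("a", left, "q", 112, "Eutheria", 1.75))
        blocks.append(AccelerationBlock("a", right, "p", 113, "Eutheria", 1.75))
    for left, right in m_joins:
        blocks.append(AccelerationBlock("b", left, "q", 125, "Metatheria", 1.75))
        blocks.append(AccelerationBlock("b", right, "p", 125, "Metatheria", 1.75))
    # one terminal Metatherian block (the Xq subtelomere of the opossum-like
    # order) so not every accelerated region spans a join
    blocks.append(AccelerationBlock("b", "chrX", "q", 250, "Metatheria", 1.75))
    blocks.append(AccelerationBlock("b", "chr8", "q", 250, "Metatheria", 1.75))
    return blocks


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    n_genes: int = 15727
    chrom_weights_a: tuple = _HUMAN_LIKE_WEIGHTS
    chrom_names_a: tuple = _HUMAN_LIKE_NAMES
    chrom_weights_b: tuple = _OPOSSUM_LIKE_WEIGHTS
    chrom_names_b: tuple = _OPOSSUM_LIKE_NAMES
    rearrangement_mode: str = "reshuffled"

    # clock-rate law: lognormal with genome-mean 0.13 %/My and ~2 orders of
    # magnitude between the 1st and 99th percentile
    mean_clock: float = 0.13
    sigma_log_rate: float = 1.0

    # divergence noise model
    n_sites: int = 450
    divergence_cap: float = 95.0

    acceleration_blocks: list = field(default_factory=_default_blocks)

    # GC/GARP model
    rho_gc_garp: float = 0.93
    base_gc: float = 52.0
    regional_sd_gc: float = 4.0
    noise_sd_gc: float = 6.0
    base_garp: float = 12.0
    regional_sd_garp: float = 1.0
    noise_sd_garp: float = 1.5
    block_gc_boost: float = 4.0
    block_garp_boost: float = 1.0

    # ultrametric divergence times (My)
    t_within_clade: float = 70.0
    t_within_metatheria: float = 60.0
    t_euarchontoglires_laurasiatheria: float = 96.0
    t_afrotheria: float = 104.0
    t_eutheria_metatheria: float = 158.5

    def __post_init__(self):
        if self.sigma_log_rate < 0:
            raise ValueError("sigma_log_rate must be >= 0")
        if not -1 < self.rho_gc_garp < 1:
            raise ValueError("rho_gc_garp must be in (-1, 1)")
        if self.rearrangement_mode not in (
            "reshuffled", "subtelomere-preserving", "identity"
        ):
            raise ValueError(
                f"unknown rearrangement_mode: {self.rearrangement_mode!r}"
            )

    @property
    def mu_log_rate(self) -> float:
        # lognormal mean exp(mu + sigma^2/2) equals mean_clock
        return float(np.log(self.mean_clock) - 0.5 * self.sigma_log_rate ** 2)


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    gene_ids: tuple
    k: np.ndarray                    # baseline clock rate per gene (%/My)
    multiplier: dict                 # lineage -> per-gene effective multiplier
    accelerated: dict                # lineage -> frozenset of planted gene ids
    order_a: GenomeOrder
    order_b: GenomeOrder

    def effective_rate(self, lineage: str) -> np.ndarray:
        return self.k * self.multiplier[lineage]


def default_species_table() -> pd.DataFrame:
    return make_species_table(SPECIES_16)


def default_pair_times(species: pd.DataFrame,
                       config: SimulationConfig | None = None) -> dict:
    """Ultrametric pairwise times from the fixed 4-level species tree."""
    config = config or SimulationConfig()
    clade = dict(zip(species["species_id"], species["clade"]))
    times = {}
    ids = list(species["species_id"])
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ca, cb = clade[a], clade[b]
            la, lb = CLADE_LINEAGE[ca], CLADE_LINEAGE[cb]
            if la != lb:
                t = config.t_eutheria_metatheria
            elif la == "Metatheria":
                t = config.t_within_metatheria
            elif ca == cb:
                t = config.t_within_clade
            elif "Afrotheria" in (ca, cb):
                t = config.t_afrotheria
            else:
                t = config.t_euarchontoglires_laurasiatheria
            times[frozenset({a, b})] = t
    return times


def default_pair_table(config: SimulationConfig | None = None) -> pd.DataFrame:
    species = default_species_table()
    return build_pair_table(species, default_pair_times(species, config))


# ---------------------------------------------------------------------------
# genome orders
# ---------------------------------------------------------------------------

def _partition_sizes(n: int, weights: Sequence[float]) -> list:
    weights = np.asarray(weights, dtype=float)
    raw = weights / weights.sum() * n
    sizes = np.floor(raw).astype(int)
    # hand the remainder to the largest fractional parts
    for i in np.argsort(raw - sizes)[::-1][: n - sizes.sum()]:
        sizes[i] += 1
    return sizes.tolist()


def _order_from_sizes(gene_ids: Sequence[str], names: Sequence[str],
                      sizes: Sequence[int]) -> GenomeOrder:
    chromosomes: dict = {}
    start = 0
    for name, size in zip(names, sizes):
        chromosomes[name] = (start, start + size)
        start += size
    return GenomeOrder(tuple(gene_ids), chromosomes)


def make_order_b(order_a: GenomeOrder, mode: str,
                 rng: np.random.Generator,
                 chrom_weights: Sequence[float] = _OPOSSUM_LIKE_WEIGHTS,
                 chrom_names: Sequence[str] = _OPOSSUM_LIKE_NAMES) -> GenomeOrder:
    """Derive a second genome order from ``order_a``.

    "reshuffled": genes are placed uniformly at random over the target
    karyotype (chromosome ends of A and B are unrelated).
    "subtelomere-preserving": every chromosome of A is split into two arms and
    arms are re-paired into new chromosomes with their telomeric ends kept
    outward, so genes at chromosome termini stay at termini (fusion/fission
    with conserved subtelomeres).
    "identity": order A unchanged.
    """
    if mode == "identity":
        return GenomeOrder(order_a.gene_ids, dict(order_a.chromosomes))
    if mode == "reshuffled":
        genes = list(rng.permutation(np.asarray(order_a.gene_ids, dtype=object)))
        sizes = _partition_sizes(order_a.n_genes, chrom_weights)
        return _order_from_sizes(genes, chrom_names, sizes)
    if mode == "subtelomere-preserving":
        arms = []  # (genes, telomere_side): "left" or "right"
        for start, stop in order_a.chromosomes.values():
            mid = (start + stop) // 2
            arms.append((list(order_a.gene_ids[start:mid]), "left"))
            arms.append((list(order_a.gene_ids[mid:stop]), "right"))
        rng.shuffle(arms)
        genes: list = []
        sizes = []
        for i in range(0, len(arms) - 1, 2):
            left_genes, left_side = arms[i]
            right_genes, right_side = arms[i + 1]
            left = left_genes if left_side == "left" else left_genes[::-1]
            right = right_genes if right_side == "right" else right_genes[::-1]
            genes.extend(left + right)
            sizes.append(len(left) + len(right))
        if len(arms) % 2:  # odd arm count: last arm becomes its own chromosome
            last_genes, side = arms[-1]
            genes.extend(last_genes if side == "left" else last_genes[::-1])
            sizes.append(len(last_genes))
        names = tuple(f"chr{i + 1}" for i in range(len(sizes)))
        return _order_from_sizes(genes, names, sizes)
    raise ValueError(f"unknown rearrangement mode: {mode!r}")


def simulate_orders(config: SimulationConfig,
                    rng: np.random.Generator) -> tuple:
    """The two reference genome orders over one shared gene set."""
    gene_ids = tuple(f"g{i + 1:05d}" for i in range(config.n_genes))
    sizes_a = _partition_sizes(config.n_genes, config.chrom_weights_a)
    order_a = _order_from_sizes(gene_ids, config.chrom_names_a, sizes_a)
    order_b = make_order_b(order_a, config.rearrangement_mode, rng,
                           config.chrom_weights_b, config.chrom_names_b)
    return order_a, order_b


# ---------------------------------------------------------------------------
# rates and divergences
# ---------------------------------------------------------------------------

def _block_ranks(block: AccelerationBlock, order: GenomeOrder) -> np.ndarray:
    start, stop = order.chromosomes[block.chromosome]
    if block.side == "p":
        return np.arange(start, min(start + block.size, stop))
    return np.arange(max(stop - block.size, start), stop)


def simulate_rates(config: SimulationConfig, rng: np.random.Generator,
                   order_a: GenomeOrder | None = None,
                   order_b: GenomeOrder | None = None) -> SyntheticTruth:
    """Per-gene baseline rates plus lineage multipliers from planted blocks."""
    if order_a is None or order_b is None:
        order_a, order_b = simulate_orders(config, rng)
    gene_ids = order_a.gene_ids
    n = len(gene_ids)
    k = rng.lognormal(config.mu_log_rate, config.sigma_log_rate, size=n)

    index = order_a.rank  # canonical gene index = rank on order A
    multiplier = {
        "Eutheria": np.ones(n),
        "Metatheria": np.ones(n),
    }
    accelerated = {"Eutheria": set(), "Metatheria": set()}
    for block in config.acceleration_blocks:
        order = order_a if block.order == "a" else order_b
        genes = [order.gene_ids[r] for r in _block_ranks(block, order)]
        idx = np.array([index[g] for g in genes])
        multiplier[block.lineage][idx] *= block.multiplier
        accelerated[block.lineage].update(genes)
    return SyntheticTruth(
        gene_ids, k, multiplier,
        {lin: frozenset(g) for lin, g in accelerated.items()},
        order_a, order_b,
    )


def pair_multiplier(truth: SyntheticTruth, lineage_a: str,
                    lineage_b: str) -> np.ndarray:
    """Effective per-gene multiplier for a species pair.

    Within a lineage the lineage's multiplier applies; across lineages each
    regional effect acts on its own branch, so the two multipliers average.
    """
    if lineage_a == lineage_b:
        return truth.multiplier[lineage_a]
    return 0.5 * (truth.multiplier["Eutheria"] + truth.multiplier["Metatheria"])


def simulate_divergences(truth: SyntheticTruth, pairs: pd.DataFrame,
                         config: SimulationConfig,
                         rng: np.random.Generator,
                         species: pd.DataFrame | None = None) -> DivergenceMatrix:
    """PD% per (gene, pair): binomial site sampling around min(k*mult*t, cap).

    The identity floor is a correction for incomplete real-world sequence
    data and is not applied here; all generated entries are included.
    """
    species = species if species is not None else default_species_table()
    lineage = dict(zip(species["species_id"], species["lineage"]))
    n = len(truth.gene_ids)
    values = np.empty((n, len(pairs)))
    for pi, row in enumerate(pairs.itertuples(index=False)):
        mult = pair_multiplier(truth, lineage[row.species_a], lineage[row.species_b])
        expected = np.minimum(truth.k * mult * row.t, config.divergence_cap)
        draws = rng.binomial(config.n_sites, expected / 100.0)
        values[:, pi] = 100.0 * draws / config.n_sites
    return DivergenceMatrix(truth.gene_ids, pairs, values)


# ---------------------------------------------------------------------------
# GC / GARP tracks
# ---------------------------------------------------------------------------

def _correlated_standard_pair(n: int, rho: float,
                              rng: np.random.Generator) -> tuple:
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
    return z1, z2


def _smooth_on_order(z: np.ndarray, order: GenomeOrder, half_width: int) -> np.ndarray:
    """Window-smooth a white-noise track on an order and re-standardize, so the
    regional component varies on the same length scale as the analysis window."""
    smooth = sliding_window(z, order, half_width).values
    return (smooth - smooth.mean()) / smooth.std()


def simulate_gc_garp(config: SimulationConfig, truth: SyntheticTruth,
                     rng: np.random.Generator,
                     species: pd.DataFrame | None = None) -> tuple:
    """Per-species per-gene GC% and GARP% with coupled regional structure.

    Both metrics share (with coupling rho at every level) a mammal-common
    regional profile, a lineage-specific regional profile (generated on the
    lineage's own reference order, so its structure is positional), elevated
    values inside the lineage's subtelomeric acceleration blocks, and
    independent per-gene noise.  The resulting within-species gene-level
    GC-GARP correlation is rho by construction.
    """
    species = species if species is not None else default_species_table()
    rho = config.rho_gc_garp
    order_a, order_b = truth.order_a, truth.order_b
    n = order_a.n_genes
    index = order_a.rank

    # shared regional components (smooth pairs, correlation rho)
    c1, c2 = _correlated_standard_pair(n, rho, rng)
    common = (_smooth_on_order(c1, order_a, 50), _smooth_on_order(c2, order_a, 50))
    l1, l2 = _correlated_standard_pair(n, rho, rng)
    lin_e = (_smooth_on_order(l1, order_a, 50), _smooth_on_order(l2, order_a, 50))
    l1, l2 = _correlated_standard_pair(n, rho, rng)
    lin_m_b = (_smooth_on_order(l1, order_b, 50), _smooth_on_order(l2, order_b, 50))
    # map the Metatherian profile (built on order B ranks) back onto gene ids
    back = np.array([index[g] for g in order_b.gene_ids])
    lin_m = (np.empty(n), np.empty(n))
    lin_m[0][back] = lin_m_b[0]
    lin_m[1][back] = lin_m_b[1]

    # block elevation masks per lineage (per-gene, canonical index)
    boost = {}
    for lin in ("Eutheria", "Metatheria"):
        mask = np.zeros(n)
        for g in truth.accelerated[lin]:
            mask[index[g]] = 1.0
        boost[lin] = mask

    w_common, w_lin = 0.85, np.sqrt(1.0 - 0.85 ** 2)
    gc, garp = {}, {}
    for sp, lin in zip(species["species_id"], species["lineage"]):
        reg = lin_e if lin == "Eutheria" else lin_m
        r_gc = w_common * common[0] + w_lin * reg[0]
        r_garp = w_common * common[1] + w_lin * reg[1]
        e_gc, e_garp = _correlated_standard_pair(n, rho, rng)
        gc[sp] = (config.base_gc + config.regional_sd_gc * r_gc
                  + config.block_gc_boost * boost[lin]
                  + config.noise_sd_gc * e_gc)
        garp[sp] = (config.base_garp + config.regional_sd_garp * r_garp
                    + config.block_garp_boost * boost[lin]
                    + config.noise_sd_garp * e_garp)
    gene_index = list(truth.gene_ids)
    return (pd.DataFrame(gc, index=gene_index),
            pd.DataFrame(garp, index=gene_index))


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _species_tree(config: SimulationConfig,
                  species: pd.DataFrame) -> dict:
    """Fixed 4-level ultrametric tree matching :func:`default_pair_times`."""
    by_clade = {c: list(g["species_id"]) for c, g in species.groupby("clade")}

    def leaf(sp):
        return {"age": 0.0, "species": sp}

    def node(age, lineage, children):
        return {"age": age, "lineage": lineage, "children": children}

    def clade_node(age, lineage, clade):
        return node(age, lineage, [leaf(sp) for sp in by_clade[clade]])

    half = config.t_within_clade
    eutheria = node(
        config.t_afrotheria, "Eutheria",
        [
            clade_node(half, "Eutheria", "Afrotheria"),
            node(config.t_euarchontoglires_laurasiatheria, "Eutheria", [
                clade_node(half, "Eutheria", "Laurasiatheria"),
                clade_node(half, "Eutheria", "Euarchontoglires"),
            ]),
        ],
    )
    metatheria = node(config.t_within_metatheria, "Metatheria",
                      [leaf(sp) for sp in by_clade["Metatheria"]])
    return node(config.t_eutheria_metatheria, None, [eutheria, metatheria])


def _evolve(seq: np.ndarray, duration: float, rate_per_site_my: float,
            rng: np.random.Generator) -> np.ndarray:
    """Poisson substitutions with uniform replacement by a different residue."""
    seq = seq.copy()
    n_sub = rng.poisson(rate_per_site_my * duration * len(seq))
    for _ in range(n_sub):
        pos = rng.integers(len(seq))
        choices = _AA[_AA != seq[pos]]
        seq[pos] = rng.choice(choices)
    return seq


def simulate_sequences(truth: SyntheticTruth, config: SimulationConfig,
                       rng: np.random.Generator,
                       gene_ids: Iterable[str] | None = None,
                       n_genes: int = 100, length: int = 450,
                       species: pd.DataFrame | None = None) -> dict:
    """Evolve root proteins along the dated tree at each gene's effective rate.

    Returns species_id -> gene_id -> protein string.  The per-branch per-site
    substitution rate is k * multiplier / 200 per My, so the expected raw
    substitution count between two species separated by time t matches
    PD% = k*t (multiple hits make realized divergence slightly lower at deep
    splits).  Intended for small gene subsets (the slow, sequence-level path).
    """
    species = species if species is not None else default_species_table()
    if gene_ids is None:
        gene_ids = truth.gene_ids[:n_genes]
    index = truth.order_a.rank
    tree = _species_tree(config, species)
    out: dict = {sp: {} for sp in species["species_id"]}

    for gene in gene_ids:
        gi = index[gene]
        root = _AA[rng.integers(len(_AA), size=length)]

        def walk(node, seq, parent_age):
            age = node["age"]
            if "species" in node:
                # terminal branch: lineage of the species
                sp = node["species"]
                lin = CLADE_LINEAGE[
                    species.loc[species["species_id"] == sp, "clade"].iloc[0]
                ]
                rate = truth.k[gi] * truth.multiplier[lin][gi] / 200.0
                out[sp][gene] = "".join(_evolve(seq, parent_age - age, rate, rng))
                return
            lin = node["lineage"]
            if lin is None:  # root: no branch above
                child_seq = seq
            else:
                rate = truth.k[gi] * truth.multiplier[lin][gi] / 200.0
                child_seq = _evolve(seq, parent_age - age, rate, rng)
            for child in node["children"]:
                walk(child, child_seq, age)

        walk(tree, root, tree["age"])
    return out


def write_fastas(sequences: Mapping[str, Mapping[str, str]], directory) -> None:
    """One protein FASTA per species, in the layout core_io reads back."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sp, genes in sequences.items():
        with open(directory / f"{sp}.fa", "w") as fh:
            for gene, seq in sorted(genes.items()):
                fh.write(f">{gene}\n{seq}\n")


def write_study(out_dir, config: SimulationConfig, seed: int = 0,
                with_sequences: bool = False, n_seq_genes: int = 50) -> dict:
    """Generate and write a full synthetic study in core_io's formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    species = default_species_table()
    pairs = build_pair_table(species, default_pair_times(species, config))
    truth = simulate_rates(config, rng)
    matrix = simulate_divergences(truth, pairs, config, rng, species)
    gc, garp = simulate_gc_garp(config, truth, rng, species)

    core_io.write_species_table(species, out / "species.tsv")
    core_io.write_pair_table(pairs, out / "pairs.tsv")
    core_io.write_gene_order(truth.order_a, out / "order_a.tsv")
    core_io.write_gene_order(truth.order_b, out / "order_b.tsv")
    matrix.to_tsv(out / "divergence.tsv")
    gc.rename_axis("gene_id").to_csv(out / "gc_percent.tsv", sep="\t")
    garp.rename_axis("gene_id").to_csv(out / "garp_percent.tsv", sep="\t")
    if with_sequences:
        seqs = simulate_sequences(truth, config, rng, n_genes=n_seq_genes)
        write_fastas(seqs, out / "fasta")
    return {"species": species, "pairs": pairs, "truth": truth,
            "divergence": matrix, "gc": gc, "garp": garp}
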