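"""External formats and run configuration.

Everything the pipeline reads or writes passes through this module: ortholog
FASTA sets, gene-order tables, species/pair tables, landscape and heatmap
TSVs, and the YAML run configuration.  All tables are tab-separated text;
coordinates are 1-based GenBank-style.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .landscape import GenomeOrder, Landscape

__all__ = [
    "RunConfig",
    "CLADE_LINEAGE",
    "OrthologSet",
    "lineage_of",
    "make_species_table",
    "read_species_table",
    "write_species_table",
    "build_pair_table",
    "read_pair_table",
    "write_pair_table",
    "read_gene_order",
    "write_gene_order",
    "read_ortholog_fastas",
    "write_landscape_tsv",
    "read_landscape_tsv",
    "write_heatmap_tsv",
    "read_heatmap_tsv",
]

log = logging.getLogger("clockscape")

#: clade -> lineage; lineage is a deterministic function of clade.
CLADE_LINEAGE = {
    "Laurasiatheria": "Eutheria",
    "Euarchontoglires": "Eutheria",
    "Afrotheria": "Eutheria",
    "Metatheria": "Metatheria",
}

PAIR_CLASSES = ("intra-Eutherian", "Eutherian-Metatherian", "intra-Metatherian")


def lineage_of(clade: str) -> str:
    try:
        return CLADE_LINEAGE[clade]
    except KeyError:
        raise ValueError(f"unknown clade: {clade!r}") from None


@dataclass
class RunConfig:
    """Tunable parameters of one analysis run.

    Defaults are the study's stated values: a 101-gene window (half-width 50),
    a 30% identity floor, three random genome orders, a mean + 3 SD
    acceleration threshold and 50-gene subtelomere margins.
    """

    window_half_width: int = 50
    identity_floor: float = 30.0
    n_random_orders: int = 3
    threshold_sd_multiplier: float = 3.0
    subtelomere_margin: int = 50
    rng_seed: int = 0
    gap_open: float = 12.0
    gap_extend: float = 2.0
    edge_policy: str = "concatenated"

    def __post_init__(self):
        if self.window_half_width < 1:
            raise ValueError("window_half_width must be >= 1")
        if not 0 < self.identity_floor < 100:
            raise ValueError("identity_floor must be in (0, 100)")
        if self.n_random_orders < 1:
            raise ValueError("n_random_orders must be >= 1")
        if self.edge_policy not in ("concatenated", "per-chromosome-truncated"):
            raise ValueError(f"unknown edge_policy: {self.edge_policy!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# species and pair tables
# ---------------------------------------------------------------------------

def make_species_table(species: Iterable[tuple]) -> pd.DataFrame:
    """Build a species table from (species_id, clade) pairs."""
    df = pd.DataFrame(list(species), columns=["species_id", "clade"])
    if df["species_id"].duplicated().any():
        raise ValueError("duplicate species_id in species table")
    df["lineage"] = df["clade"].map(lineage_of)
    return df


def read_species_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["species_id", "clade"], path)
    return make_species_table(zip(df["species_id"], df["clade"]))


def write_species_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _pair_class(lin_a: str, lin_b: str) -> str:
    if lin_a == lin_b == "Eutheria":
        return "intra-Eutherian"
    if lin_a == lin_b == "Metatheria":
        return "intra-Metatherian"
    return "Eutherian-Metatherian"


def build_pair_table(species: pd.DataFrame, times: Mapping[frozenset, float]) -> pd.DataFrame:
    """All unordered species pairs with class and divergence time.

    ``times`` maps ``frozenset({a, b})`` to the time (My) to the last common
    ancestor.  Pairs are numbered 1..P ordered intra-Eutherian first, then
    cross-lineage, then intra-Metatherian (the ordering used for the heatmap
    rows: 1-66, 67-114, 115-120 for the 16-species design).
    """
    lineage = dict(zip(species["species_id"], species["lineage"]))
    rows = []
    ids = list(species["species_id"])
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            t = times[frozenset({a, b})]
            if not t > 0:
                raise ValueError(f"divergence time for ({a}, {b}) must be > 0")
            rows.append((a, b, _pair_class(lineage[a], lineage[b]), float(t)))
    order = {c: i for i, c in enumerate(PAIR_CLASSES)}
    rows.sort(key=lambda r: (order[r[2]], r[0], r[1]))
    df = pd.DataFrame(rows, columns=["species_a", "species_b", "pair_class", "t"])
    df.insert(0, "pair_id", np.arange(1, len(df) + 1))
    return df


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["pair_id", "species_a", "species_b", "pair_class", "t"], path)
    if (df["t"] <= 0).any():
        raise ValueError("divergence times must be > 0")
    return df


def write_pair_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene orders
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_gene_order(path) -> GenomeOrder:
    """Read a gene-order TSV (gene_id, chromosome, start) into a GenomeOrder.

    Genes are ranked by (chromosome in file order of first appearance, start
    ascending, gene_id); an explicit ``rank`` column, when present, is used
    instead of ``start``.  Strand is ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    pos_col = "rank" if "rank" in df.columns else "start"
    _require_columns(df, ["gene_id", "chromosome", pos_col], path)
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    chrom_order = {c: i for i, c in enumerate(df["chromosome"].drop_duplicates())}
    df = df.sort_values(
        by=["chromosome", pos_col, "gene_id"],
        key=lambda col: col.map(chrom_order) if col.name == "chromosome" else col,
        kind="stable",
    )
    gene_ids = tuple(df["gene_id"])
    chromosomes: dict = {}
    start = 0
    for name, group in df.groupby("chromosome", sort=False):
        chromosomes[name] = (start, start + len(group))
        start += len(group)
    return GenomeOrder(gene_ids, chromosomes)


def write_gene_order(order: GenomeOrder, path) -> None:
    """Write a GenomeOrder as TSV; ``start`` is the 1-based within-chromosome
    position so the file round-trips through :func:`read_gene_order`."""
    chrom = order.chromosome_of()
    starts = np.empty(order.n_genes, dtype=int)
    for name, (lo, hi) in order.chromosomes.items():
        starts[lo:hi] = np.arange(1, hi - lo + 1)
    pd.DataFrame(
        {"gene_id": order.gene_ids, "chromosome": chrom, "start": starts}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ortholog FASTA sets
# ---------------------------------------------------------------------------

@dataclass
class OrthologSet:
    """gene_id -> species_id -> sequence, for proteins and (optionally) CDS."""

    proteins: dict
    cds: dict = field(default_factory=dict)
    species: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list:
        return sorted(self.proteins)

    def species_with(self, gene_id: str) -> list:
        return sorted(self.proteins.get(gene_id, {}))


def _parse_species_fasta(path: Path, species_id: str) -> dict:
    out: dict = {}
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # malformed file
        raise ValueError(f"unparseable FASTA {path}: {exc}") from exc
    for rec in records:
        if not rec.id:
            raise ValueError(f"unparseable FASTA {path}: record without id")
        if rec.id in out:
            raise ValueError(
                f"duplicate gene id {rec.id!r} for species {species_id!r} in {path}"
            )
        out[rec.id] = str(rec.seq).upper()
    return out


def read_ortholog_fastas(directory, species: pd.DataFrame) -> OrthologSet:
    """Read one protein FASTA per species (``<species_id>.fa[a|sta]``).

    Optional CDS files ``<species_id>.cds.fa[sta]`` are attached when present.
    Genes present in only one lineage are dropped (lineage-specific genes are
    excluded from the common set); missing species per gene are allowed.
    """
    directory = Path(directory)
    lineage = dict(zip(species["species_id"], species["lineage"]))
    proteins: dict = {}
    cds: dict = {}
    n_files = 0
    for sp in species["species_id"]:
        path = next(
            (directory / f"{sp}{ext}" for ext in (".fa", ".faa", ".fasta")
             if (directory / f"{sp}{ext}").exists()),
            None,
        )
        if path is None:
            continue
        n_files += 1
        for gene, seq in _parse_species_fasta(path, sp).items():
            proteins.setdefault(gene, {})[sp] = seq
        cpath = next(
            (directory / f"{sp}.cds{ext}" for ext in (".fa", ".fasta")
             if (directory / f"{sp}.cds{ext}").exists()),
            None,
        )
        if cpath is not None:
            for gene, seq in _parse_species_fasta(cpath, sp).items():
                cds.setdefault(gene, {})[sp] = seq
    if n_files == 0:
        raise ValueError(f"no species FASTAs found in {directory}")

    kept, dropped = {}, 0
    for gene, per_species in proteins.items():
        lineages = {lineage[sp] for sp in per_species if sp in lineage}
        if {"Eutheria", "Metatheria"} <= lineages:
            kept[gene] = per_species
        else:
            dropped += 1
    if dropped:
        log.info("excluded %d lineage-specific gene(s)", dropped)
    return OrthologSet(
        proteins=kept,
        cds={g: v for g, v in cds.items() if g in kept},
        species=species,
    )


# ---------------------------------------------------------------------------
# landscape / heatmap TSVs
# ---------------------------------------------------------------------------

def write_landscape_tsv(landscape: Landscape, path) -> None:
    order = landscape.order
    if len(landscape.values) != order.n_genes:
        raise ValueError("length mismatch between values and order")
    pd.DataFrame(
        {
            "gene_id": order.gene_ids,
            "chromosome": order.chromosome_of(),
            "rank": np.arange(order.n_genes),
            "value": landscape.values,
        }
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_landscape_tsv(path, order: GenomeOrder | None = None) -> Landscape:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"gene_id": str, "chromosome": str})
    _require_columns(df, ["gene_id", "chromosome", "rank", "value"], path)
    df = df.sort_values("rank", kind="stable")
    if order is None:
        chromosomes: dict = {}
        start = 0
        for name, group in df.groupby("chromosome", sort=False):
            chromosomes[name] = (start, start + len(group))
            start += len(group)
        order = GenomeOrder(tuple(df["gene_id"]), chromosomes)
    elif tuple(df["gene_id"]) != order.gene_ids:
        raise ValueError(f"{path}: gene ids do not match the given order")
    return Landscape(order, df["value"].to_numpy(dtype=float))


def write_heatmap_tsv(matrix: np.ndarray, order: GenomeOrder, track_names: Sequence, path) -> None:
    """Write a (tracks x ranks) heatmap as TSV, one value column per track,
    with gene/chromosome annotations so chromosome boundaries are recoverable."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(track_names), order.n_genes):
        raise ValueError("length mismatch between matrix and order/tracks")
    df = pd.DataFrame(
        {
            "gene_id": order.gene_ids,
            "chromosome": order.chromosome_of(),
            "rank": np.arange(order.n_genes),
        }
    )
    for name, row in zip(track_names, matrix):
        df[str(name)] = row
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_heatmap_tsv(path) -> tuple:
    """Read a heatmap TSV back into (matrix, order, track_names)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"gene_id": str, "chromosome": str})
    _require_columns(df, ["gene_id", "chromosome", "rank"], path)
    df = df.sort_values("rank", kind="stable")
    chromosomes: dict = {}
    start = 0
    for name, group in df.groupby("chromosome", sort=False):
        chromosomes[name] = (start, start + len(group))
        start += len(group)
    order = GenomeOrder(tuple(df["gene_id"]), chromosomes)
    track_names = [c for c in df.columns if c not in ("gene_id", "chromosome", "rank")]
    matrix = df[track_names].to_numpy(dtype=float).T
    return matrix, order, track_names
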