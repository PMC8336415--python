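"""Cross-genome concordance of accelerated subtelomeric genes.

A gene set (typically the accelerated genes of one lineage) is mapped between
two reference genome orders; each shared gene becomes a link colored green
when it is subtelomeric in both orders and black otherwise (the Circos
convention).  The green fraction measures whether subtelomeric regions stayed
subtelomeric across karyotype rearrangements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .acceleration import subtelomere_labels
from .landscape import GenomeOrder

__all__ = [
    "GeneLink",
    "map_genes_between_orders",
    "concordance_summary",
    "export_links",
    "read_links",
]

log = logging.getLogger("clockscape")


@dataclass(frozen=True)
class GeneLink:
    gene_id: str
    chrom_a: str
    rank_a: int
    chrom_b: str
    rank_b: int
    subtel_a: bool
    subtel_b: bool

    @property
    def color(self) -> str:
        return "green" if (self.subtel_a and self.subtel_b) else "black"


def map_genes_between_orders(genes, order_a: GenomeOrder, order_b: GenomeOrder,
                             margin: int = 50) -> list:
    """One GeneLink per gene present in both orders (others dropped, logged)."""
    sub_a = subtelomere_labels(order_a, margin)
    sub_b = subtelomere_labels(order_b, margin)
    chrom_a = order_a.chromosome_of()
    chrom_b = order_b.chromosome_of()
    rank_a, rank_b = order_a.rank, order_b.rank
    links = []
    dropped = 0
    for gene in sorted(set(genes)):
        ra, rb = rank_a.get(gene), rank_b.get(gene)
        if ra is None or rb is None:
            dropped += 1
            continue
        links.append(GeneLink(gene, chrom_a[ra], ra, chrom_b[rb], rb,
                              bool(sub_a[ra]), bool(sub_b[rb])))
    if dropped:
        log.info("dropped %d gene(s) absent from one order", dropped)
    if not links:
        raise ValueError("no genes shared between the two orders")
    return links


def concordance_summary(links) -> tuple:
    """(n_green, n_black, green fraction)."""
    if len(links) == 0:
        raise ValueError("no links")
    n_green = sum(1 for l in links if l.color == "green")
    n_black = len(links) - n_green
    return (n_green, n_black, n_green / len(links))


_LINK_COLUMNS = ["gene_id", "chrom_a", "start_a", "end_a",
                 "chrom_b", "start_b", "end_b", "color",
                 "subtel_a", "subtel_b"]


def export_links(links, path) -> None:
    """Write Circos-style link records (tab-separated, one line per link).

    Coordinates are gene ranks (half-open, one gene wide); the color attribute
    carries the green/black concordance classification, and the per-side
    subtelomere flags make the file round-trip exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(_LINK_COLUMNS) + "\n")
        for l in links:
            fh.write("\t".join(map(str, (
                l.gene_id, l.chrom_a, l.rank_a, l.rank_a + 1,
                l.chrom_b, l.rank_b, l.rank_b + 1, l.color,
                int(l.subtel_a), int(l.subtel_b),
            ))) + "\n")


def read_links(path) -> list:
    """Round-trip reader for :func:`export_links` output."""
    links = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            (gene, ca, sa, _ea, cb, sb, _eb, _color,
             sub_a, sub_b) = line.rstrip("\n").split("\t")
            links.append(GeneLink(gene, ca, int(sa), cb, int(sb),
                                  bool(int(sub_a)), bool(int(sub_b))))
    return links
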