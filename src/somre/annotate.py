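"""Strand-aware gene and promoter annotation of insertion coordinates.

The promoter of a gene is the 5,000 bp immediately upstream of its
transcription start site on the gene's strand, clipped at chromosome
bounds.  An insertion point falling in a gene body is "genic"; one
falling only in a promoter window is "promoter"; anything else is
intergenic (genic takes precedence so the compartments partition the
genome).  Orientation is defined inside genic/promoter compartments:
co-oriented means the inserted element's strand equals the gene strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

PROMOTER_SPAN = 5_000


@dataclass(frozen=True)
class Gene:
    chrom: str
    start: int
    end: int
    name: str
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def promoter(self) -> tuple[int, int]:
        if self.strand == "+":
            return max(0, self.start - PROMOTER_SPAN), self.start
        return self.end, self.end + PROMOTER_SPAN


class AnnotationIndex:
    """Interval index over gene bodies and derived promoter windows."""

    def __init__(
        self, genes: pd.DataFrame, chrom_lengths: dict[str, int] | None = None
    ):
        self.gene_trees: dict[str, IntervalTree] = {}
        self.promoter_trees: dict[str, IntervalTree] = {}
        self.chrom_lengths = chrom_lengths or {}
        for _, row in genes.iterrows():
            strand = row.get("strand")
            if strand not in ("+", "-"):
                raise ValueError(
                    f"gene record {row.get('name', '?')} lacks a strand"
                )
            gene = Gene(row["chrom"], int(row["start"]), int(row["end"]),
                        str(row.get("name", ".")), strand)
            gt = self.gene_trees.setdefault(gene.chrom, IntervalTree())
            gt.addi(gene.start, gene.end, gene)
            ps, pe = gene.promoter
            limit = self.chrom_lengths.get(gene.chrom)
            if limit is not None:
                pe = min(pe, limit)
            if pe > ps:
                pt = self.promoter_trees.setdefault(gene.chrom, IntervalTree())
                pt.addi(ps, pe, gene)
        self._warned_chroms: set[str] = set()

    def query(self, chrom: str, position: int) -> tuple[str, Gene | None]:
        """Compartment of a point: genic > promoter > intergenic."""
        if chrom not in self.gene_trees and chrom not in self.promoter_trees:
            if chrom not in self._warned_chroms:
                logger.warning("chromosome %s absent from annotation", chrom)
                self._warned_chroms.add(chrom)
            return "intergenic", None
        hits = self.gene_trees.get(chrom, IntervalTree())[position]
        if hits:
            gene = min(hits, key=lambda iv: (iv.begin, iv.data.name)).data
            return "genic", gene
        hits = self.promoter_trees.get(chrom, IntervalTree())[position]
        if hits:
            gene = min(hits, key=lambda iv: (iv.begin, iv.data.name)).data
            return "promoter", gene
        return "intergenic", None

    def union_boundaries(self, which: str) -> dict[str, np.ndarray]:
        """Merged-interval boundaries per chromosome (for fast membership)."""
        trees = self.gene_trees if which == "genic" else self.promoter_trees
        out = {}
        for chrom, tree in trees.items():
            merged = tree.copy()
            merged.merge_overlaps(strict=False)
            ivs = sorted(merged)
            out[chrom] = np.array(
                [b for iv in ivs for b in (iv.begin, iv.end)], dtype=np.int64
            )
        return out


def build_index(
    genes: pd.DataFrame, chrom_lengths: dict[str, int] | None = None
) -> AnnotationIndex:
    """Build the annotation index from a BED6-style gene frame."""
    return AnnotationIndex(genes, chrom_lengths)


@dataclass
class LocatedInsertion:
    chrom: str
    position: int
    strand: str
    compartment: str  # genic | promoter | intergenic
    orientation: str  # co | counter | na
    gene: str | None


def locate(
    insertions: list, index: AnnotationIndex
) -> tuple[list[LocatedInsertion], dict[str, int]]:
    """Annotate insertion loci with compartment and orientation.

    ``insertions`` may be any objects with ``chrom``, ``position`` and
    ``strand`` attributes.  Returns the located records plus compartment
    and orientation tallies.
    """
    located = []
    tallies = {
        "genic": 0, "promoter": 0, "intergenic": 0,
        "genic_co": 0, "genic_counter": 0,
        "promoter_co": 0, "promoter_counter": 0,
    }
    for ins in insertions:
        compartment, gene = index.query(ins.chrom, ins.position)
        if gene is None:
            orientation = "na"
        else:
            orientation = "co" if ins.strand == gene.strand else "counter"
        tallies[compartment] += 1
        if compartment in ("genic", "promoter"):
            tallies[f"{compartment}_{orientation}"] += 1
        located.append(
            LocatedInsertion(
                ins.chrom, ins.position, ins.strand, compartment, orientation,
                gene.name if gene else None,
            )
        )
    return located, tallies


def located_frame(located: list[LocatedInsertion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": l.chrom,
                "position": l.position,
                "strand": l.strand,
                "compartment": l.compartment,
                "orientation": l.orientation,
                "gene": l.gene,
            }
            for l in located
        ],
        columns=["chrom", "position", "strand", "compartment", "orientation", "gene"],
    )
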