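"""Associate DE lncRNAs with overlapping or nearby protein-coding genes.

A gene within ``window_bp`` (default 5000, inclusive) of a DE lncRNA on
the same chromosome becomes a "lncGene". Distances are measured between
gene spans on 1-based inclusive coordinates: overlapping spans have
distance 0 and adjacent spans (...-100 / 101-...) have distance 1.
Association is strand-agnostic; the gene's strand only labels the
relation (a lncRNA 5' of the gene is "upstream").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from lncora.annotations import GenomicFeature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationRecord:
    lncrna_id: str
    gene_id: str
    relation: str  # overlap | upstream | downstream
    distance: int  # 0 for overlap
    window_bp: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if (self.relation == "overlap") != (self.distance == 0):
            raise ValueError("relation 'overlap' iff distance == 0")
        if self.distance > self.window_bp:
            raise ValueError("distance exceeds window")


@dataclass
class LncGeneSet:
    """Unique lncGene identifiers with their supporting associations and
    the deduplicated count ``r`` used by the augmented enrichment test."""

    genes: dict[str, list[AssociationRecord]] = field(default_factory=dict)
    r: int = 0
    dedup: str = "subtract_de"

    @property
    def gene_ids(self) -> set[str]:
        return set(self.genes)


def interval_distance(a: GenomicFeature, b: GenomicFeature) -> int | None:
    """Gap in bp between two features; 0 if they overlap, None if they are
    on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.start <= b.end and b.start <= a.end:
        return 0
    if a.end < b.start:
        return b.start - a.end
    return a.start - b.end


def _relation(lnc: GenomicFeature, gene: GenomicFeature, distance: int) -> str:
    if distance == 0:
        return "overlap"
    lnc_is_left = lnc.end < gene.start
    if gene.strand == "-":
        return "downstream" if lnc_is_left else "upstream"
    return "upstream" if lnc_is_left else "downstream"


def find_associations(
    lncrnas: list[GenomicFeature],
    genes: list[GenomicFeature],
    window_bp: int = 5000,
) -> list[AssociationRecord]:
    """All (lncRNA, gene) pairs with distance <= window_bp (inclusive) on
    the same chromosome."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    if not genes:
        logger.warning("find_associations: empty gene list")
        return []
    by_chrom: dict[str, list[GenomicFeature]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    arrays = {
        chrom: (
            np.array([g.start for g in glist], dtype=np.int64),
            np.array([g.end for g in glist], dtype=np.int64),
        )
        for chrom, glist in by_chrom.items()
    }
    records: list[AssociationRecord] = []
    for lnc in lncrnas:
        entry = arrays.get(lnc.chrom)
        if entry is None:
            continue
        starts, ends = entry
        # gap is 0 for overlap, else distance between nearest span ends
        gaps = np.maximum(
            0, np.maximum(starts - lnc.end, lnc.start - ends)
        )
        for idx in np.nonzero(gaps <= window_bp)[0]:
            gene = by_chrom[lnc.chrom][idx]
            dist = int(gaps[idx])
            records.append(
                AssociationRecord(
                    lncrna_id=lnc.feature_id,
                    gene_id=gene.feature_id,
                    relation=_relation(lnc, gene, dist),
                    distance=dist,
                    window_bp=window_bp,
                )
            )
    logger.info(
        "find_associations: %d pairs within %d bp (%d lncRNAs vs %d genes)",
        len(records), window_bp, len(lncrnas), len(genes),
    )
    return records


def derive_lncgenes(
    associations: list[AssociationRecord],
    de_genes: set[str] | frozenset[str] = frozenset(),
    dedup: str = "subtract_de",
) -> LncGeneSet:
    """Collapse associations to the unique lncGene set.

    Under the default ``subtract_de`` policy, genes already in the DE list
    do not count toward ``r`` (so no gene is drawn twice in the augmented
    test); ``keep_all`` counts every unique associated gene.
    """
    if dedup not in {"subtract_de", "keep_all"}:
        raise ValueError(f"unknown dedup policy: {dedup!r}")
    genes: dict[str, list[AssociationRecord]] = {}
    for rec in associations:
        genes.setdefault(rec.gene_id, []).append(rec)
    if dedup == "subtract_de":
        counted = set(genes) - set(de_genes)
    else:
        counted = set(genes)
    return LncGeneSet(genes=genes, r=len(counted), dedup=dedup)


def lncgene_ids_for_enrichment(lncgene_set: LncGeneSet, de_genes: set[str]) -> set[str]:
    """lncGene identifiers that enter the augmented test (excludes DE genes
    under subtract_de)."""
    if lncgene_set.dedup == "subtract_de":
        return lncgene_set.gene_ids - set(de_genes)
    return lncgene_set.gene_ids


def associations_to_rows(associations: list[AssociationRecord]) -> list[dict]:
    return [
        {
            "lncrna_id": a.lncrna_id,
            "gene_id": a.gene_id,
            "relation": a.relation,
            "distance": a.distance,
        }
        for a in associations
    ]
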