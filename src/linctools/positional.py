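"""Positional classification of lncRNA genes against coding genes.

A lncRNA gene is *genic* when any of its transcripts overlaps a coding gene,
*intergenic* (a lincRNA) when it does not overlap but a coding gene lies
within the window ``W`` (default 100 kb), and *non-neighboring* when no
coding gene is that close. Intergenic genes get their nearest coding
neighbor, a sense/antisense orientation and, for antisense, a
divergent/convergent/both subtype from the 5'/3' geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .annotation import (
    STRAND_UNKNOWN,
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    edge_distance,
)

CATEGORY_GENIC = "genic"
CATEGORY_INTERGENIC = "intergenic"
CATEGORY_NON_NEIGHBORING = "non_neighboring"

ORIENT_SENSE = "sense"
ORIENT_ANTISENSE = "antisense"
ORIENT_UNKNOWN = "unknown"

SUBTYPE_DIVERGENT = "divergent"
SUBTYPE_CONVERGENT = "convergent"
SUBTYPE_BOTH = "both"
SUBTYPE_NA = "n/a"


@dataclass
class PositionalClass:
    lnc_gene_id: str
    category: str
    neighbor_gene_id: str | None = None
    distance_bp: int | None = None
    orientation: str = ORIENT_UNKNOWN
    antisense_subtype: str = SUBTYPE_NA


def _overlaps_coding(
    lnc: GeneModel, coding: GenomeAnnotation, level: str = "span"
) -> bool:
    if level == "span":
        for t in lnc.transcripts:
            s, e = t.span
            if coding.overlapping(lnc.seq_id, s, e):
                return True
        return False
    if level == "exon":
        for t in lnc.transcripts:
            for s, e in t.exons:
                if coding.overlapping(lnc.seq_id, s, e):
                    return True
        return False
    raise ValueError(f"unknown overlap level {level!r}")


def _transcript_subtype(tx: TranscriptModel, neighbor: GeneModel) -> str:
    """Divergent/convergent geometry of one antisense transcript vs its neighbor.

    Divergent = head-to-head (5' ends face each other), convergent =
    tail-to-tail; decided from which side the transcript lies and its strand,
    requiring both strands known and opposite.
    """
    if tx.strand == STRAND_UNKNOWN or neighbor.strand == STRAND_UNKNOWN:
        return SUBTYPE_NA
    if tx.strand == neighbor.strand:
        return SUBTYPE_NA
    ts, te = tx.span
    ns, ne = neighbor.span
    tx_left = (ts + te) / 2 < (ns + ne) / 2
    if tx_left:
        # <-- tx ... neighbor --> is head-to-head
        return SUBTYPE_DIVERGENT if tx.strand == "-" else SUBTYPE_CONVERGENT
    return SUBTYPE_DIVERGENT if tx.strand == "+" else SUBTYPE_CONVERGENT


def orientation(
    linc: GeneModel, neighbor: GeneModel
) -> tuple[str, str]:
    """Gene-level orientation and antisense subtype of an intergenic lncRNA."""
    if linc.strand == STRAND_UNKNOWN or neighbor.strand == STRAND_UNKNOWN:
        return ORIENT_UNKNOWN, SUBTYPE_NA
    if linc.strand == neighbor.strand:
        return ORIENT_SENSE, SUBTYPE_NA
    subtypes = {
        _transcript_subtype(t, neighbor)
        for t in linc.transcripts
        if t.strand != STRAND_UNKNOWN and t.strand != neighbor.strand
    }
    subtypes.discard(SUBTYPE_NA)
    if not subtypes:
        return ORIENT_ANTISENSE, SUBTYPE_NA
    if len(subtypes) == 2:
        return ORIENT_ANTISENSE, SUBTYPE_BOTH
    return ORIENT_ANTISENSE, subtypes.pop()


def classify(
    lnc_genes: Iterable[GeneModel] | GenomeAnnotation,
    coding_annotation: GenomeAnnotation,
    W: int = 100_000,
    overlap_level: str = "span",
) -> list[PositionalClass]:
    """Assign every lncRNA gene exactly one positional category.

    Genic takes precedence over intergenic; the nearest coding gene is by
    edge-to-edge span distance on the same scaffold (any strand), ties broken
    by smaller gene_id.
    """
    if W <= 0:
        raise ValueError("window W must be positive")
    if isinstance(lnc_genes, GenomeAnnotation):
        lnc_genes = [lnc_genes.genes[g] for g in sorted(lnc_genes.genes)]
    out: list[PositionalClass] = []
    for lnc in lnc_genes:
        if _overlaps_coding(lnc, coding_annotation, level=overlap_level):
            out.append(PositionalClass(lnc.gene_id, CATEGORY_GENIC))
            continue
        s, e = lnc.span
        hit = coding_annotation.nearest(lnc.seq_id, s, e)
        if hit is None:
            out.append(PositionalClass(lnc.gene_id, CATEGORY_NON_NEIGHBORING))
            continue
        neighbor_id, dist = hit
        if dist > W:
            out.append(PositionalClass(lnc.gene_id, CATEGORY_NON_NEIGHBORING))
            continue
        neighbor = coding_annotation.genes[neighbor_id]
        orient, subtype = orientation(lnc, neighbor)
        out.append(
            PositionalClass(
                lnc_gene_id=lnc.gene_id,
                category=CATEGORY_INTERGENIC,
                neighbor_gene_id=neighbor_id,
                distance_bp=dist,
                orientation=orient,
                antisense_subtype=subtype,
            )
        )
    return out


def category_counts(classes: Iterable[PositionalClass]) -> dict[str, int]:
    """Summary counts of categories, orientations and antisense subtypes."""
    classes = list(classes)
    counts = {
        "total": len(classes),
        CATEGORY_GENIC: 0,
        CATEGORY_INTERGENIC: 0,
        CATEGORY_NON_NEIGHBORING: 0,
        ORIENT_SENSE: 0,
        ORIENT_ANTISENSE: 0,
        ORIENT_UNKNOWN: 0,
        SUBTYPE_DIVERGENT: 0,
        SUBTYPE_CONVERGENT: 0,
        SUBTYPE_BOTH: 0,
    }
    for c in classes:
        counts[c.category] += 1
        if c.category == CATEGORY_INTERGENIC:
            counts[c.orientation] += 1
            if c.orientation == ORIENT_ANTISENSE and c.antisense_subtype != SUBTYPE_NA:
                counts[c.antisense_subtype] += 1
    return counts


def classes_to_frame(classes: Iterable[PositionalClass]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_gene_id": c.lnc_gene_id,
                "category": c.category,
                "neighbor": c.neighbor_gene_id,
                "distance": c.distance_bp,
                "orientation": c.orientation,
                "subtype": c.antisense_subtype,
            }
            for c in classes
        ]
    )


def neighbor_map(classes: Iterable[PositionalClass]) -> dict[str, str]:
    """lnc gene id -> assigned coding neighbor, for intergenic genes."""
    return {
        c.lnc_gene_id: c.neighbor_gene_id
        for c in classes
        if c.category == CATEGORY_INTERGENIC and c.neighbor_gene_id is not None
    }
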