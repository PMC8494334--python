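"""Genomic-context classification of TE loci and closest-gene linking.

A TE copy is labelled hierarchically and exhaustively: ``Exonic`` if it
overlaps any exon by at least 1 bp, otherwise ``Intronic`` if it
overlaps any gene span (min exon start to max exon end), otherwise
``Intergenic``.  Overlap is strand-blind by default.  Intergenic copies
are linked to the nearest gene with a signed gap distance (negative
when the TE lies upstream of the gene start, i.e. to its left in
genome coordinates); ties go to the lexicographically smallest gene id
and are logged.  Book-ended (touching, non-overlapping) intervals are
reported at distance 1, the minimum separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from telocus.synth import Gene, TEAnnotation

logger = logging.getLogger("telocus.context")

__all__ = ["ContextLink", "GeneIntervals", "classify_context", "link_closest", "classify_all"]

CONTEXTS = ("Exonic", "Intronic", "Intergenic")


@dataclass(slots=True)
class ContextLink:
    te_id: str
    context: str
    gene_id: str
    distance: int  # 0 for overlapping; signed gap for intergenic


class GeneIntervals:
    """Interval indexes over exons and gene spans, built once per gene set."""

    def __init__(self, genes: Sequence[Gene], stranded: bool = False):
        self.genes = list(genes)
        self.stranded = stranded
        self.exons: dict[str, IntervalTree] = {}
        self.spans: dict[str, IntervalTree] = {}
        for g in self.genes:
            for s, e in g.exons:
                self.exons.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
            self.spans.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def _hits(self, trees: dict[str, IntervalTree], te: TEAnnotation) -> list[Gene]:
        tree = trees.get(te.chrom)
        if tree is None:
            return []
        out = [iv.data for iv in tree.overlap(te.start, te.end)]
        if self.stranded:
            out = [g for g in out if g.strand == te.strand]
        return sorted(out, key=lambda g: g.gene_id)


def classify_context(te: TEAnnotation, genes: Sequence[Gene] | GeneIntervals) -> str:
    """Exonic > Intronic > Intergenic, in that priority order."""
    gi = genes if isinstance(genes, GeneIntervals) else GeneIntervals(genes)
    if gi._hits(gi.exons, te):
        return "Exonic"
    if gi._hits(gi.spans, te):
        return "Intronic"
    return "Intergenic"


def _signed_gap(te: TEAnnotation, g: Gene) -> int:
    """Signed bp separation; negative = TE upstream of the gene start."""
    if te.end <= g.start:
        return -max(g.start - te.end, 1)
    if g.end <= te.start:
        return max(te.start - g.end, 1)
    return 0


def link_closest(te: TEAnnotation, genes: Sequence[Gene]) -> tuple[str, int]:
    """Nearest gene (by interval gap, any chromosome-mate) for an intergenic TE."""
    same_chrom = [g for g in genes if g.chrom == te.chrom]
    if not same_chrom:
        raise ValueError(f"no gene on {te.chrom} to link {te.te_id}")
    best: tuple[int, str] | None = None
    tied = False
    for g in sorted(same_chrom, key=lambda g: g.gene_id):
        d = _signed_gap(te, g)
        if best is None or abs(d) < abs(best[0]):
            best = (d, g.gene_id)
            tied = False
        elif abs(d) == abs(best[0]) and g.gene_id != best[1]:
            tied = True
    assert best is not None
    if tied:
        logger.info("closest-gene tie for %s at |d|=%d; kept %s", te.te_id, abs(best[0]), best[1])
    return best[1], best[0]


def classify_all(
    tes: Sequence[TEAnnotation],
    genes: Sequence[Gene],
    stranded: bool = False,
) -> list[ContextLink]:
    """Context label plus linked gene for every TE.

    Exonic/Intronic TEs are linked to the (lexicographically smallest)
    overlapped gene at distance 0; intergenic TEs to the closest gene
    by signed gap.  Intergenic TEs on gene-free chromosomes keep an
    empty gene link.
    """
    gi = GeneIntervals(genes, stranded=stranded)
    links = []
    for te in tes:
        ex = gi._hits(gi.exons, te)
        if ex:
            links.append(ContextLink(te.te_id, "Exonic", ex[0].gene_id, 0))
            continue
        sp = gi._hits(gi.spans, te)
        if sp:
            links.append(ContextLink(te.te_id, "Intronic", sp[0].gene_id, 0))
            continue
        try:
            gid, d = link_closest(te, genes)
        except ValueError:
            gid, d = "", 0
        links.append(ContextLink(te.te_id, "Intergenic", gid, d))
    return links
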