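"""Peak-to-gene annotation.

Implements the linkage rule used for the JunD cistromes: a peak is assigned
to a gene if its midpoint lies within a fixed window (default 20 kb) upstream
of the gene's transcriptional start site, or if the peak overlaps the gene
body by at least one base. Linked peaks are classified into genomic features
(exon / intron / promoter), unlinked peaks into upstream (10-50 kb) or
intergenic, and every peak gets a signed distance to the nearest TSS.

Coordinates are 0-based half-open throughout; strand is respected, so
"upstream" always means 5' of the TSS in the gene's own orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .peaks import Peak

log = logging.getLogger(__name__)

FEATURES = ("promoter", "upstream", "exon", "intron", "intergenic")
#: peaks linked to a gene carry one of these features
LINKED_FEATURES = frozenset({"promoter", "exon", "intron"})


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval with exon structure.

    ``tss`` is the strand-dependent 5' end: ``start`` for + genes,
    ``end - 1`` for - genes.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside gene body")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PeakAnnotation:
    """Assignment of one peak to (at most) one gene with a feature label.

    ``dist_to_tss`` is measured from the peak midpoint to the TSS of the
    annotated gene (or the nearest gene for intergenic peaks); negative
    values are upstream of the TSS in the gene's orientation.
    """

    peak_id: str
    gene_id: Optional[str]
    feature: str
    dist_to_tss: Optional[int]
    linked: bool


def _signed_dist(midpoint: int, gene: GeneModel) -> int:
    """Signed midpoint-to-TSS distance; negative = upstream of the gene."""
    return midpoint - gene.tss if gene.strand == "+" else gene.tss - midpoint


def _midpoint(peak: Peak) -> int:
    return (peak.start + peak.end) // 2


def _overlaps_body(peak: Peak, gene: GeneModel) -> bool:
    return peak.chrom == gene.chrom and peak.start < gene.end and gene.start < peak.end


def _overlaps_exon(peak: Peak, gene: GeneModel) -> bool:
    return any(peak.start < e and s < peak.end for s, e in gene.exons)


def classify_feature(peak: Peak, gene: Optional[GeneModel],
                     promoter_window: int = 20_000,
                     upstream_range: tuple[int, int] = (10_000, 50_000)) -> str:
    """Feature label for a peak relative to its assigned gene.

    Precedence: exon > intron > promoter (0 to ``promoter_window`` bp
    upstream of the TSS) > upstream (``upstream_range`` bp upstream) >
    intergenic. The declared promoter and upstream windows overlap between
    10 and 20 kb upstream; promoter wins there by precedence.
    """
    if gene is None:
        return "intergenic"
    if _overlaps_body(peak, gene):
        return "exon" if _overlaps_exon(peak, gene) else "intron"
    d = _signed_dist(_midpoint(peak), gene)
    if -promoter_window <= d <= 0:
        return "promoter"
    lo, hi = upstream_range
    if -hi <= d <= -lo:
        return "upstream"
    return "intergenic"


def distance_to_tss(peak: Peak, genes: Sequence[GeneModel]) -> tuple[str, int]:
    """Nearest-TSS gene and signed midpoint distance (ties: lexicographic id)."""
    if not genes:
        raise ValueError("need at least one gene")
    mid = _midpoint(peak)
    same_chrom = [g for g in genes if g.chrom == peak.chrom]
    if not same_chrom:
        raise ValueError(f"no gene on chromosome {peak.chrom}")
    best = min(same_chrom, key=lambda g: (abs(_signed_dist(mid, g)), g.gene_id))
    return best.gene_id, _signed_dist(mid, best)


def link_peaks_to_genes(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                        tss_window: int = 20_000,
                        promoter_window: int = 20_000,
                        upstream_range: tuple[int, int] = (10_000, 50_000)
                        ) -> list[PeakAnnotation]:
    """Assign peaks to genes by the TSS-window / gene-body rule.

    A peak is linked iff its midpoint lies within ``tss_window`` bp upstream
    of a TSS (strand-aware) or it overlaps a gene body by >= 1 bp. When
    several genes qualify, gene priority applies: gene-body overlap beats a
    promoter hit, then smallest absolute TSS distance, then lexicographic
    gene id. Unlinked peaks are classified upstream (10-50 kb) when a TSS is
    in range, otherwise intergenic; intergenic peaks still report the
    distance to the nearest TSS when any gene exists.
    """
    if not genes:
        log.info("no genes supplied; all %d peaks annotated intergenic", len(peaks))
        return [PeakAnnotation(p.peak_id, None, "intergenic", None, False) for p in peaks]

    by_chrom: dict[str, list[GeneModel]] = {}
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    out: list[PeakAnnotation] = []
    for p in peaks:
        mid = _midpoint(p)
        chrom_genes = by_chrom.get(p.chrom, [])
        body_hits = sorted((iv.data for iv in trees[p.chrom].overlap(p.start, p.end)),
                           key=lambda g: (abs(_signed_dist(mid, g)), g.gene_id)) \
            if p.chrom in trees else []
        promoter_hits = sorted(
            (g for g in chrom_genes if -tss_window <= _signed_dist(mid, g) <= 0),
            key=lambda g: (abs(_signed_dist(mid, g)), g.gene_id))
        if body_hits:
            gene = body_hits[0]
        elif promoter_hits:
            gene = promoter_hits[0]
        else:
            gene = None

        if gene is not None:
            feature = classify_feature(p, gene, promoter_window, upstream_range)
            out.append(PeakAnnotation(p.peak_id, gene.gene_id, feature,
                                      _signed_dist(mid, gene), True))
            continue

        lo, hi = upstream_range
        upstream_hits = sorted(
            (g for g in chrom_genes if -hi <= _signed_dist(mid, g) <= -lo),
            key=lambda g: (abs(_signed_dist(mid, g)), g.gene_id))
        if upstream_hits:
            g = upstream_hits[0]
            out.append(PeakAnnotation(p.peak_id, g.gene_id, "upstream",
                                      _signed_dist(mid, g), False))
        else:
            dist = distance_to_tss(p, genes)[1] if chrom_genes else None
            out.append(PeakAnnotation(p.peak_id, None, "intergenic", dist, False))
    return out


def linked_gene_sets(annotations: Iterable[PeakAnnotation]) -> dict[str, list[str]]:
    """Map linked gene id -> peak ids, the per-gene binding evidence."""
    out: dict[str, list[str]] = {}
    for a in annotations:
        if a.linked and a.gene_id is not None:
            out.setdefault(a.gene_id, []).append(a.peak_id)
    return out


def percent_reduction(a: float, b: float) -> Optional[int]:
    """100*(1 - b/a) rounded half-up to the nearest integer; None if a == 0."""
    if a == 0:
        return None
    from .util import round_half_up
    return int(round_half_up(100.0 * (1.0 - b / a), 0))


def summarize_linkage(annotation_sets: Mapping[str, Sequence[PeakAnnotation]]) -> pd.DataFrame:
    """Per-dataset peak/gene counts in cistrome-summary form.

    Columns: total peaks, peaks linked to a gene, distinct genes with at
    least one peak — one row per named annotation set.
    """
    rows = []
    for name, anns in annotation_sets.items():
        linked = [a for a in anns if a.linked]
        rows.append({
            "dataset": name,
            "total_peaks": len(list(anns)),
            "linked_peaks": len(linked),
            "genes_with_peak": len({a.gene_id for a in linked}),
        })
    return pd.DataFrame(rows).set_index("dataset")
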