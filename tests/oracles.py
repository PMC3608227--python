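"""Independent brute-force reference implementations used to check the
library. These deliberately share no code with the package: plain loops,
literal rule statements, scipy per-gene calls."""

from __future__ import annotations

import numpy as np
from scipy import stats

from tftargets.annotation import GeneModel
from tftargets.peaks import Peak


def union_intervals(intervals):
    """Literal union of half-open intervals per chromosome by sweeping."""
    by_chrom = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def annotate_peak_bruteforce(peak: Peak, genes: list[GeneModel],
                             tss_window=20_000, promoter_window=20_000,
                             upstream_range=(10_000, 50_000)):
    """Apply the linkage/feature rule literally, peak by peak, gene by gene.

    Returns (gene_id or None, feature, dist or None, linked).
    """
    mid = (peak.start + peak.end) // 2

    def sdist(g):
        return mid - g.tss if g.strand == "+" else g.tss - mid

    body = [g for g in genes if g.chrom == peak.chrom
            and peak.start < g.end and g.start < peak.end]
    promo = [g for g in genes if g.chrom == peak.chrom
             and -tss_window <= sdist(g) <= 0]
    # gene priority: body overlap first, then nearest |TSS distance|, then id
    if body:
        gene = sorted(body, key=lambda g: (abs(sdist(g)), g.gene_id))[0]
    elif promo:
        gene = sorted(promo, key=lambda g: (abs(sdist(g)), g.gene_id))[0]
    else:
        gene = None

    if gene is not None:
        overlaps_body = peak.start < gene.end and gene.start < peak.end
        if overlaps_body:
            in_exon = any(peak.start < e and s < peak.end for s, e in gene.exons)
            feature = "exon" if in_exon else "intron"
        elif -promoter_window <= sdist(gene) <= 0:
            feature = "promoter"
        elif -upstream_range[1] <= sdist(gene) <= -upstream_range[0]:
            feature = "upstream"
        else:
            feature = "intergenic"
        return gene.gene_id, feature, sdist(gene), True

    lo, hi = upstream_range
    ups = [g for g in genes if g.chrom == peak.chrom and -hi <= sdist(g) <= -lo]
    if ups:
        g = sorted(ups, key=lambda g: (abs(sdist(g)), g.gene_id))[0]
        return g.gene_id, "upstream", sdist(g), False
    near = [g for g in genes if g.chrom == peak.chrom]
    dist = None
    if near:
        g = sorted(near, key=lambda g: (abs(sdist(g)), g.gene_id))[0]
        dist = sdist(g)
    return None, "intergenic", dist, False


def sam_d_bruteforce(X: np.ndarray, ref_mask: np.ndarray, s0: float) -> np.ndarray:
    """The moderated t evaluated gene by gene from its definition."""
    out = np.empty(X.shape[0])
    n1, n2 = int(ref_mask.sum()), int((~ref_mask).sum())
    for i in range(X.shape[0]):
        x1, x2 = X[i, ref_mask], X[i, ~ref_mask]
        ss = ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
        s = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
        out[i] = (x1.mean() - x2.mean()) / (s + s0) if s + s0 > 0 else np.nan
    return out


def spearman_bruteforce(x: np.ndarray, y: np.ndarray):
    """Per-pair scipy Spearman (average ranks, t approximation)."""
    rho, p = stats.spearmanr(x, y)
    return rho, p


def base_coverage_mass(reads, chrom_sizes, extend_bp):
    """Total covered base-pairs (with multiplicity) of extended reads,
    accumulated at single-base resolution."""
    mass = 0
    for r in reads.itertuples(index=False):
        if r.strand == "+":
            s, e = r.start, r.start + extend_bp
        else:
            s, e = r.end - extend_bp, r.end
        s = max(s, 0)
        e = min(e, chrom_sizes[r.chrom])
        mass += max(0, e - s)
    return mass
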