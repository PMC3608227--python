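#!/usr/bin/env python
"""Link peaks to genes (midpoint within 20 kb upstream of a TSS, or any
gene-body overlap), classify genomic features, and summarise each cistrome
as total peaks / linked peaks / genes with a peak, with the percent
reduction between the high- and low-expressing strains.

Reads results/sim/ and results/peaks/, writes results/annotation/.
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from tftargets import annotation, io

log = logging.getLogger("03_annotate_peaks")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--peakdir", type=Path, default=Path("results/peaks"))
    ap.add_argument("--outdir", type=Path, default=Path("results/annotation"))
    ap.add_argument("--tss-window", type=int, default=20_000)
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    genes = io.read_gff3(args.simdir / "genes.gff3")

    ann_sets = {}
    rows = []
    for bed in sorted(args.peakdir.glob("peaks_*.bed")):
        tag = bed.stem.removeprefix("peaks_")
        peaks = io.bed_to_peaks(io.read_bed6(bed))
        anns = annotation.link_peaks_to_genes(peaks, genes, args.tss_window)
        ann_sets[tag] = anns
        for a in anns:
            rows.append((tag, a.peak_id, a.gene_id or "", a.feature,
                         a.dist_to_tss, a.linked))
        feats = pd.Series([a.feature for a in anns]).value_counts()
        log.info("%s: %s", tag, ", ".join(f"{k}={v}" for k, v in feats.items()))

    io.write_table(pd.DataFrame(rows, columns=[
        "dataset", "peak_id", "gene_id", "feature", "dist_to_tss", "linked"]),
        out / "peak_annotations.tsv", index=False)

    summary = annotation.summarize_linkage(ann_sets)
    io.write_table(summary, out / "cistrome_summary.tsv")
    log.info("cistrome summary:\n%s", summary.to_string())

    # percent reduction between strains, per condition, as in the study table
    tags = list(summary.index)
    for cond in ("basal", "LPS"):
        pair = [t for t in tags if t.endswith(cond)]
        if len(pair) == 2:
            hi, lo = sorted(pair, key=lambda t: -summary.loc[t, "genes_with_peak"])
            red = annotation.percent_reduction(
                summary.loc[hi, "genes_with_peak"],
                summary.loc[lo, "genes_with_peak"])
            log.info("%s: %d%% reduction in genes with a peak (%s -> %s)",
                     cond, red, hi, lo)


if __name__ == "__main__":
    main()
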