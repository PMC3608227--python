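#!/usr/bin/env python
"""Filter raw caller bins (posterior >= 0.9), drop over-fitting regions
(lambda1 < 0.7 and score < -2.25), merge survivors into contiguous peaks,
build one extended-read coverage track, and scan peaks for the AP-1
consensus on both strands.

Reads results/sim/, writes results/peaks/.
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from tftargets import io
from tftargets import peaks as pk

log = logging.getLogger("02_process_peaks")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/peaks"))
    ap.add_argument("--posterior", type=float, default=0.9)
    ap.add_argument("--lambda1-cut", type=float, default=0.7)
    ap.add_argument("--score-cut", type=float, default=-2.25)
    ap.add_argument("--extend", type=int, default=200)
    ap.add_argument("--bin", type=int, default=10)
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    genome = io.read_fasta(args.simdir / "genome.fa")
    sizes = {c: len(s) for c, s in genome.items()}

    rows = []
    for bins_path in sorted(args.simdir.glob("bins_*.tsv")):
        tag = bins_path.stem.removeprefix("bins_")
        bins = pk.bins_from_frame(io.read_bins_tsv(bins_path))
        kept = pk.filter_bins(bins, args.posterior)
        cleaned = pk.overfit_filter(kept, args.lambda1_cut, args.score_cut)
        merged = pk.merge_bins(cleaned)
        frac, _ = pk.ap1_consensus_scan(merged, genome)
        io.write_bed6(io.peaks_to_bed(merged), out / f"peaks_{tag}.bed")
        rows.append((tag, len(bins), len(kept), len(kept) - len(cleaned),
                     len(merged), round(frac, 3)))
        log.info("%s: %d bins -> %d pass posterior, %d over-fit removed, "
                 "%d peaks, AP-1 motif in %.0f%% of peaks",
                 tag, len(bins), len(kept), len(kept) - len(cleaned),
                 len(merged), 100 * frac)

    stats = pd.DataFrame(rows, columns=["dataset", "bins", "pass_posterior",
                                        "overfit_removed", "peaks",
                                        "motif_fraction"])
    io.write_table(stats, out / "peak_stats.tsv", index=False)

    first = sorted(args.simdir.glob("reads_*.bed"))[0]
    reads = io.read_bed6(first)
    track = pk.make_wig(reads, sizes, args.extend, args.bin)
    io.write_wig(track, out / f"coverage_{first.stem.removeprefix('reads_')}.wig",
                 args.bin)
    log.info("coverage track written for %s", first.name)


if __name__ == "__main__":
    main()
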