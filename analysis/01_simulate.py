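#!/usr/bin/env python
"""Generate the synthetic study: toy genome, gene models, planted truth,
two-strain LPS timecourse and siRNA expression matrices, per-strain
peak-caller output with reads, and qPCR Ct tables.

Writes everything under results/sim/. Later scripts consume these files.
"""

import argparse
import logging
from pathlib import Path

from tftargets import io, synth

log = logging.getLogger("01_simulate")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

    cfg = synth.SimConfig(seed=args.seed)
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    truth = synth.make_truth(cfg)
    genome = synth.make_toy_genome(cfg)
    tc = synth.simulate_timecourse(genome.genes, truth, cfg)
    sirna = synth.simulate_sirna(genome.genes, truth, cfg)
    peak_sets = synth.simulate_peaks(genome, truth, cfg)
    ct = synth.simulate_ct(truth, cfg)

    io.write_gff3(genome.genes, out / "genes.gff3")
    io.write_fasta(genome.sequences, out / "genome.fa")
    io.write_table(truth, out / "truth.tsv")
    io.write_expression(tc, out / "timecourse_expr.tsv",
                        out / "timecourse_samples.tsv")
    io.write_expression(sirna, out / "sirna_expr.tsv",
                        out / "sirna_samples.tsv")
    io.write_table(ct, out / "ct_table.tsv", index=False)
    for (strain, cond), bundle in peak_sets.items():
        tag = f"{strain}_{cond}".replace(".", "_")
        io.write_bins_tsv(bundle["bins"], out / f"bins_{tag}.tsv")
        io.write_bed6(bundle["reads"], out / f"reads_{tag}.bed")

    log.info("genome: %d genes on %d chromosomes", len(genome.genes),
             len(genome.sequences))
    log.info("timecourse matrix: %s; siRNA matrix: %s",
             tc.values.shape, sirna.values.shape)
    for cond in cfg.conditions:
        log.info("planted primary targets (%s): %d", cond,
                 int(truth[f"expected_primary_{cond}"].sum()))
    log.info("outputs under %s", out)


if __name__ == "__main__":
    main()
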