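#!/usr/bin/env python
"""Integrate the three evidence layers: Spearman-correlate every transcript
with the driver's timecourse profile (raw P < 0.001), intersect with the
knockdown DE calls and peak-linked genes per condition, call primary
targets with direction, and export the star networks (SIF + GraphML) and
ring-category summaries.

Reads results/sim/, results/de/ and results/annotation/; writes
results/integration/.
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from tftargets import integration, io

log = logging.getLogger("05_integrate_targets")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--dedir", type=Path, default=Path("results/de"))
    ap.add_argument("--anndir", type=Path, default=Path("results/annotation"))
    ap.add_argument("--outdir", type=Path, default=Path("results/integration"))
    ap.add_argument("--driver", default="Jund")
    ap.add_argument("--p-cut", type=float, default=0.001)
    ap.add_argument("--high-strain", default="WKY",
                    help="strain whose cistrome defines the binding layer")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    tc = io.read_expression(args.simdir / "timecourse_expr.tsv",
                            args.simdir / "timecourse_samples.tsv")
    corr = integration.driver_correlation(tc.values, args.driver)
    io.write_table(corr, out / "driver_correlation.tsv")
    correlated = integration.select_correlated(corr, args.driver, args.p_cut)
    log.info("%d transcripts correlate with %s at raw P < %g",
             len(correlated), args.driver, args.p_cut)

    anns = pd.read_csv(args.anndir / "peak_annotations.tsv", sep="\t")
    truth = pd.read_csv(args.simdir / "truth.tsv", sep="\t", index_col="gene_id")

    for cond in ("basal", "LPS"):
        tag = f"{args.high_strain}_{cond}".replace(".", "_")
        sub = anns[(anns["dataset"] == tag) & anns["linked"]]
        linked = {g: list(s["peak_id"]) for g, s in sub.groupby("gene_id")}
        de = pd.read_csv(args.dedir / f"sirna_de_{cond}.tsv", sep="\t",
                         index_col=0)
        targets = integration.call_primary_targets(
            correlated, de, linked, cond, corr=corr)
        frame = pd.DataFrame(
            [(t.gene_id, t.direction, t.rho, t.sirna_fc, ",".join(t.peak_ids))
             for t in targets],
            columns=["gene_id", "direction", "rho", "sirna_fc", "peak_ids"])
        io.write_table(frame, out / f"primary_targets_{cond}.tsv", index=False)

        graph = integration.build_network(targets, args.driver)
        integration.write_sif(graph, out / f"network_{cond}.sif")
        integration.write_graphml(graph, out / f"network_{cond}.graphml")

        ring = integration.ring_summary(correlated, linked, de)
        io.write_table(ring, out / f"ring_summary_{cond}.tsv")

        expected = set(truth.index[truth[f"expected_primary_{cond}"]])
        called = {t.gene_id for t in targets}
        n_act = sum(t.direction == "activated" for t in targets)
        log.info("%s: %d primary targets (%d activated, %d repressed); "
                 "network %d nodes / %d edges; matches planted truth: %s",
                 cond, len(targets), n_act, len(targets) - n_act,
                 graph.number_of_nodes(), graph.number_of_edges(),
                 called == expected)


if __name__ == "__main__":
    main()
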