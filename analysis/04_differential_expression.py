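#!/usr/bin/env python
"""Knockdown differential expression (moderated t + permutation FDR at 5%,
basal and LPS separately) with the >3-fold and >2-fold threshold lists, and
the strain-difference timecourse permutation F test.

Reads results/sim/, writes results/de/.
"""

import argparse
import logging
from pathlib import Path

from tftargets import diffexpr, io
from tftargets.util import stage_seed

log = logging.getLogger("04_differential_expression")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/de"))
    ap.add_argument("--n-perm", type=int, default=500)
    ap.add_argument("--fdr", type=float, default=0.05)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    sirna = io.read_expression(args.simdir / "sirna_expr.tsv",
                               args.simdir / "sirna_samples.tsv")
    for cond in sorted(sirna.samples["condition"].unique()):
        mask = sirna.samples["condition"] == cond
        expr = sirna.values.loc[:, sirna.samples.loc[mask, "sample_id"]]
        labels = sirna.samples.loc[mask, "sirna"].to_numpy()
        res = diffexpr.two_group_de(expr, labels, reference="scrambled",
                                    n_perm=args.n_perm, fdr=args.fdr,
                                    seed=stage_seed(args.seed, f"de_{cond}"))
        io.write_table(res, out / f"sirna_de_{cond}.tsv")
        log.info("%s: %d/%d genes called at %.0f%% FDR", cond,
                 int(res["called"].sum()), len(res), 100 * args.fdr)
        for cut in (3.0, 2.0):
            top = diffexpr.threshold_filter(res, cut, args.fdr)
            io.write_table(top, out / f"sirna_de_{cond}_fc{cut:g}.tsv")
            log.info("  |fold| > %g and q <= %.2f: %d genes%s", cut, args.fdr,
                     len(top),
                     "" if top.empty else f" (top: {top.index[0]}, "
                     f"FC {top['fold_change'].iloc[0]:+.1f})")

    tc = io.read_expression(args.simdir / "timecourse_expr.tsv",
                            args.simdir / "timecourse_samples.tsv")
    res = diffexpr.timecourse_de(
        tc.values, tc.samples["strain"].to_numpy(),
        tc.samples["timepoint"].to_numpy(), n_perm=args.n_perm,
        fdr=args.fdr, seed=stage_seed(args.seed, "timecourse_de"))
    io.write_table(res, out / "timecourse_de.tsv")
    log.info("timecourse: %d/%d genes differ between strains at %.0f%% FDR",
             int(res["called"].sum()), len(res), 100 * args.fdr)


if __name__ == "__main__":
    main()
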