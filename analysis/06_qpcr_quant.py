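#!/usr/bin/env python
"""qPCR quantification of the simulated Ct tables: reference-gene
(comparative Ct) expression fold changes between siRNA groups, and ChIP
enrichment as percent input and fold over IgG per strain.

Reads results/sim/ct_table.tsv, writes results/qpcr/.
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from tftargets import io, qpcr

log = logging.getLogger("06_qpcr_quant")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/qpcr"))
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(args.simdir / "ct_table.tsv", sep="\t")

    expr = table[table["assay"] == "expression"]
    res = qpcr.comparative_ct(expr, group_col="group",
                              reference_group="scrambled")
    io.write_table(res, out / "expression_folds.tsv")
    for locus, row in res.iterrows():
        log.info("%s: fold change %+.2f (scrambled vs knockdown, %s-normalised)",
                 locus, row["fold_change"], qpcr.REFERENCE_GENE)

    chip = table[table["assay"] == "chip"]
    rows = []
    for (group, locus), sub in chip.groupby(["group", "locus"], sort=True):
        piv = sub.pivot_table(index="sample_id", columns="antibody", values="ct")
        frac = sub["input_fraction"].dropna().iloc[0]
        pi_tf = piv.apply(lambda r: qpcr.percent_input(r["TF"], r["input"], frac),
                          axis=1).mean()
        pi_igg = piv.apply(lambda r: qpcr.percent_input(r["IgG"], r["input"], frac),
                           axis=1).mean()
        fold = piv.apply(lambda r: qpcr.fold_over_igg(r["TF"] - r["input"],
                                                      r["IgG"] - r["input"]),
                         axis=1).mean()
        rows.append((group, locus, pi_tf, pi_igg, fold))
        log.info("%s %s: %%input %.3f (antibody) vs %.3f (IgG) -> %.1f-fold",
                 group, locus, pi_tf, pi_igg, fold)
    io.write_table(pd.DataFrame(rows, columns=[
        "group", "locus", "percent_input_tf", "percent_input_igg",
        "fold_over_igg"]), out / "chip_enrichment.tsv", index=False)


if __name__ == "__main__":
    main()
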