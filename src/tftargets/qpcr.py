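"""qPCR quantification: comparative Ct expression and ChIP enrichment.

Three closed-form quantities (amplification efficiency fixed at 2, i.e. a
perfect doubling per cycle):

* comparative Ct expression: per-sample dCt = Ct(target) - Ct(reference
  gene, default Hprt); the group fold change is ``2**-(mean dCt_1 - mean
  dCt_2)``.
* percent input for ChIP: ``%total = 2**(Ct_input - Ct_sample) * (% of
  input used)``.
* fold over IgG: ``2**-(dCt_ab - dCt_igg)`` with both dCt taken against the
  same input — algebraically the ratio of the two percent-input values.

The standard-curve path estimates efficiency empirically from an input
dilution series instead of assuming 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REFERENCE_GENE = "Hprt"


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement."""

    sample_id: str
    locus: str
    assay: str  # expression | chip
    antibody: str  # for chip: e.g. JunD / IgG / input; expression: none
    ct: float
    input_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("Ct must be positive")
        if self.assay == "chip" and self.antibody != "input":
            if self.input_fraction is None or not 0 < self.input_fraction <= 1:
                raise ValueError("chip records need input_fraction in (0, 1]")


def comparative_ct(records: pd.DataFrame, reference_gene: str = REFERENCE_GENE,
                   group_col: str = "group", reference_group=None) -> pd.DataFrame:
    """Reference-gene-normalised expression fold change per target locus.

    ``records`` needs columns sample_id, locus, ct and a group column with
    exactly two levels. Samples missing the reference gene are dropped with
    a log message. Fold changes are signed-magnitude (+2 = twice as high in
    the reference group), matching the array convention.
    """
    ref = records[records["locus"] == reference_gene].set_index("sample_id")["ct"]
    groups = records.drop_duplicates("sample_id").set_index("sample_id")[group_col]
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if reference_group is None:
        reference_group = levels[0]
    other = next(g for g in levels if g != reference_group)

    rows = []
    for locus, sub in records[records["locus"] != reference_gene].groupby("locus", sort=True):
        sub = sub.set_index("sample_id")
        missing = sub.index.difference(ref.index)
        if len(missing):
            log.warning("locus %s: dropping samples without %s: %s",
                        locus, reference_gene, sorted(missing))
            sub = sub.loc[sub.index.intersection(ref.index)]
        dct = sub["ct"] - ref.loc[sub.index]
        grp = groups.loc[dct.index]
        mean_ref = dct[grp == reference_group].mean()
        mean_other = dct[grp == other].mean()
        ratio = 2.0 ** -(mean_ref - mean_other)
        fc = ratio if ratio >= 1 else -1.0 / ratio
        rows.append({"locus": locus, "ddct": mean_ref - mean_other,
                     "ratio": ratio, "fold_change": fc})
    return pd.DataFrame(rows).set_index("locus")


def percent_input(ct_sample: float, ct_input: float, input_fraction: float) -> float:
    """ChIP signal as percent of total chromatin: 2**(Ct_in - Ct_s) * 100*f."""
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    if not (np.isfinite(ct_sample) and np.isfinite(ct_input)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_input - ct_sample) * 100.0 * input_fraction


def fold_over_igg(dct_ab: float, dct_igg: float) -> float:
    """Antibody enrichment over the IgG control: 2**-(dCt_ab - dCt_igg).

    Both dCt values are Ct(sample) - Ct(input) against the same input, so
    this equals percent_input(ab) / percent_input(IgG).
    """
    return 2.0 ** -(dct_ab - dct_igg)


def standard_curve_quantify(dilution_cts: Sequence[tuple[float, float]],
                            sample_ct: float) -> dict[str, float]:
    """Quantify a sample against an input dilution series.

    ``dilution_cts`` is a list of (fraction of undiluted input, Ct), with
    strictly decreasing fractions (e.g. 1:5 series). Fits Ct ~ log2(fraction)
    by least squares, inverts at ``sample_ct``, and reports the sample as a
    percentage of the undiluted input plus the implied per-cycle efficiency
    (2.0 for a perfect -1 slope per log2 dilution).
    """
    if len(dilution_cts) < 3:
        raise ValueError("need >= 3 dilution points")
    fracs = np.array([f for f, _ in dilution_cts], dtype=float)
    cts = np.array([c for _, c in dilution_cts], dtype=float)
    if np.any(fracs <= 0) or np.any(np.diff(fracs) >= 0):
        raise ValueError("dilution fractions must be positive and strictly decreasing")
    monotone = bool(np.all(np.diff(cts) > 0))
    if not monotone:
        log.warning("standard-curve Ct series is not monotone increasing; fit is suspect")
    slope, intercept = np.polyfit(np.log2(fracs), cts, 1)
    if slope == 0:
        raise ValueError("degenerate standard curve (zero slope)")
    log2_q = (sample_ct - intercept) / slope
    resid = cts - (intercept + slope * np.log2(fracs))
    return {
        "percent_input": 100.0 * 2.0 ** log2_q,
        "efficiency": 2.0 ** (-1.0 / slope),
        "slope": float(slope),
        "monotone": float(monotone),
        "max_abs_residual": float(np.max(np.abs(resid))),
    }
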