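"""Reported summary counts from the JunD BMDM cistrome/transcriptome study.

These printed table values are inputs for consistency arithmetic (percent
reductions between cistromes, ring-category percentages); nothing in the
pipeline is fit to them.
"""

from __future__ import annotations

import pandas as pd

#: Cistrome summary per strain/condition: total peaks called, peaks linked
#: to a gene by the 20 kb TSS / gene-body rule, and distinct genes with at
#: least one peak.
CISTROME_SUMMARY = pd.DataFrame(
    [
        ("WKY basal", 27124, 12522, 5339),
        ("WKY LPS", 36687, 18124, 7612),
        ("WKY.LCrgn2 basal", 16593, 6408, 2606),
        ("WKY.LCrgn2 LPS", 8689, 3361, 1022),
    ],
    columns=["dataset", "total_peaks", "linked_peaks", "genes_with_peak"],
).set_index("dataset")

#: Ring-diagram category counts over all driver-correlated transcripts:
#: correlated-only, correlated with a binding peak, correlated and
#: down-regulated on knockdown, correlated and up-regulated on knockdown.
RING_COUNTS = {
    "correlated_only": 1445,
    "peak": 232,
    "down_regulated": 125,
    "up_regulated": 116,
}

#: Primary-target network sizes in the basal and LPS-stimulated states.
PRIMARY_TARGET_COUNTS = {"basal": 24, "LPS": 36}
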