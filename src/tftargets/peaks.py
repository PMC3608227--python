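"""ChIP-Seq peak post-processing.

Consumes bin-level output of a Bayesian peak caller (per-bin posterior
probability of enrichment plus the caller's over-fitting diagnostics
``lambda1`` and ``score``), applies the retention/removal filters, merges
surviving bins into contiguous peak regions, builds read-extension coverage
tracks, and scans peak sequence for the AP-1 consensus motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: AP-1 consensus binding site, written 5'->3'.
AP1_CONSENSUS = "TGAGTCA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class BinCall:
    """One caller bin: half-open genomic interval with enrichment posterior."""

    chrom: str
    start: int
    end: int
    posterior: float
    lambda1: float
    score: float

    def validate(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"malformed bin on {self.chrom}: start {self.start} >= end {self.end}")
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError(f"posterior {self.posterior} outside [0, 1]")


@dataclass(frozen=True)
class Peak:
    """A merged contiguous enriched region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    max_posterior: float
    n_bins: int
    peak_id: str


def bins_from_frame(frame: pd.DataFrame) -> list[BinCall]:
    """Build :class:`BinCall` records from a table with the bin-call columns."""
    return [
        BinCall(str(r.chrom), int(r.start), int(r.end), float(r.posterior),
                float(r.lambda1), float(r.score))
        for r in frame.itertuples(index=False)
    ]


def filter_bins(bins: Iterable[BinCall], posterior_threshold: float = 0.9) -> list[BinCall]:
    """Retain bins whose posterior is >= ``posterior_threshold`` (inclusive).

    The default 0.9 is the stringent retention cutoff used for the JunD
    cistromes. Input order is preserved; every bin is validated first.
    """
    if not 0.0 <= posterior_threshold <= 1.0:
        raise ValueError("posterior_threshold must lie in [0, 1]")
    out = []
    for b in bins:
        b.validate()
        if b.posterior >= posterior_threshold:
            out.append(b)
    return out


def overfit_filter(regions: Iterable[BinCall], lambda1_cut: float = 0.7,
                   score_cut: float = -2.25) -> list[BinCall]:
    """Drop regions flagged by the over-fitting diagnostic.

    A region is removed only when *both* ``lambda1 < lambda1_cut`` and
    ``score < score_cut`` — such regions have enough background for the
    caller to fire but show no genuine enrichment. Either condition alone
    retains the region.
    """
    for c in (lambda1_cut, score_cut):
        if not np.isfinite(c):
            raise ValueError("filter cuts must be finite")
    return [r for r in regions if not (r.lambda1 < lambda1_cut and r.score < score_cut)]


def merge_bins(bins: Iterable[BinCall]) -> list[Peak]:
    """Merge touching/overlapping bins into final contiguous peak regions.

    Bins on the same chromosome whose intervals touch (``end == next start``)
    or overlap are collapsed into a single peak spanning the run;
    ``max_posterior`` is the maximum over member bins. Output is sorted by
    (chrom, start) and pairwise disjoint.
    """
    bins = list(bins)
    for b in bins:
        b.validate()
    names = {b.chrom for b in bins}
    lowered: dict[str, str] = {}
    for n in names:
        if n.lower() in lowered and lowered[n.lower()] != n:
            raise ValueError(f"chromosome names differ only by case: {n!r} vs {lowered[n.lower()]!r}")
        lowered[n.lower()] = n

    peaks: list[Peak] = []
    counter = 0
    for b in sorted(bins, key=lambda b: (b.chrom, b.start, b.end)):
        if peaks and peaks[-1].chrom == b.chrom and b.start <= peaks[-1].end:
            last = peaks[-1]
            peaks[-1] = Peak(last.chrom, last.start, max(last.end, b.end),
                             max(last.max_posterior, b.posterior),
                             last.n_bins + 1, last.peak_id)
        else:
            counter += 1
            peaks.append(Peak(b.chrom, b.start, b.end, b.posterior, 1, f"peak{counter:05d}"))
    return peaks


def call_peaks(bins: Iterable[BinCall], posterior_threshold: float = 0.9,
               lambda1_cut: float = 0.7, score_cut: float = -2.25) -> list[Peak]:
    """Full bin-to-peak pipeline: posterior filter -> over-fit filter -> merge."""
    return merge_bins(overfit_filter(filter_bins(bins, posterior_threshold),
                                     lambda1_cut, score_cut))


def make_wig(reads: pd.DataFrame, chrom_sizes: Mapping[str, int],
             extend_bp: int = 200, bin_bp: int = 10) -> dict[str, np.ndarray]:
    """Extended-read binned coverage, the track used to visualise peaks.

    Each mapped read is extended to ``extend_bp`` from its 5' end in its
    strand direction (the approximate fragment length); each ``bin_bp`` bin
    counts the number of extended reads overlapping it. Reads running past a
    chromosome end are clipped with a warning.

    Parameters
    ----------
    reads
        BED6-style frame with columns chrom, start, end, strand
        (0-based half-open).
    chrom_sizes
        Mapping chromosome name -> length in bp.

    Returns
    -------
    dict mapping chromosome name to an int array of per-bin overlap counts.
    """
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    if len(reads) and extend_bp < int((reads["end"] - reads["start"]).max()):
        raise ValueError("extend_bp must be at least the read length")
    diff: dict[str, np.ndarray] = {
        chrom: np.zeros(-(-size // bin_bp) + 1, dtype=np.int64)
        for chrom, size in chrom_sizes.items()
    }
    clipped = 0
    for chrom, sub in reads.groupby("chrom", sort=True):
        if chrom not in chrom_sizes:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        start = sub["start"].to_numpy(dtype=np.int64)
        end = sub["end"].to_numpy(dtype=np.int64)
        plus = (sub["strand"].to_numpy() == "+")
        ext_start = np.where(plus, start, end - extend_bp)
        ext_end = np.where(plus, start + extend_bp, end)
        oob = (ext_start < 0) | (ext_end > size)
        clipped += int(oob.sum())
        ext_start = np.clip(ext_start, 0, size)
        ext_end = np.clip(ext_end, 0, size)
        keep = ext_end > ext_start
        first_bin = ext_start[keep] // bin_bp
        last_bin = (ext_end[keep] - 1) // bin_bp
        np.add.at(diff[chrom], first_bin, 1)
        np.add.at(diff[chrom], last_bin + 1, -1)
    if clipped:
        log.warning("%d extended reads clipped at chromosome bounds", clipped)
    return {chrom: np.cumsum(arr)[:-1] for chrom, arr in diff.items()}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def ap1_consensus_scan(peaks: Sequence[Peak], genome: Mapping[str, str],
                       motif: str = AP1_CONSENSUS) -> tuple[float, dict[str, list[int]]]:
    """Scan peak sequences for the AP-1 consensus on both strands.

    Returns the fraction of peaks with at least one exact match to ``motif``
    or its reverse complement, together with per-peak 0-based hit offsets
    (relative to the peak start; reverse-strand hits are reported at the
    position of the match on the forward sequence).
    """
    motifs = {motif.upper(), reverse_complement(motif.upper())}
    hits: dict[str, list[int]] = {}
    n_hit = 0
    for p in peaks:
        seq = genome[p.chrom]
        if p.end > len(seq):
            raise ValueError(f"peak {p.peak_id} extends beyond {p.chrom} sequence end")
        window = str(seq[p.start:p.end]).upper()
        positions = []
        for m in sorted(motifs):
            ofs = window.find(m)
            while ofs != -1:
                positions.append(ofs)
                ofs = window.find(m, ofs + 1)
        hits[p.peak_id] = sorted(set(positions))
        if positions:
            n_hit += 1
    fraction = n_hit / len(peaks) if peaks else 0.0
    return fraction, hits
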