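"""File format boundaries.

Internal coordinates are 0-based half-open everywhere; conversion to each
format's native convention (GFF3 1-based closed, BED 0-based half-open,
WIG 1-based fixedStep) happens only here. Writers are deterministic:
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel
from .peaks import Peak

BIN_COLUMNS = ["chrom", "start", "end", "posterior", "lambda1", "score"]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\ttftargets\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\ttftargets\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{k};Parent={g.gene_id}\n")


def read_gff3(path) -> list[GeneModel]:
    try:
        db = gffutils.create_db(str(path), ":memory:", merge_strategy="error",
                                keep_order=True)
    except gffutils.exceptions.EmptyInputError:
        return []
    genes = []
    for feat in db.features_of_type("gene"):
        exons = tuple(sorted((e.start - 1, e.end)
                             for e in db.children(feat, featuretype="exon")))
        genes.append(GeneModel(feat.id, feat.seqid, feat.strand,
                               feat.start - 1, feat.end, exons))
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def write_fasta(sequences: Mapping[str, bytearray], path) -> None:
    records = [SeqRecord(Seq(bytes(seq).decode()), id=chrom, description="")
               for chrom, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bins_tsv(bins: pd.DataFrame, path) -> None:
    bins.to_csv(path, sep="\t", index=False, columns=BIN_COLUMNS,
                float_format="%.6g")


def read_bins_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed6(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, header=False,
                 columns=BED6_COLUMNS)


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)


def peaks_to_bed(peaks: Iterable[Peak]) -> pd.DataFrame:
    """BED6 rows for merged peaks; score = floor(1000 * max posterior)."""
    return pd.DataFrame(
        [(p.chrom, p.start, p.end, p.peak_id, int(1000 * p.max_posterior), ".")
         for p in peaks], columns=BED6_COLUMNS)


def bed_to_peaks(frame: pd.DataFrame) -> list[Peak]:
    """Rebuild peaks from BED6 (bin membership is not stored; n_bins = 0)."""
    return [Peak(r.chrom, int(r.start), int(r.end), r.score / 1000.0, 0, r.name)
            for r in frame.itertuples(index=False)]


def write_wig(track: Mapping[str, np.ndarray], path, bin_bp: int = 10) -> None:
    """fixedStep WIG (1-based starts, step=span=bin width); zero bins omitted
    by breaking into separate fixedStep blocks."""
    with open(path, "w") as fh:
        fh.write('track type=wiggle_0 name="coverage"\n')
        for chrom in sorted(track):
            values = np.asarray(track[chrom])
            nz = values != 0
            if not nz.any():
                continue
            breaks = np.flatnonzero(np.diff(nz.astype(int)) != 0) + 1
            start = 0
            for stop in [*breaks.tolist(), len(values)]:
                if nz[start]:
                    fh.write(f"fixedStep chrom={chrom} start={start * bin_bp + 1} "
                             f"step={bin_bp} span={bin_bp}\n")
                    fh.write("\n".join(str(int(v)) for v in values[start:stop]))
                    fh.write("\n")
                start = stop


def write_expression(matrix, values_path, samples_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", float_format="%.6f",
                         index_label="gene_id")
    matrix.samples.to_csv(samples_path, sep="\t", index=False)


def read_expression(values_path, samples_path):
    from .synth import ExpressionMatrix
    return ExpressionMatrix(
        values=pd.read_csv(values_path, sep="\t", index_col="gene_id"),
        samples=pd.read_csv(samples_path, sep="\t"))


def write_table(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", float_format="%.6g", index=index)
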