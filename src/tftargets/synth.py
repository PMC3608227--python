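"""Synthetic study generator with planted ground truth.

Emulates the data shapes of a two-strain macrophage study of a driver
transcription factor: a toy genome with non-overlapping gene models, an
LPS-timecourse expression matrix for a high-expressing and a low-expressing
strain, a scrambled-vs-knockdown siRNA expression matrix (basal and LPS),
bin-level peak-caller output with reads per strain/condition, and qPCR Ct
tables. Every planted property (target rank correlation with the driver,
knockdown log2 fold change, bound/not bound per strain and condition) is
recorded in a truth table so each downstream stage can be scored exactly.

Planted categories are kept cleanly separated: genes bound in the
high-expressing strain are either (high-correlation AND differentially
expressed) — the intended primary targets — or entirely null in the other
two layers. Mid-tier correlated genes are never bound, so the primary-target
conjunction has an unambiguous expected answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log2

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .peaks import AP1_CONSENSUS
from .qpcr import REFERENCE_GENE
from .util import stage_seed

log = logging.getLogger(__name__)

#: |planted rho| at or above this counts as high-tier for the truth table
RHO_HIGH_TIER = 0.8

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated design: four biological replicates per
    strain/timepoint/siRNA group, an eight-hour LPS timecourse sampled at
    0/2/4/8 h, log2-scale replicate noise of 0.25, and knockdown fold-change
    tiers above 3 and above 2.
    """

    n_genes: int = 300
    chrom_sizes: tuple[tuple[str, int], ...] = (("chr1", 13_000_000),
                                                ("chr2", 13_000_000))
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)
    n_replicates: int = 4
    noise_sd: float = 0.25
    n_planted_correlated: int = 60
    n_planted_de: int = 40
    n_planted_bound: int = 36
    fold_tiers: tuple[float, ...] = (3.3, 2.2)
    read_depth: int = 20_000
    fragment_len: int = 200
    read_len: int = 36
    bin_size: int = 100
    n_background_bins: int = 300
    decoy_fraction: float = 0.15
    motif_fraction: float = 0.63
    rho_high: float = 0.9
    rho_mid: float = 0.5
    strains: tuple[str, str] = ("WKY", "WKY.LCrgn2")  # high-, low-expressing
    conditions: tuple[str, str] = ("basal", "LPS")
    driver_gene: str = "Jund"
    input_fraction: float = 0.1
    ct_noise_sd: float = 0.1
    nested_bound: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        tps = self.timepoints
        if len(tps) < 2 or tps[0] != 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must start at 0 and increase strictly")
        for name, v in (("n_replicates", self.n_replicates),
                        ("read_depth", self.read_depth),
                        ("fragment_len", self.fragment_len),
                        ("bin_size", self.bin_size)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        for name, v in (("n_planted_correlated", self.n_planted_correlated),
                        ("n_planted_de", self.n_planted_de),
                        ("n_planted_bound", self.n_planted_bound)):
            if v < 0 or v > self.n_genes:
                raise ValueError(f"{name} must be in [0, n_genes]")
        if not any(t > 3 for t in self.fold_tiers) or \
           not any(2 < t <= 3 for t in self.fold_tiers):
            raise ValueError("fold_tiers must include a >3 tier and a (2,3] tier")
        if not 0 <= self.decoy_fraction <= 1 or not 0 <= self.motif_fraction <= 1:
            raise ValueError("fractions must be in [0, 1]")
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")


@dataclass
class ToyGenome:
    genes: list[GeneModel]
    sequences: dict[str, bytearray]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def sequence_str(self, chrom: str) -> str:
        return self.sequences[chrom].decode()


def _bound_col(strain: str, condition: str) -> str:
    return f"bound_{strain}_{condition}"


def expected_primary(truth: pd.DataFrame, strain: str, condition: str) -> pd.Series:
    """Recompute the primary-target flag from the planted property columns."""
    high_corr = truth["planted_rho"].abs() >= RHO_HIGH_TIER
    de = truth["planted_log2fc_sirna"] != 0
    bound = truth[_bound_col(strain, condition)]
    return (high_corr & de & bound & ~truth["is_driver"]).rename(None)


def make_truth(config: SimConfig) -> pd.DataFrame:
    """Plant the three property layers and derive the expected primary sets.

    Gene index 0 is the driver itself (high in everything but excluded from
    its own target list); then, in order: targets bound in both conditions,
    targets bound only after LPS, correlated+DE but unbound genes,
    correlated-only genes (high then mid tier), DE-only genes, bound-only
    genes (uncorrelated, not DE), and pure nulls.
    """
    config.validate()
    n = config.n_genes
    ids = ([config.driver_gene] + [f"g{i:04d}" for i in range(1, n)]) if n else []
    truth = pd.DataFrame({
        "gene_id": ids,
        "planted_rho": 0.0,
        "planted_log2fc_sirna": 0.0,
        "is_driver": [True] + [False] * (n - 1) if n else [],
        "placement": "none",
    }).set_index("gene_id")
    high, low_strain = config.strains
    for s in config.strains:
        for c in config.conditions:
            truth[_bound_col(s, c)] = False
    if n == 0:
        for c in config.conditions:
            truth[f"expected_primary_{c}"] = pd.Series(dtype=bool)
        return truth

    nc, nd, nb = (config.n_planted_correlated, config.n_planted_de,
                  config.n_planted_bound)
    core = min(nc, nd, nb)
    a = core * 2 // 5          # primary in both conditions
    b = core * 2 // 5          # primary after LPS only
    e = min(nc, nd) - a - b    # correlated + DE, unbound
    e = min(e, max(0, min(nc, nd) // 5)) if a + b > 0 else min(nc, nd)
    h = nd - a - b - e         # DE only
    i_cnt = nb - a - b         # bound only, null elsewhere
    rest_c = nc - a - b - e
    f_high = rest_c // 2       # correlated only, high tier
    g_mid = rest_c - f_high    # correlated only, mid tier
    needed = 1 + a + b + e + f_high + g_mid + h + i_cnt
    if needed > n:
        raise ValueError(f"n_genes={n} too small for planted layout ({needed} needed)")

    pos = 1
    tiers = list(config.fold_tiers)

    def take(k: int) -> list[str]:
        nonlocal pos
        out = ids[pos:pos + k]
        pos += k
        return out

    seg_a, seg_b, seg_e = take(a), take(b), take(e)
    seg_f, seg_g = take(f_high), take(g_mid)
    seg_h, seg_i = take(h), take(i_cnt)

    for j, g in enumerate(seg_a + seg_b + seg_e):
        sign = 1.0 if j % 2 == 0 else -1.0
        rho = config.rho_high + (0.05 if j % 4 in (0, 3) else 0.0)
        truth.loc[g, "planted_rho"] = sign * min(rho, 0.98)
        truth.loc[g, "planted_log2fc_sirna"] = sign * log2(tiers[j % len(tiers)])
    for j, g in enumerate(seg_f):
        truth.loc[g, "planted_rho"] = (1.0 if j % 2 == 0 else -1.0) * config.rho_high
    for j, g in enumerate(seg_g):
        truth.loc[g, "planted_rho"] = (1.0 if j % 2 == 0 else -1.0) * config.rho_mid
    for j, g in enumerate(seg_h):
        truth.loc[g, "planted_log2fc_sirna"] = (1.0 if j % 2 == 0 else -1.0) \
            * log2(tiers[j % len(tiers)])

    basal, lps = config.conditions
    driver = ids[0]
    truth.loc[driver, ["planted_rho", "planted_log2fc_sirna"]] = [1.0, 2.0]
    bound_basal = [driver] + seg_a + seg_i
    bound_lps = [driver] + seg_a + seg_b + seg_i
    truth.loc[bound_basal, _bound_col(high, basal)] = True
    truth.loc[bound_lps, _bound_col(high, lps)] = True
    if config.nested_bound:
        truth.loc[bound_basal[::2], _bound_col(low_strain, basal)] = True
        truth.loc[bound_lps[::2], _bound_col(low_strain, lps)] = True

    placed = truth.index[truth[[_bound_col(s, c) for s in config.strains
                                for c in config.conditions]].any(axis=1)]
    for j, g in enumerate(placed):
        truth.loc[g, "placement"] = "promoter" if j % 2 == 0 else "body"

    for c in config.conditions:
        truth[f"expected_primary_{c}"] = expected_primary(truth, high, c)
    return truth


def make_toy_genome(config: SimConfig) -> ToyGenome:
    """Random genome and non-overlapping gene models (>= 60 kb spacing).

    Genes are laid down chromosome by chromosome with 60-90 kb intergenic
    gaps and a 55 kb margin at each chromosome end so that every promoter
    and upstream window stays on-sequence. Raises a sizing error when the
    requested gene count does not fit.
    """
    config.validate()
    rng = np.random.default_rng(stage_seed(config.seed, "genome"))
    truth = make_truth(config)
    gene_ids = list(truth.index)

    genes: list[GeneModel] = []
    sequences: dict[str, bytearray] = {}
    margin = 55_000
    gi = 0
    for chrom, size in config.chrom_sizes:
        seq = _BASES[rng.integers(0, 4, size=size)].tobytes()
        sequences[chrom] = bytearray(seq)
        cursor = margin
        while gi < len(gene_ids):
            length = int(rng.integers(3_000, 15_001))
            gap = int(rng.integers(60_000, 90_001))
            if cursor + length + margin > size:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gene_ids[gi], chrom, strand, cursor,
                                   cursor + length,
                                   _make_exons(cursor, cursor + length, rng)))
            gi += 1
            cursor += length + gap
    if gi < len(gene_ids):
        raise ValueError(
            f"genome too small: placed {gi} of {len(gene_ids)} genes "
            f"(need ~75 kb per gene plus margins)")
    return ToyGenome(genes=genes, sequences=sequences)


def _make_exons(start: int, end: int, rng: np.random.Generator
                ) -> tuple[tuple[int, int], ...]:
    n_exons = int(rng.integers(1, 5))
    if n_exons == 1:
        return ((start, end),)
    # 2k-1 alternating exon/intron segments with random positive lengths
    cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * n_exons - 2,
                              replace=False))
    bounds = [start, *cuts.tolist(), end]
    return tuple((bounds[k], bounds[k + 1]) for k in range(0, 2 * n_exons - 1, 2))


@dataclass
class ExpressionMatrix:
    """log2 expression values (genes x samples) with sample metadata."""

    values: pd.DataFrame
    samples: pd.DataFrame  # sample_id, strain, condition, timepoint, sirna, replicate


def _induction(t: np.ndarray, t_max: float) -> np.ndarray:
    u = t / t_max
    return np.sin(0.75 * np.pi * u)


def simulate_timecourse(genes: list[GeneModel], truth: pd.DataFrame,
                        config: SimConfig) -> ExpressionMatrix:
    """Two-strain LPS timecourse matrix with planted driver correlations.

    The driver follows a strain-dependent induction profile (high strain
    well above the low strain). Each planted-correlated gene's expected
    profile is a linear blend ``r * z(driver) + sqrt(1 - r^2) * eta`` of the
    standardised driver profile with gene-specific independent structure, so
    its expected rank correlation approaches the planted rho; other genes
    are flat plus noise. Gaussian noise of sd ``noise_sd`` (log2 units) is
    added to every measurement.
    """
    gene_ids = [g.gene_id for g in genes]
    if config.driver_gene not in gene_ids:
        raise KeyError(f"driver gene {config.driver_gene!r} absent from gene set")
    if set(gene_ids) - set(truth.index):
        raise ValueError("truth table does not cover all genes")
    rng = np.random.default_rng(stage_seed(config.seed, "timecourse"))
    high, low = config.strains
    tps = np.asarray(config.timepoints, dtype=float)

    meta = pd.DataFrame([
        {"sample_id": f"{strain}_t{t:g}_r{r}", "strain": strain,
         "condition": "LPS_timecourse", "timepoint": t, "sirna": "none",
         "replicate": r}
        for strain in config.strains for t in tps
        for r in range(1, config.n_replicates + 1)
    ])
    strain_vec = meta["strain"].to_numpy()
    t_vec = meta["timepoint"].to_numpy(dtype=float)
    w = _induction(t_vec, tps.max())
    driver_expected = np.where(strain_vec == high, 7.0 + 2.5 * w, 5.5 + 0.8 * w)
    z = (driver_expected - driver_expected.mean()) / driver_expected.std()

    n_samp = len(meta)
    values = np.empty((len(gene_ids), n_samp))
    amp = 1.2
    for k, gid in enumerate(gene_ids):
        r = float(truth.loc[gid, "planted_rho"])
        base = float(rng.uniform(5.0, 9.0))
        if gid == config.driver_gene:
            values[k] = driver_expected
        elif r != 0.0:
            eta = rng.standard_normal(n_samp)
            values[k] = base + amp * (r * z + np.sqrt(1.0 - r**2) * eta)
        else:
            values[k] = base
    values += rng.normal(0.0, config.noise_sd, size=values.shape)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=meta["sample_id"]),
        samples=meta)


def simulate_sirna(genes: list[GeneModel], truth: pd.DataFrame,
                   config: SimConfig) -> ExpressionMatrix:
    """Scrambled-vs-knockdown matrix, basal and LPS conditions.

    Planted DE genes shift by their planted log2 fold change between the two
    siRNA groups; positive planted fold means higher in the scrambled
    control (the driver-activated direction).
    """
    if config.n_replicates < 2:
        raise ValueError("siRNA design needs >= 2 replicates per group")
    gene_ids = [g.gene_id for g in genes]
    if set(gene_ids) - set(truth.index):
        raise ValueError("truth table does not cover all genes")
    rng = np.random.default_rng(stage_seed(config.seed, "sirna"))
    meta = pd.DataFrame([
        {"sample_id": f"{cond}_{sirna}_r{r}", "strain": config.strains[0],
         "condition": cond, "timepoint": 8.0 if cond == config.conditions[1] else 0.0,
         "sirna": sirna, "replicate": r}
        for cond in config.conditions for sirna in ("scrambled", "knockdown")
        for r in range(1, config.n_replicates + 1)
    ])
    scr = (meta["sirna"] == "scrambled").to_numpy(dtype=float)
    lps = (meta["condition"] == config.conditions[1]).to_numpy(dtype=float)
    values = np.empty((len(gene_ids), len(meta)))
    for k, gid in enumerate(gene_ids):
        base = float(rng.uniform(5.0, 9.0))
        lps_shift = float(rng.normal(0.0, 0.3))
        fc = float(truth.loc[gid, "planted_log2fc_sirna"])
        values[k] = base + lps_shift * lps + fc * (scr - 0.5)
    values += rng.normal(0.0, config.noise_sd, size=values.shape)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=meta["sample_id"]),
        samples=meta)


def _intergenic_spots(genome: ToyGenome, margin: int = 55_000) -> list[tuple[str, int]]:
    spots = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genome.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gene_list in by_chrom.items():
        gene_list = sorted(gene_list, key=lambda g: g.start)
        for g1, g2 in zip(gene_list, gene_list[1:]):
            lo, hi = g1.end + margin, g2.start - margin
            if hi > lo:
                spots.append((chrom, (lo + hi) // 2))
    return spots


def simulate_peaks(genome: ToyGenome, truth: pd.DataFrame, config: SimConfig
                   ) -> dict[tuple[str, str], dict[str, pd.DataFrame]]:
    """Bin-level caller output and read positions per (strain, condition).

    Every planted-bound gene gets a run of contiguous high-posterior
    (>= 0.95) bins either 2-18 kb upstream of its TSS or inside its gene
    body, per the truth table's placement arm. Background bins (posterior
    < 0.9) are scattered genome-wide, and a configurable fraction of decoy
    regions pass the posterior threshold but carry the over-fitting
    signature (lambda1 < 0.7, score < -2.25). Read start positions are
    enriched under the true peaks. The AP-1 consensus is written into a
    ``motif_fraction`` share of true peak regions of the genome sequence.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "peaks"))
    genes = {g.gene_id: g for g in genome.genes}
    sizes = genome.chrom_sizes
    spots = _intergenic_spots(genome)
    out: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}
    motif = AP1_CONSENSUS.encode()
    motif_injected: set[tuple[str, int]] = set()

    for strain in config.strains:
        for cond in config.conditions:
            bound = truth.index[truth[_bound_col(strain, cond)]]
            bin_rows, peak_regions = [], []
            for gid in bound:
                g = genes[gid]
                arm = truth.loc[gid, "placement"]
                if arm == "promoter":
                    ofs = int(rng.integers(2_000, 18_000))
                    center = g.tss - ofs if g.strand == "+" else g.tss + ofs
                else:
                    pad = min(500, (g.end - g.start) // 4)
                    center = int(rng.integers(g.start + pad, g.end - pad))
                n_bins = int(rng.integers(3, 7))
                first = (center // config.bin_size - n_bins // 2) * config.bin_size
                if first < 0 or first + n_bins * config.bin_size > sizes[g.chrom]:
                    raise ValueError(f"no legal peak placement for {gid}")
                for k in range(n_bins):
                    s = first + k * config.bin_size
                    bin_rows.append((g.chrom, s, s + config.bin_size,
                                     float(rng.uniform(0.95, 1.0)),
                                     float(rng.uniform(1.0, 3.0)),
                                     float(rng.uniform(0.0, 5.0))))
                peak_regions.append((g.chrom, first, first + n_bins * config.bin_size))

            n_decoy = int(round(config.decoy_fraction * len(peak_regions)))
            for _ in range(n_decoy):
                if spots:
                    chrom, center = spots[int(rng.integers(0, len(spots)))]
                else:
                    chrom = list(sizes)[0]
                    center = int(rng.integers(60_000, sizes[chrom] - 60_000))
                s = (center // config.bin_size) * config.bin_size
                for k in range(int(rng.integers(2, 5))):
                    bin_rows.append((chrom, s + k * config.bin_size,
                                     s + (k + 1) * config.bin_size,
                                     float(rng.uniform(0.9, 0.99)),
                                     float(rng.uniform(0.1, 0.69)),
                                     float(rng.uniform(-6.0, -2.3))))

            for _ in range(config.n_background_bins):
                chrom = list(sizes)[int(rng.integers(0, len(sizes)))]
                s = int(rng.integers(0, sizes[chrom] - config.bin_size))
                s = (s // config.bin_size) * config.bin_size
                bin_rows.append((chrom, s, s + config.bin_size,
                                 float(rng.uniform(0.0, 0.89)),
                                 float(rng.uniform(0.5, 2.0)),
                                 float(rng.uniform(-2.0, 2.0))))

            bins = pd.DataFrame(bin_rows, columns=["chrom", "start", "end",
                                                   "posterior", "lambda1", "score"])
            reads = _simulate_reads(peak_regions, sizes, config, rng)
            out[(strain, cond)] = {"bins": bins, "reads": reads}

            for chrom, s, e in peak_regions:
                key = (chrom, s)
                if key in motif_injected:
                    continue
                motif_injected.add(key)
                if rng.random() < config.motif_fraction:
                    ofs = int(rng.integers(s, e - len(motif)))
                    genome.sequences[chrom][ofs:ofs + len(motif)] = motif
    return out


def _simulate_reads(peak_regions: list[tuple[str, int, int]],
                    sizes: dict[str, int], config: SimConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    n_peak_reads = int(config.read_depth * 0.6)
    per_peak = n_peak_reads // max(1, len(peak_regions)) if peak_regions else 0
    rid = 0
    for chrom, s, e in peak_regions:
        for _ in range(per_peak):
            strand = "+" if rng.random() < 0.5 else "-"
            lo = max(0, s - config.fragment_len // 2)
            hi = min(sizes[chrom] - config.read_len, e + config.fragment_len // 2)
            start = int(rng.integers(lo, hi))
            rows.append((chrom, start, start + config.read_len,
                         f"read{rid:07d}", 0, strand))
            rid += 1
    n_bg = config.read_depth - rid
    chroms = list(sizes)
    for _ in range(max(0, n_bg)):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, sizes[chrom] - config.read_len))
        rows.append((chrom, start, start + config.read_len,
                     f"read{rid:07d}", 0, "+" if rng.random() < 0.5 else "-"))
        rid += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


def simulate_ct(truth: pd.DataFrame, config: SimConfig,
                n_expr_loci: int = 4, n_chip_loci: int = 3,
                chip_enrichment: float = 4.0, igg_percent_input: float = 0.05
                ) -> pd.DataFrame:
    """Ct tables for expression (reference-gene) and ChIP (percent-input) qPCR.

    Ct values are constructed by inverting the quantification formulas, so
    with ``ct_noise_sd = 0`` the downstream computations recover the planted
    fold changes and enrichments exactly.
    """
    if chip_enrichment <= 0 or igg_percent_input <= 0:
        raise ValueError("enrichment parameters must be positive")
    rng = np.random.default_rng(stage_seed(config.seed, "qpcr"))
    rows = []
    high, low = config.strains
    de_genes = [config.driver_gene] + list(
        truth.index[(truth["planted_log2fc_sirna"] != 0) & ~truth["is_driver"]][:n_expr_loci - 1])
    ref_ct = 20.0
    for rep in range(1, 4):
        for group in ("scrambled", "knockdown"):
            sid = f"{group}_r{rep}"
            rows.append((sid, REFERENCE_GENE, "expression", "none", group,
                         ref_ct + rng.normal(0, config.ct_noise_sd), np.nan))
            for gid in de_genes:
                fc = float(truth.loc[gid, "planted_log2fc_sirna"])
                dct = 3.0 - fc / 2.0 if group == "scrambled" else 3.0 + fc / 2.0
                rows.append((sid, gid, "expression", "none", group,
                             ref_ct + dct + rng.normal(0, config.ct_noise_sd), np.nan))

    bound_high = truth.index[truth[_bound_col(high, config.conditions[0])]
                             & ~truth["is_driver"]][:n_chip_loci]
    for strain, fold in ((high, chip_enrichment), (low, max(1.0, chip_enrichment / 2))):
        for rep in range(1, 4):
            sid = f"{strain}_chip_r{rep}"
            for gid in bound_high:
                ct_input = 24.0
                rows.append((sid, gid, "chip", "input", strain,
                             ct_input + rng.normal(0, config.ct_noise_sd), np.nan))
                for ab, pct in (("TF", igg_percent_input * fold),
                                ("IgG", igg_percent_input)):
                    ct = ct_input - np.log2(pct / (100.0 * config.input_fraction))
                    rows.append((sid, gid, "chip", ab, strain,
                                 ct + rng.normal(0, config.ct_noise_sd),
                                 config.input_fraction))
    return pd.DataFrame(rows, columns=["sample_id", "locus", "assay", "antibody",
                                       "group", "ct", "input_fraction"])
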