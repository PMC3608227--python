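"""End-to-end orchestration: simulate -> peaks -> annotate -> DE ->
timecourse -> correlate -> integrate -> qPCR -> report.

``run_all`` executes the stages in the analysis order on a synthetic study
generated from a single :class:`PipelineConfig`, writes every artefact under
an output directory, and records a manifest (config, per-stage seeds,
sha256 of every file). Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation, diffexpr, integration, io, peaks as pk, qpcr, synth
from .util import stage_seed

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the analysis, defaulting to the study's values."""

    posterior_threshold: float = 0.9
    lambda1_cut: float = 0.7
    score_cut: float = -2.25
    tss_window: int = 20_000
    promoter_window: int = 20_000
    upstream_range: tuple[int, int] = (10_000, 50_000)
    corr_p_cut: float = 0.001
    fdr: float = 0.05
    fc_cuts: tuple[float, ...] = (3.0, 2.0)
    extend_bp: int = 200
    bin_bp: int = 10
    n_perm: int = 500
    basis_df: int = 3
    seed: int = 0
    sim: synth.SimConfig = field(default_factory=synth.SimConfig)

    def validate(self) -> None:
        if not 0 <= self.posterior_threshold <= 1:
            raise ValueError("posterior_threshold outside [0, 1]")
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr outside (0, 1]")
        if not 0 < self.corr_p_cut <= 1:
            raise ValueError("corr_p_cut outside (0, 1]")
        if self.tss_window <= 0 or self.promoter_window <= 0:
            raise ValueError("windows must be positive")
        lo, hi = self.upstream_range
        if not 0 <= lo < hi:
            raise ValueError("upstream_range must be an increasing pair")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.extend_bp <= 0 or self.bin_bp <= 0:
            raise ValueError("extend_bp and bin_bp must be positive")
        self.sim.validate()

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, sim=dataclasses.replace(self.sim, seed=seed))


def validation_config(seed: int = 0, n_perm: int = 300) -> PipelineConfig:
    """The bundled end-to-end validation fixture: a reduced synthetic study
    (80 genes on two 4 Mb chromosomes) sized so a full pipeline run takes
    under a second while exercising every planted category."""
    sim = synth.SimConfig(
        n_genes=80, chrom_sizes=(("chr1", 4_000_000), ("chr2", 4_000_000)),
        n_planted_correlated=24, n_planted_de=16, n_planted_bound=12,
        read_depth=3_000, n_background_bins=80, seed=seed)
    return PipelineConfig(n_perm=n_perm, seed=seed, sim=sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir: str | Path,
            write_wig_tracks: bool = False) -> dict:
    """Run the full synthetic analysis; returns the in-memory result bundle.

    Stage order mirrors the analysis narrative: synthetic study generation,
    bin filtering and merging into peaks, peak-to-gene annotation with
    cistrome summary, knockdown DE (basal and LPS), timecourse DE between
    strains, driver correlation screen, primary-target integration with
    network export, and qPCR quantification.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    high, low = sim.strains
    basal, lps = sim.conditions

    log.info("stage 1: synthetic study (n_genes=%d, seed=%d)", sim.n_genes, sim.seed)
    truth = synth.make_truth(sim)
    genome = synth.make_toy_genome(sim)
    tc = synth.simulate_timecourse(genome.genes, truth, sim)
    sirna = synth.simulate_sirna(genome.genes, truth, sim)
    peak_sets = synth.simulate_peaks(genome, truth, sim)
    ct_table = synth.simulate_ct(truth, sim)

    io.write_gff3(genome.genes, out / "genes.gff3")
    io.write_fasta(genome.sequences, out / "genome.fa")
    io.write_table(truth, out / "truth.tsv")
    io.write_expression(tc, out / "timecourse_expr.tsv", out / "timecourse_samples.tsv")
    io.write_expression(sirna, out / "sirna_expr.tsv", out / "sirna_samples.tsv")
    io.write_table(ct_table, out / "ct_table.tsv", index=False)

    log.info("stage 2: peak processing")
    genome_str = {c: genome.sequence_str(c) for c in genome.sequences}
    called: dict[tuple[str, str], list[pk.Peak]] = {}
    motif_fraction: dict[str, float] = {}
    for (strain, cond), bundle in peak_sets.items():
        tag = f"{strain}_{cond}".replace(".", "_")
        io.write_bins_tsv(bundle["bins"], out / f"bins_{tag}.tsv")
        io.write_bed6(bundle["reads"], out / f"reads_{tag}.bed")
        bins = pk.bins_from_frame(bundle["bins"])
        merged = pk.call_peaks(bins, config.posterior_threshold,
                               config.lambda1_cut, config.score_cut)
        called[(strain, cond)] = merged
        io.write_bed6(io.peaks_to_bed(merged), out / f"peaks_{tag}.bed")
        frac, _ = pk.ap1_consensus_scan(merged, genome_str)
        motif_fraction[f"{strain}_{cond}"] = frac
        log.info("  %s %s: %d bins -> %d peaks (motif fraction %.2f)",
                 strain, cond, len(bins), len(merged), frac)
        if write_wig_tracks:
            track = pk.make_wig(bundle["reads"], genome.chrom_sizes,
                                config.extend_bp, config.bin_bp)
            io.write_wig(track, out / f"coverage_{tag}.wig", config.bin_bp)

    log.info("stage 3: annotation")
    annotations = {}
    for key, merged in called.items():
        annotations[key] = annotation.link_peaks_to_genes(
            merged, genome.genes, config.tss_window, config.promoter_window,
            config.upstream_range)
    summary = annotation.summarize_linkage(
        {f"{s} {c}": a for (s, c), a in annotations.items()})
    io.write_table(summary, out / "cistrome_summary.tsv")
    linked = {cond: annotation.linked_gene_sets(annotations[(high, cond)])
              for cond in sim.conditions}
    ann_rows = []
    for (strain, cond), anns in annotations.items():
        for a in anns:
            ann_rows.append((strain, cond, a.peak_id, a.gene_id or "",
                             a.feature, a.dist_to_tss, a.linked))
    io.write_table(pd.DataFrame(ann_rows, columns=[
        "strain", "condition", "peak_id", "gene_id", "feature",
        "dist_to_tss", "linked"]), out / "peak_annotations.tsv", index=False)

    log.info("stage 4: knockdown differential expression")
    de_results = {}
    for cond in sim.conditions:
        mask = sirna.samples["condition"] == cond
        expr = sirna.values.loc[:, sirna.samples.loc[mask, "sample_id"]]
        labels = sirna.samples.loc[mask, "sirna"].to_numpy()
        de = diffexpr.two_group_de(expr, labels, reference="scrambled",
                                   n_perm=config.n_perm, fdr=config.fdr,
                                   seed=stage_seed(config.seed, f"de_{cond}"))
        de_results[cond] = de
        io.write_table(de, out / f"sirna_de_{cond}.tsv")
        for cut in config.fc_cuts:
            top = diffexpr.threshold_filter(de, cut, config.fdr)
            io.write_table(top, out / f"sirna_de_{cond}_fc{cut:g}.tsv")
        log.info("  %s: %d called at %.0f%% FDR", cond, int(de["called"].sum()),
                 100 * config.fdr)

    log.info("stage 5: strain timecourse differential expression")
    tc_de = diffexpr.timecourse_de(
        tc.values, tc.samples["strain"].to_numpy(),
        tc.samples["timepoint"].to_numpy(), n_perm=config.n_perm,
        basis_df=config.basis_df, fdr=config.fdr,
        seed=stage_seed(config.seed, "timecourse_de"))
    io.write_table(tc_de, out / "timecourse_de.tsv")
    log.info("  %d genes called at %.0f%% FDR", int(tc_de["called"].sum()),
             100 * config.fdr)

    log.info("stage 6: driver correlation screen")
    corr = integration.driver_correlation(tc.values, sim.driver_gene)
    io.write_table(corr, out / "driver_correlation.tsv")
    correlated = integration.select_correlated(corr, sim.driver_gene,
                                               config.corr_p_cut)

    log.info("stage 7: integration (%d correlated transcripts)", len(correlated))
    targets = {}
    for cond in sim.conditions:
        tgt = integration.call_primary_targets(
            correlated, de_results[cond], linked[cond], cond, corr=corr,
            de_condition=cond, peaks_condition=cond)
        targets[cond] = tgt
        frame = pd.DataFrame(
            [(t.gene_id, t.condition, t.direction, t.rho, t.sirna_fc,
              ",".join(t.peak_ids)) for t in tgt],
            columns=["gene_id", "condition", "direction", "rho", "sirna_fc",
                     "peak_ids"])
        io.write_table(frame, out / f"primary_targets_{cond}.tsv", index=False)
        graph = integration.build_network(tgt, sim.driver_gene)
        integration.write_sif(graph, out / f"network_{cond}.sif")
        integration.write_graphml(graph, out / f"network_{cond}.graphml")
        ring = integration.ring_summary(correlated, linked[cond], de_results[cond])
        io.write_table(ring, out / f"ring_summary_{cond}.tsv")
        log.info("  %s: %d primary targets", cond, len(tgt))

    log.info("stage 8: qPCR quantification")
    expr_ct = ct_table[ct_table["assay"] == "expression"]
    qpcr_expr = qpcr.comparative_ct(expr_ct, group_col="group",
                                    reference_group="scrambled")
    io.write_table(qpcr_expr, out / "qpcr_expression.tsv")
    chip_rows = []
    chip_ct = ct_table[ct_table["assay"] == "chip"]
    for (group, locus), sub in chip_ct.groupby(["group", "locus"], sort=True):
        piv = sub.pivot_table(index="sample_id", columns="antibody", values="ct")
        frac = sub["input_fraction"].dropna().iloc[0]
        pi_tf = [qpcr.percent_input(r["TF"], r["input"], frac)
                 for _, r in piv.iterrows()]
        pi_igg = [qpcr.percent_input(r["IgG"], r["input"], frac)
                  for _, r in piv.iterrows()]
        folds = [qpcr.fold_over_igg(r["TF"] - r["input"], r["IgG"] - r["input"])
                 for _, r in piv.iterrows()]
        chip_rows.append((group, locus, float(pd.Series(pi_tf).mean()),
                          float(pd.Series(pi_igg).mean()),
                          float(pd.Series(folds).mean())))
    qpcr_chip = pd.DataFrame(chip_rows, columns=[
        "group", "locus", "percent_input_tf", "percent_input_igg",
        "fold_over_igg"])
    io.write_table(qpcr_chip, out / "qpcr_chip.tsv", index=False)

    manifest = _write_manifest(config, out)
    return {
        "config": config, "truth": truth, "genome": genome,
        "timecourse": tc, "sirna": sirna, "peaks": called,
        "annotations": annotations, "summary": summary, "linked": linked,
        "de": de_results, "timecourse_de": tc_de, "correlation": corr,
        "correlated": correlated, "targets": targets,
        "motif_fraction": motif_fraction, "qpcr_expression": qpcr_expr,
        "qpcr_chip": qpcr_chip, "manifest": manifest,
    }


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=list))


def _write_manifest(config: PipelineConfig, out: Path) -> dict:
    files = {p.name: _sha256(p) for p in sorted(out.iterdir())
             if p.is_file() and p.name != "manifest.json"}
    body = {
        "config": _config_dict(config),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in
                        ("genome", "timecourse", "sirna", "peaks", "qpcr",
                         "timecourse_de")},
        "files": files,
    }
    body["manifest_hash"] = hashlib.sha256(
        json.dumps(body, sort_keys=True).encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(body, fh, indent=2, sort_keys=True)
    return body
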