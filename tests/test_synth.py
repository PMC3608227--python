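"""The planted-truth generator: determinism, design arithmetic, planted
effect recovery and null calibration."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import tftargets.io as tio
from tftargets.annotation import GeneModel
from tftargets.synth import (ExpressionMatrix, SimConfig, _bound_col,
                             expected_primary, make_toy_genome, make_truth,
                             simulate_sirna, simulate_timecourse)


def tiny_config(**kw):
    base = dict(n_genes=20, chrom_sizes=(("chr1", 2_000_000),),
                n_planted_correlated=8, n_planted_de=6, n_planted_bound=5,
                read_depth=500, n_background_bins=30, seed=5)
    base.update(kw)
    return SimConfig(**base)


def _fake_genes(gene_ids):
    return [GeneModel(g, "chr1", "+", i * 100_000, i * 100_000 + 5_000)
            for i, g in enumerate(gene_ids)]


class TestConfig:
    def test_timepoints_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError, match="timepoints"):
            tiny_config(timepoints=(2.0, 4.0)).validate()
        with pytest.raises(ValueError, match="timepoints"):
            tiny_config(timepoints=(0.0, 4.0, 2.0)).validate()

    def test_fold_tiers_must_span_both_cutoffs(self):
        with pytest.raises(ValueError, match="fold_tiers"):
            tiny_config(fold_tiers=(2.5, 2.2)).validate()

    def test_planted_counts_bounded_by_gene_count(self):
        with pytest.raises(ValueError, match="n_planted"):
            tiny_config(n_planted_de=100).validate()


class TestTruth:
    def test_every_gene_appears_once(self):
        truth = make_truth(tiny_config())
        assert truth.index.is_unique and len(truth) == 20

    def test_expected_primary_is_the_conjunction(self):
        """Recompute the flag independently from the planted columns."""
        cfg = tiny_config()
        truth = make_truth(cfg)
        high = cfg.strains[0]
        for cond in cfg.conditions:
            recomputed = ((truth["planted_rho"].abs() >= 0.8)
                          & (truth["planted_log2fc_sirna"] != 0)
                          & truth[_bound_col(high, cond)]
                          & ~truth["is_driver"])
            assert (truth[f"expected_primary_{cond}"] == recomputed).all()
            assert (truth[f"expected_primary_{cond}"]
                    == expected_primary(truth, high, cond)).all()

    def test_primary_sets_nonempty_and_nested_conditions(self):
        truth = make_truth(tiny_config())
        basal = set(truth.index[truth["expected_primary_basal"]])
        lps = set(truth.index[truth["expected_primary_LPS"]])
        assert basal and lps and basal <= lps

    def test_low_strain_bound_sets_nested_in_high(self):
        cfg = tiny_config()
        truth = make_truth(cfg)
        high, low = cfg.strains
        for cond in cfg.conditions:
            high_set = set(truth.index[truth[_bound_col(high, cond)]])
            low_set = set(truth.index[truth[_bound_col(low, cond)]])
            assert low_set < high_set


class TestToyGenome:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = tiny_config()
        for d in ("a", "b"):
            g = make_toy_genome(cfg)
            (tmp_path / d).mkdir()
            tio.write_gff3(g.genes, tmp_path / d / "genes.gff3")
            tio.write_fasta(g.sequences, tmp_path / d / "genome.fa")
        assert (tmp_path / "a/genes.gff3").read_bytes() == \
            (tmp_path / "b/genes.gff3").read_bytes()
        assert (tmp_path / "a/genome.fa").read_bytes() == \
            (tmp_path / "b/genome.fa").read_bytes()

    def test_empty_gene_set_still_valid(self, tmp_path):
        cfg = tiny_config(n_genes=0, n_planted_correlated=0, n_planted_de=0,
                          n_planted_bound=0, chrom_sizes=(("chr1", 200_000),))
        g = make_toy_genome(cfg)
        assert g.genes == []
        tio.write_gff3(g.genes, tmp_path / "empty.gff3")
        assert tio.read_gff3(tmp_path / "empty.gff3") == []

    def test_fifty_genes_pairwise_nonoverlapping_by_exhaustive_check(self):
        cfg = tiny_config(n_genes=50, chrom_sizes=(("chr1", 5_000_000),
                                                   ("chr2", 5_000_000)),
                          n_planted_correlated=12, n_planted_de=8,
                          n_planted_bound=6)
        genes = make_toy_genome(cfg).genes
        assert len(genes) == 50
        for a in genes:
            for b in genes:
                if a is not b and a.chrom == b.chrom:
                    assert a.end <= b.start or b.end <= a.start

    def test_genome_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            make_toy_genome(tiny_config(chrom_sizes=(("chr1", 300_000),)))

    def test_gff3_round_trip(self, tmp_path):
        g = make_toy_genome(tiny_config())
        tio.write_gff3(g.genes, tmp_path / "genes.gff3")
        back = tio.read_gff3(tmp_path / "genes.gff3")
        assert back == sorted(g.genes, key=lambda x: (x.chrom, x.start, x.gene_id))


class TestTimecourse:
    def test_matrix_dimensions_follow_the_design(self):
        cfg = tiny_config()
        genes = _fake_genes(make_truth(cfg).index)
        m = simulate_timecourse(genes, make_truth(cfg), cfg)
        assert m.values.shape == (20, 2 * len(cfg.timepoints) * cfg.n_replicates)
        assert list(m.values.columns) == list(m.samples["sample_id"])

    def test_noiseless_full_correlation_is_exact(self):
        cfg = tiny_config(noise_sd=0.0)
        truth = make_truth(cfg)
        truth.loc["g0001", "planted_rho"] = 1.0
        genes = _fake_genes(truth.index)
        m = simulate_timecourse(genes, truth, cfg)
        rho = stats.spearmanr(m.values.loc[cfg.driver_gene],
                              m.values.loc["g0001"]).statistic
        assert rho == 1.0

    def test_driver_absent_raises(self):
        cfg = tiny_config()
        truth = make_truth(cfg)
        genes = _fake_genes([g for g in truth.index if g != cfg.driver_gene])
        with pytest.raises(KeyError, match="driver"):
            simulate_timecourse(genes, truth, cfg)

    def test_null_rho_centred_and_p_uniform(self):
        """Monte-Carlo calibration: uncorrelated genes give near-zero rho
        and approximately uniform p-values (coarse KS)."""
        from tftargets.integration import driver_correlation
        cfg = tiny_config(n_genes=600, chrom_sizes=(("chr1", 60_000_000),),
                          n_planted_correlated=0, n_planted_de=0,
                          n_planted_bound=0)
        truth = make_truth(cfg)
        genes = _fake_genes(truth.index)
        m = simulate_timecourse(genes, truth, cfg)
        res = driver_correlation(m.values, cfg.driver_gene).drop(cfg.driver_gene)
        # E|rho| under the null is ~0.8/sqrt(n-1) ~= 0.14 at n=32 samples
        assert res["rho"].abs().mean() < 0.2
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 1e-4

    def test_same_seed_identical_matrix(self):
        cfg = tiny_config()
        truth = make_truth(cfg)
        genes = _fake_genes(truth.index)
        m1 = simulate_timecourse(genes, truth, cfg)
        m2 = simulate_timecourse(genes, truth, cfg)
        assert m1.values.equals(m2.values)


class TestSirna:
    def test_noiseless_fold_recovery_at_planted_tier(self):
        from tftargets.diffexpr import fold_change
        cfg = tiny_config(noise_sd=0.0)
        truth = make_truth(cfg)
        genes = _fake_genes(truth.index)
        m = simulate_sirna(genes, truth, cfg)
        basal = m.samples["condition"] == "basal"
        expr = m.values.loc[:, m.samples.loc[basal, "sample_id"]]
        labels = m.samples.loc[basal, "sirna"].to_numpy()
        fc = fold_change(expr, labels, reference="scrambled")
        planted = truth["planted_log2fc_sirna"]
        tier = planted[planted.abs().between(1.6, 1.8)].index[0]  # log2(3.3)
        assert abs(fc.loc[tier]) == pytest.approx(3.3, abs=1e-9)
        assert np.sign(fc.loc[tier]) == np.sign(planted.loc[tier])

    def test_null_generator_yields_no_de_calls(self):
        """All planted folds zero: group means equal within noise and the
        5% FDR caller stays near zero calls (>= 500 genes)."""
        from tftargets.diffexpr import two_group_de
        cfg = tiny_config(n_genes=520, chrom_sizes=(("chr1", 50_000_000),),
                          n_planted_correlated=0, n_planted_de=0,
                          n_planted_bound=0)
        truth = make_truth(cfg)
        truth["planted_log2fc_sirna"] = 0.0  # include the driver
        genes = _fake_genes(truth.index)
        m = simulate_sirna(genes, truth, cfg)
        basal = m.samples["condition"] == "basal"
        expr = m.values.loc[:, m.samples.loc[basal, "sample_id"]]
        labels = m.samples.loc[basal, "sirna"].to_numpy()
        res = two_group_de(expr, labels, reference="scrambled", n_perm=200,
                           seed=0)
        assert res["called"].mean() <= 0.075

    def test_too_few_replicates_rejected(self):
        cfg = tiny_config(n_replicates=1)
        truth = make_truth(cfg)
        with pytest.raises(ValueError, match="replicates"):
            simulate_sirna(_fake_genes(truth.index), truth, cfg)


class TestPeaksGenerator:
    def test_decoy_fraction_zero_means_overfit_filter_is_a_noop(self):
        from tftargets.peaks import bins_from_frame, filter_bins, overfit_filter
        cfg = tiny_config(decoy_fraction=0.0)
        genome = make_toy_genome(cfg)
        sets = __import__("tftargets").synth.simulate_peaks(
            genome, make_truth(cfg), cfg)
        for bundle in sets.values():
            kept = filter_bins(bins_from_frame(bundle["bins"]), 0.9)
            assert overfit_filter(kept) == kept

    def test_same_seed_identical_bins(self):
        import tftargets.synth as synth
        cfg = tiny_config()
        truth = make_truth(cfg)
        b1 = synth.simulate_peaks(make_toy_genome(cfg), truth, cfg)
        b2 = synth.simulate_peaks(make_toy_genome(cfg), truth, cfg)
        for key in b1:
            assert b1[key]["bins"].equals(b2[key]["bins"])
            assert b1[key]["reads"].equals(b2[key]["reads"])
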