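"""Ground-truth behaviour of the synthetic panel generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from atscan import synth
from atscan.experiments import hudson_fst


def _small_cfg(**kw):
    defaults = dict(n_accessions=30, n_markers=200, n_genes=20, seed=7)
    defaults.update(kw)
    return synth.PanelConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"fst": 1.0},
            {"fst": -0.1},
            {"n_accessions": 0},
            {"heritability": 1.5},
            {"causal_snps": ((500, 0.3),)},
            {"mediator_genes": ((25, 10, 1.0, 0.2),)},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _small_cfg(**kw)

    def test_roundtrip_dict(self):
        cfg = _small_cfg(causal_snps=((3, 0.5),))
        assert synth.PanelConfig.from_dict(cfg.to_dict()) == cfg


class TestGenotypes:
    def test_same_seed_byte_identical_panels(self, tmp_path):
        cfg = _small_cfg(causal_snps=((3, 0.5),), mediator_genes=((2, 100, 1.0, 0.3),))
        p1 = synth.write_panel(synth.simulate_panel(cfg), tmp_path / "a")
        p2 = synth.write_panel(synth.simulate_panel(cfg), tmp_path / "b")
        for name in ("genotypes", "expression", "q", "traits", "truth"):
            assert p1[name].read_bytes() == p2[name].read_bytes(), name

    def test_q_rows_sum_to_one(self):
        snps, q, _ = synth.simulate_genotypes(_small_cfg())
        assert np.allclose(q.sum(axis=1).to_numpy(), 1.0, atol=1e-12)
        assert (q.to_numpy() >= 0).all()

    def test_genotype_codes_and_map(self):
        cfg = _small_cfg()
        snps, _, _ = synth.simulate_genotypes(cfg)
        vals = snps.genotypes.to_numpy()
        assert np.all(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        assert snps.marker_map["chrom"].nunique() >= 2
        for _, sub in snps.marker_map.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing

    def test_zero_fst_means_identical_subpop_frequencies(self):
        _, _, parts = synth.simulate_genotypes(_small_cfg(fst=0.0))
        freqs = parts["subpop_freqs"]
        assert np.abs(freqs[0] - freqs[1]).max() == 0.0

    def test_fst_recovered_by_hudson_estimator(self):
        """Balding–Nichols draws at Fst 0.2: the Hudson ratio-of-averages
        over 5000 markers sits within ±0.03 of the target."""
        cfg = _small_cfg(n_accessions=20, n_markers=5000, fst=0.2, seed=5)
        _, _, parts = synth.simulate_genotypes(cfg)
        est = hudson_fst(parts["subpop_freqs"])
        assert est == pytest.approx(0.2, abs=0.03)

    def test_homoeologue_duplication_correlates_pairs(self):
        cfg = _small_cfg(n_markers=400, dup_fraction=0.2, missing_rate=0.0, seed=9)
        snps, _, parts = synth.simulate_genotypes(cfg)
        assert parts["dup_pairs"]
        G = snps.genotypes.to_numpy()
        cors = []
        for a, c in parts["dup_pairs"]:
            ga, gc = G[:, a], G[:, c]
            if np.std(ga) > 0 and np.std(gc) > 0:
                cors.append(np.corrcoef(ga, gc)[0, 1])
        assert np.mean(cors) > 0.5


class TestExpression:
    def test_zero_cis_effect_gives_flat_regression(self):
        cfg = _small_cfg(mediator_genes=((2, 100, 0.0, 0.0),), missing_rate=0.0)
        snps, _, _ = synth.simulate_genotypes(cfg)
        expr = synth.simulate_expression(cfg, snps)
        x = snps.genotypes.iloc[:, 100].to_numpy()
        y = np.log2(expr.rpkm.iloc[2].to_numpy())
        slope, _ = np.polyfit(x, y, 1)
        se = np.std(y) / (np.std(x) * np.sqrt(len(x)))
        assert abs(slope) < 3 * se

    def test_noise_free_class_contrast_is_twice_the_cis_effect(self):
        e = 0.8
        cfg = _small_cfg(
            mediator_genes=((2, 100, e, 0.0),), expr_noise_sd=0.0, missing_rate=0.0
        )
        snps, _, _ = synth.simulate_genotypes(cfg)
        expr = synth.simulate_expression(cfg, snps)
        x = snps.genotypes.iloc[:, 100].to_numpy()
        y = np.log2(expr.rpkm.iloc[2].to_numpy())
        assert y[x == 2.0].mean() - y[x == 0.0].mean() == pytest.approx(2 * e, abs=1e-12)

    def test_cis_effect_recovered_by_ols(self):
        e = 1.2
        cfg = _small_cfg(n_accessions=60, mediator_genes=((2, 100, e, 0.0),), missing_rate=0.0)
        snps, _, _ = synth.simulate_genotypes(cfg)
        expr = synth.simulate_expression(cfg, snps)
        x = snps.genotypes.iloc[:, 100].to_numpy()
        y = np.log2(expr.rpkm.iloc[2].to_numpy())
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        se = np.sqrt(resid.var(ddof=2) / (len(x) * x.var()))
        assert abs(slope - e) < 2 * se

    def test_rpkm_non_negative(self):
        cfg = _small_cfg()
        snps, _, _ = synth.simulate_genotypes(cfg)
        expr = synth.simulate_expression(cfg, snps)
        assert (expr.rpkm.to_numpy() >= 0).all()


class TestTraits:
    def test_full_heritability_no_effects_means_identical_replicates(self):
        cfg = _small_cfg(heritability=1.0, polygenic_var=0.0)
        panel = synth.simulate_panel(cfg)
        within = panel.traits.groupby("accession")["fmax"].var()
        assert within.max() == pytest.approx(0.0, abs=1e-24)

    def test_slr_correlation_near_target(self):
        cfg = synth.PanelConfig(
            n_accessions=79, n_markers=300, n_genes=5, slr_correlation=0.4, seed=13
        )
        panel = synth.simulate_panel(cfg)
        means = panel.traits.groupby("accession")[["fmax", "slr"]].mean()
        r = means["fmax"].corr(means["slr"])
        # Fisher-z 95% sampling band around 0.4 at n=79 is about +/-0.2
        assert r == pytest.approx(0.4, abs=0.2)

    def test_planted_causal_effect_recovered_by_ols(self):
        cfg = _small_cfg(
            n_accessions=79, causal_snps=((50, 0.7),), polygenic_var=0.05,
            missing_rate=0.0, seed=21,
        )
        panel = synth.simulate_panel(cfg)
        y = panel.traits.groupby("accession")["fmax"].mean().to_numpy()
        x = panel.snps.genotypes.iloc[:, 50].to_numpy()
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        se = np.sqrt(resid.var(ddof=2) / (len(x) * x.var()))
        assert abs(slope - 0.7) < 2 * se

    def test_subpop_effect_shifts_trait_with_ancestry(self):
        cfg = _small_cfg(n_accessions=60, subpop_effect=2.0, polygenic_var=0.0, seed=17)
        panel = synth.simulate_panel(cfg)
        means = panel.traits.groupby("accession")["fmax"].mean()
        anc = panel.q.iloc[:, 0]
        assert means.corr(anc) > 0.5

    def test_ground_truth_records_configuration(self, small_panel):
        truth = small_panel.truth
        assert truth.causal_snps == small_panel.config.causal_snps
        assert truth.mediator_genes == small_panel.config.mediator_genes
        assert len(truth.causal_markers) == 1
        assert truth.genetic_values.index.equals(small_panel.snps.accessions)


class TestBendCurve:
    def test_noise_free_peak_is_exact(self):
        curve = synth.simulate_bend_curve(24.2, 19.9)
        assert curve.force.max() == 24.2
        pre = curve.force[: int(np.argmax(curve.force)) + 1]
        slopes = np.diff(pre) / np.diff(curve.displacement[: len(pre)])
        assert np.allclose(slopes, 19.9, rtol=1e-9)

    @pytest.mark.parametrize("fmax, slope", [(0.0, 1.0), (1.0, 0.0), (-2.0, 3.0)])
    def test_invalid_parameters_rejected(self, fmax, slope):
        with pytest.raises(ValueError):
            synth.simulate_bend_curve(fmax, slope)

    def test_same_seed_identical(self):
        c1 = synth.simulate_bend_curve(10.0, 8.0, noise_sd=0.3, seed=4)
        c2 = synth.simulate_bend_curve(10.0, 8.0, noise_sd=0.3, seed=4)
        assert np.array_equal(c1.force, c2.force)


class TestSpectra:
    def test_zero_ester_level_has_no_1740_band(self):
        s0 = synth.simulate_spectra(0.0, 1, seed=1, noise_sd=0.0)[0]
        bare = synth.simulate_spectra(0.0, 1, seed=1, noise_sd=0.0, band_amplitude=0.0)[0]
        near_1740 = (s0.wavenumber > 1735) & (s0.wavenumber < 1745)
        # only the far tail of the 1624 band distinguishes them there
        assert np.allclose(
            s0.absorbance[near_1740], bare.absorbance[near_1740], atol=1e-9
        )
        # while the 1624 band is present at full amplitude
        assert s0.value_at(1624.0) > bare.value_at(1624.0)

    def test_same_seed_identical_spectra(self):
        s1 = synth.simulate_spectra(0.5, 2, seed=8)
        s2 = synth.simulate_spectra(0.5, 2, seed=8)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.absorbance, b.absorbance)

    def test_ester_level_out_of_range(self):
        with pytest.raises(ValueError):
            synth.simulate_spectra(1.2, 1, seed=0)

    def test_difference_spectrum_sign_matches_construction(self):
        from atscan import ftir

        hi = synth.simulate_spectra(0.9, 3, seed=2)
        lo = synth.simulate_spectra(0.1, 3, seed=3)
        diff = ftir.difference_spectrum(hi, lo)
        assert diff.band_values[ftir.ESTER_BAND] > 0
        assert diff.band_values[ftir.CARBOXYLATE_BAND] < 0
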