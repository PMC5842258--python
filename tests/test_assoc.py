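"""MAF filtering, kinship, REML/MLM machinery and the GEM scans."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atscan import synth
from atscan.assoc import (
    ExpressionMatrix,
    SnpMatrix,
    expression_as_trait,
    fit_null_model,
    gem_scan,
    genomic_inflation,
    kinship_matrix,
    maf_filter,
    mlm_scan,
    ols_scan,
    trait_effect_percent,
)


def _matrix_from_calls(calls: np.ndarray) -> SnpMatrix:
    n, m = calls.shape
    acc = pd.Index([f"a{i}" for i in range(n)], name="accession")
    markers = pd.Index([f"m{j}" for j in range(m)], name="marker")
    return SnpMatrix(
        genotypes=pd.DataFrame(calls.astype(float), index=acc, columns=markers),
        marker_map=pd.DataFrame({"chrom": "A1", "pos": np.arange(1, m + 1)}, index=markers),
    )


class TestMafFilter:
    def test_boundary_maf_exactly_at_threshold_is_retained(self):
        # 20 accessions, minor allele count 2 of 40 -> MAF exactly 0.05
        calls = np.zeros((20, 1))
        calls[0, 0] = 2.0
        snps = _matrix_from_calls(calls)
        kept, report = maf_filter(snps, 0.05)
        assert kept.n_markers == 1
        assert report.n_removed_maf == 0

    def test_maf_below_threshold_removed(self):
        # 25 accessions, minor allele count 2 of 50 -> MAF 0.04
        calls = np.zeros((25, 1))
        calls[0, 0] = 2.0
        kept, report = maf_filter(_matrix_from_calls(calls), 0.05)
        assert kept.n_markers == 0
        assert report.n_removed_maf == 1

    def test_all_missing_marker_logged_separately(self):
        calls = np.column_stack([np.full(10, np.nan), np.tile([0.0, 2.0], 5)])
        kept, report = maf_filter(_matrix_from_calls(calls), 0.05)
        assert kept.n_markers == 1
        assert report.n_all_missing == 1

    def test_idempotent(self, small_panel):
        once, r1 = maf_filter(small_panel.snps)
        twice, r2 = maf_filter(once)
        assert list(once.markers) == list(twice.markers)
        assert r2.n_removed_maf == 0 and r2.n_all_missing == 0

    def test_threshold_domain(self, small_panel):
        with pytest.raises(ValueError):
            maf_filter(small_panel.snps, 0.0)


class TestKinship:
    def test_matches_two_loop_oracle(self, rng):
        calls = rng.integers(0, 3, size=(5, 10)).astype(float)
        calls[0, 3] = np.nan
        calls[4, 7] = np.nan
        snps = _matrix_from_calls(calls)
        K = kinship_matrix(snps).to_numpy()

        # brute force: per-marker mean imputation, centering, scaling
        G = calls.copy()
        p = np.nanmean(G, axis=0) / 2.0
        for j in range(G.shape[1]):
            G[np.isnan(G[:, j]), j] = 2.0 * p[j]
        denom = 2.0 * np.sum(p * (1 - p))
        expected = np.zeros((5, 5))
        for i in range(5):
            for k in range(5):
                expected[i, k] = sum(
                    (G[i, j] - 2 * p[j]) * (G[k, j] - 2 * p[j]) for j in range(10)
                ) / denom
        assert np.allclose(K, expected, atol=1e-10)

    def test_duplicated_accessions_share_diagonal_value(self, rng):
        calls = rng.integers(0, 3, size=(4, 30)).astype(float)
        calls[1] = calls[0]
        K = kinship_matrix(_matrix_from_calls(calls)).to_numpy()
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-12)
        assert K[0, 1] == pytest.approx(K[1, 1], rel=1e-12)

    def test_permutation_conjugation(self, small_panel):
        snps = small_panel.snps
        K = kinship_matrix(snps)
        perm = list(reversed(snps.accessions))
        snps_perm = SnpMatrix(
            genotypes=snps.genotypes.loc[perm],
            marker_map=snps.marker_map,
            alleles=snps.alleles,
        )
        K_perm = kinship_matrix(snps_perm)
        assert np.allclose(K_perm.to_numpy(), K.loc[perm, perm].to_numpy(), atol=1e-12)

    def test_positive_semidefinite_after_repair(self, small_panel):
        K = kinship_matrix(small_panel.snps).to_numpy()
        assert np.linalg.eigvalsh(K)[0] >= -1e-8


def _structured_trait(K: np.ndarray, delta: float, rng) -> np.ndarray:
    n = K.shape[0]
    evals, evecs = np.linalg.eigh(K)
    L = evecs * np.sqrt(np.clip(evals, 0, None))
    return L @ rng.standard_normal(n) + math.sqrt(delta) * rng.standard_normal(n)


def _dense_reml_loglik(delta: float, y, X, K) -> float:
    """Naive dense REML evaluation: explicit inverses and determinants."""
    n, p = X.shape
    V = K + delta * np.eye(n)
    Vi = np.linalg.inv(V)
    XViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XViX) @ X.T @ Vi
    ypy = float(y @ P @ y)
    nq = n - p
    _, ld_v = np.linalg.slogdet(V)
    _, ld_xvx = np.linalg.slogdet(XViX)
    _, ld_xx = np.linalg.slogdet(X.T @ X)
    return 0.5 * (
        nq * math.log(nq / (2 * math.pi))
        - nq
        - nq * math.log(ypy)
        - ld_v
        - ld_xvx
        + ld_xx
    )


class TestNullModelReml:
    def test_matches_dense_brute_force_likelihood(self, rng):
        n = 30
        cfg = synth.PanelConfig(
            n_accessions=n, n_markers=120, n_genes=2, fst=0.3, missing_rate=0.0, seed=8
        )
        snps, q, _ = synth.simulate_genotypes(cfg)
        K = kinship_matrix(snps)
        y = pd.Series(_structured_trait(K.to_numpy(), 1.0, rng), index=K.index)
        vc = fit_null_model(y, q, K)
        X = np.column_stack([np.ones(n), q.to_numpy()[:, :-1]])
        dense = _dense_reml_loglik(vc.delta, y.to_numpy(), X, K.to_numpy())
        assert vc.loglik == pytest.approx(dense, abs=1e-6)

    def test_pure_noise_trait_drives_delta_to_upper_bound(self, rng):
        n = 40
        snps = _matrix_from_calls(rng.integers(0, 3, (n, 150)).astype(float))
        K = kinship_matrix(snps)
        y = pd.Series(rng.standard_normal(n), index=K.index)
        vc = fit_null_model(y, None, K)
        assert vc.at_bound and vc.delta >= 1e4
        assert vc.sigma_g2 * vc.delta == pytest.approx(vc.sigma_e2)

    def test_delta_recovered_within_factor_two(self):
        rng = np.random.default_rng(99)
        n = 200
        cfg = synth.PanelConfig(
            n_accessions=n, n_markers=400, n_genes=2, fst=0.3, missing_rate=0.0, seed=12
        )
        snps, _, _ = synth.simulate_genotypes(cfg)
        K = kinship_matrix(snps)
        estimates = []
        for _ in range(20):
            y = pd.Series(_structured_trait(K.to_numpy(), 1.0, rng), index=K.index)
            estimates.append(fit_null_model(y, None, K).delta)
        med = float(np.median(estimates))
        assert 0.5 <= med <= 2.0


class TestMlmScan:
    def test_identity_kinship_matches_ols_ftest(self, rng):
        n, m = 50, 100
        calls = rng.integers(0, 3, (n, m)).astype(float)
        snps = _matrix_from_calls(calls)
        K = pd.DataFrame(np.eye(n), index=snps.accessions, columns=snps.accessions)
        y = pd.Series(rng.standard_normal(n), index=snps.accessions)
        res = mlm_scan(y, snps, None, K)
        import statsmodels.api as sm

        for j in np.linspace(0, m - 1, 25, dtype=int):
            g = calls[:, j]
            if np.ptp(g) == 0:
                continue
            fit = sm.OLS(y.to_numpy(), sm.add_constant(g)).fit()
            assert res["pvalue"].iloc[j] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_permuted_trait_gives_uniform_pvalues(self):
        rng = np.random.default_rng(42)
        cfg = synth.PanelConfig(
            n_accessions=50, n_markers=5000, n_genes=2, polygenic_var=0.3, seed=77
        )
        prng = np.random.default_rng(cfg.seed)
        snps, q, _ = synth.simulate_genotypes(cfg, prng)
        expr = synth.simulate_expression(cfg, snps, prng)
        traits, _ = synth.simulate_traits(cfg, snps, expr, q, prng)
        y = traits.groupby("accession")["fmax"].mean()
        y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        filtered, _ = maf_filter(snps)
        K = kinship_matrix(filtered)
        res = mlm_scan(y_perm, filtered, q, K)
        pv = res["pvalue"].dropna().to_numpy()
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_affine_trait_rescaling_leaves_pvalues_unchanged(self, small_panel):
        snps, _ = maf_filter(small_panel.snps)
        K = kinship_matrix(snps)
        y = small_panel.traits.groupby("accession")["fmax"].mean()
        r1 = mlm_scan(y, snps, small_panel.q, K)
        r2 = mlm_scan(3.7 * y - 12.0, snps, small_panel.q, K)
        p1, p2 = r1["pvalue"].to_numpy(), r2["pvalue"].to_numpy()
        ok = ~np.isnan(p1)
        assert np.allclose(p1[ok], p2[ok], rtol=1e-8, atol=1e-12)

    def test_gls_converges_to_ols_at_large_delta(self, rng):
        from atscan.assoc import VarianceComponents

        n, m = 40, 30
        calls = rng.integers(0, 3, (n, m)).astype(float)
        snps = _matrix_from_calls(calls)
        K = kinship_matrix(snps)
        y = pd.Series(rng.standard_normal(n), index=snps.accessions)
        vc = VarianceComponents(1.0, 1e5, 1e5, 0.0, n, 1)
        gls = mlm_scan(y, snps, None, K, vc=vc)
        ident = pd.DataFrame(np.eye(n), index=snps.accessions, columns=snps.accessions)
        ols = mlm_scan(y, snps, None, ident, vc=vc)
        ok = gls["pvalue"].notna()
        assert np.allclose(
            gls.loc[ok, "beta"], ols.loc[ok, "beta"], rtol=1e-3, atol=1e-4
        )
        assert np.allclose(
            gls.loc[ok, "pvalue"], ols.loc[ok, "pvalue"], rtol=5e-3, atol=1e-4
        )

    def test_monomorphic_marker_flagged(self, rng):
        calls = rng.integers(0, 3, (12, 3)).astype(float)
        calls[:, 1] = 2.0
        snps = _matrix_from_calls(calls)
        K = kinship_matrix(snps)
        y = pd.Series(rng.standard_normal(12), index=snps.accessions)
        res = mlm_scan(y, snps, None, K)
        assert res.loc[1, "status"] == "monomorphic"
        assert np.isnan(res.loc[1, "pvalue"])
        assert (res.loc[res["status"] == "ok", "pvalue"] > 0).all()

    def test_planted_causal_marker_tops_scan_and_controls_inflation(self, small_panel):
        filtered, _ = maf_filter(small_panel.snps)
        K = kinship_matrix(filtered)
        y = small_panel.traits.groupby("accession")["fmax"].mean()
        res = mlm_scan(y, filtered, small_panel.q, K)
        ok = res.dropna(subset=["pvalue"])
        top2 = set(ok.nsmallest(2, "pvalue")["marker"])
        planted = {small_panel.truth.causal_markers[0], small_panel.truth.cis_markers[0]}
        assert top2 & planted

    def test_results_keep_genome_order(self, small_panel):
        filtered, _ = maf_filter(small_panel.snps)
        K = kinship_matrix(filtered)
        y = small_panel.traits.groupby("accession")["fmax"].mean()
        res = mlm_scan(y, filtered, small_panel.q, K)
        assert list(res["marker"]) == list(filtered.markers)


class TestGemScan:
    def test_trait_as_its_own_gem_reaches_floor(self, small_panel):
        y = small_panel.traits.groupby("accession")["fmax"].mean()
        rpkm = small_panel.expr.rpkm.copy()
        rpkm.iloc[0] = np.exp2(y.loc[rpkm.columns].to_numpy()) - 1.0
        expr = ExpressionMatrix(rpkm=rpkm, gene_map=small_panel.expr.gene_map)
        res = gem_scan(y, expr, small_panel.q)
        assert res.loc[0, "pvalue"] < 1e-12
        assert res.loc[0, "r2"] == pytest.approx(1.0, abs=1e-9)

    def test_noise_gems_give_uniform_pvalues(self, rng):
        n, g = 60, 400
        acc = pd.Index([f"a{i}" for i in range(n)], name="accession")
        rpkm = pd.DataFrame(
            np.exp2(rng.normal(3, 1, size=(g, n))),
            index=pd.Index([f"u{i}" for i in range(g)], name="unigene"),
            columns=acc,
        )
        expr = ExpressionMatrix(rpkm=rpkm)
        y = pd.Series(rng.standard_normal(n), index=acc)
        res = gem_scan(y, expr, None)
        assert stats.kstest(res["pvalue"].dropna(), "uniform").pvalue > 0.01

    def test_planted_mediator_attains_minimum_p(self, small_panel):
        y = small_panel.traits.groupby("accession")["fmax"].mean()
        res = gem_scan(y, small_panel.expr, small_panel.q)
        ok = res.dropna(subset=["pvalue"])
        assert ok.loc[ok["pvalue"].idxmin(), "unigene"] == small_panel.truth.mediator_unigenes[0]

    def test_zero_variance_gene_flagged(self, small_panel):
        y = small_panel.traits.groupby("accession")["fmax"].mean()
        rpkm = small_panel.expr.rpkm.iloc[:5].copy()
        rpkm.iloc[3] = 7.0
        res = gem_scan(y, ExpressionMatrix(rpkm=rpkm), small_panel.q)
        assert res.loc[3, "status"] == "zero_variance"

    def test_negative_association_reported_with_sign(self, small_panel):
        y = small_panel.traits.groupby("accession")["fmax"].mean()
        rpkm = small_panel.expr.rpkm.iloc[:3].copy()
        rpkm.iloc[0] = np.exp2(-2.0 * y.loc[rpkm.columns].to_numpy() + 40.0)
        res = gem_scan(y, ExpressionMatrix(rpkm=rpkm), small_panel.q)
        assert res.loc[0, "beta"] < 0


class TestExpressionAsTrait:
    def test_cis_marker_attains_minimum_p(self, small_panel):
        filtered, _ = maf_filter(small_panel.snps)
        K = kinship_matrix(filtered)
        res = expression_as_trait(
            small_panel.truth.mediator_unigenes[0],
            small_panel.expr,
            filtered,
            small_panel.q,
            K,
        )
        ok = res.dropna(subset=["pvalue"])
        assert ok.loc[ok["pvalue"].idxmin(), "marker"] == small_panel.truth.cis_markers[0]

    def test_composition_identity_with_manual_mlm_call(self, small_panel):
        filtered, _ = maf_filter(small_panel.snps)
        K = kinship_matrix(filtered)
        unigene = small_panel.truth.mediator_unigenes[0]
        res = expression_as_trait(unigene, small_panel.expr, filtered, small_panel.q, K)
        y = pd.Series(
            np.log2(small_panel.expr.rpkm.loc[unigene].to_numpy() + 1.0),
            index=small_panel.expr.accessions,
        ).loc[filtered.accessions]
        manual = mlm_scan(y, filtered, small_panel.q, K)
        assert np.allclose(
            res["pvalue"].to_numpy(), manual["pvalue"].to_numpy(), equal_nan=True
        )

    def test_unknown_unigene_rejected(self, small_panel):
        filtered, _ = maf_filter(small_panel.snps)
        K = kinship_matrix(filtered)
        with pytest.raises(KeyError):
            expression_as_trait("nope", small_panel.expr, filtered, small_panel.q, K)


class TestTraitEffectPercent:
    def test_definition(self):
        y = np.array([10.0, 10.0, 20.0, 20.0, 30.0])
        g = np.array([0.0, 0.0, 2.0, 2.0, 1.0])
        assert trait_effect_percent(y, g) == pytest.approx(50.0)

    def test_equal_class_means_give_zero(self):
        y = np.array([5.0, 5.0, 1.0, 9.0])
        g = np.array([0.0, 2.0, 1.0, 1.0])
        assert trait_effect_percent(y, g) == 0.0

    def test_toy_table_matches_hand_computation(self):
        y = np.array([12.0, 14.0, 9.0, 16.0, 20.0, 22.0, 11.0, 18.0])
        g = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 2.0, 1.0, 2.0])
        mean0 = (12 + 14 + 9) / 3.0
        mean2 = (20 + 22 + 18) / 3.0
        assert trait_effect_percent(y, g) == pytest.approx(
            abs(mean2 - mean0) / (22.0 - 9.0) * 100.0
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            trait_effect_percent(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            trait_effect_percent(np.array([3.0, 3.0]), np.array([0.0, 2.0]))


def test_genomic_inflation_of_uniform_pvalues_is_one():
    rng = np.random.default_rng(5)
    lam = genomic_inflation(rng.uniform(size=20000))
    assert lam == pytest.approx(1.0, abs=0.05)


def test_naive_scan_inflated_under_structure():
    """With an ancestry-confounded trait the uncorrected scan inflates
    while the Q+K-corrected scan stays near nominal."""
    cfg = synth.PanelConfig(
        n_accessions=60, n_markers=800, n_genes=2, polygenic_var=0.3,
        subpop_effect=1.5, seed=55,
    )
    prng = np.random.default_rng(cfg.seed)
    snps, q, _ = synth.simulate_genotypes(cfg, prng)
    expr = synth.simulate_expression(cfg, snps, prng)
    traits, _ = synth.simulate_traits(cfg, snps, expr, q, prng)
    y = traits.groupby("accession")["fmax"].mean()
    filtered, _ = maf_filter(snps)
    K = kinship_matrix(filtered)
    lam_mlm = genomic_inflation(mlm_scan(y, filtered, q, K)["pvalue"].dropna())
    lam_naive = genomic_inflation(ols_scan(y, filtered)["pvalue"].dropna())
    assert lam_naive > 1.2
    assert lam_naive > lam_mlm
    assert lam_mlm < 1.3
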