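"""Logistic association, meta-analysis, effective tests, PCs, scans."""

import numpy as np
import pandas as pd
import pytest
from numpy.random import default_rng

from finescan.assoc import (
    AssocResult,
    compute_pcs,
    effective_tests,
    fit_logistic,
    meta_fixed,
    phenotype_selection,
    region_correlation,
    scan_region,
)
from finescan.simulate import (
    DiseaseModel,
    PopulationSpec,
    RegionSpec,
    simulate_cohort,
    simulate_panel,
    simulate_single_causal_region,
)

from conftest import make_gm


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        # cases 30 exposed / 70 not; controls 10 / 90 -> log-OR = ln(27/7)
        g = np.array([1.0] * 30 + [0.0] * 70 + [1.0] * 10 + [0.0] * 90)
        y = np.array([1.0] * 100 + [0.0] * 100)
        res = fit_logistic(g, y)
        assert res.evaluable
        assert res.beta == pytest.approx(np.log((30 * 90) / (70 * 10)), abs=1e-6)
        # Wald SE of a 2x2 log-OR: sqrt(sum of reciprocal cell counts)
        assert res.se == pytest.approx(np.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90), rel=1e-4)
        assert res.loglik >= res.null_loglik - 1e-8

    def test_null_permutations_rarely_exceed_z4(self):
        rng = default_rng(0)
        g = rng.binomial(2, 0.3, 200).astype(float)
        y = np.array([1.0] * 100 + [0.0] * 100)
        n_big = 0
        for _ in range(1000):
            z = fit_logistic(g, rng.permutation(y)).z
            n_big += abs(z) >= 4
        assert n_big <= 10

    def test_degenerate_inputs_not_evaluable(self):
        y = np.array([1.0, 1, 0, 0])
        assert not fit_logistic(np.zeros(4), y).evaluable
        assert not fit_logistic(np.array([0.0, 1, 2, 1]), np.ones(4)).evaluable
        # quasi-complete separation
        res = fit_logistic(np.array([2.0] * 20 + [0.0] * 20), np.array([1.0] * 20 + [0.0] * 20))
        assert not res.evaluable

    def test_missing_dosages_dropped(self):
        g = np.array([np.nan, 1, 0, 2, 1, 0, 1, 2])
        y = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        res = fit_logistic(g, y)
        assert res.n == 7

    def test_matches_brute_force_maximizer(self):
        """IRLS agrees with an independent two-parameter likelihood
        maximization (scipy Nelder-Mead on a from-scratch log-likelihood)."""
        from scipy.optimize import minimize

        rng = default_rng(42)
        for _ in range(20):
            g = rng.binomial(2, rng.uniform(0.2, 0.5), 50).astype(float)
            y = rng.permutation(np.array([1.0] * 25 + [0.0] * 25))
            if g.min() == g.max():
                continue
            res = fit_logistic(g, y)
            assert res.evaluable

            def nll(theta):
                eta = theta[0] + theta[1] * g
                return -np.sum(y * eta - np.log1p(np.exp(eta)))

            opt = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
            assert res.loglik == pytest.approx(-opt.fun, abs=1e-4)
            assert res.beta == pytest.approx(opt.x[1], abs=1e-4)


class TestMetaFixed:
    def _res(self, beta, se, pop):
        return AssocResult(variant_id="v", population=pop, beta=beta, se=se,
                           z=beta / se, p=0.5, n=10, evaluable=True)

    def test_single_population_identity(self):
        r = self._res(0.3, 0.15, "AA")
        m = meta_fixed([r])
        assert m.beta == pytest.approx(0.3) and m.se == pytest.approx(0.15)

    def test_closed_form_inverse_variance(self):
        m = meta_fixed([self._res(0.2, 0.1, "A"), self._res(0.4, 0.2, "B")])
        assert m.beta == pytest.approx(0.24, abs=1e-12)
        assert m.se == pytest.approx(0.2 / np.sqrt(5), abs=1e-6)  # 0.0894427

    def test_symmetric_effects_cancel(self):
        m = meta_fixed([self._res(0.5, 0.1, "A"), self._res(-0.5, 0.1, "B")])
        assert m.beta == pytest.approx(0.0, abs=1e-12)
        assert m.p == pytest.approx(1.0)

    def test_not_evaluable_skipped_and_empty_rejected(self):
        dead = AssocResult(variant_id="v", population="C")
        m = meta_fixed([self._res(0.2, 0.1, "A"), dead])
        assert m.populations == ["A"]
        with pytest.raises(ValueError, match="no evaluable"):
            meta_fixed([dead])

    def test_combined_se_not_larger_than_any_input(self):
        m = meta_fixed([self._res(0.1, 0.12, "A"), self._res(0.2, 0.4, "B")])
        assert m.se <= 0.12

    def test_equal_strata_halve_the_variance(self):
        region = RegionSpec("r", 30, founder_haplotypes=100, common_fraction=1.0)
        pop = PopulationSpec("P", 400, 400, 0.05)
        ses_single, ses_meta = [], []
        for seed in range(5):
            panel = simulate_panel(region, [pop], seed=seed)
            gm, sheet = simulate_cohort(panel, DiseaseModel(), [pop], seed=100 + seed, read_stats=None)
            half = np.arange(gm.n_samples) % 2 == 0
            res_a = scan_region(gm.take_samples(half), sheet[half].reset_index(drop=True), population="A")
            res_b = scan_region(gm.take_samples(~half), sheet[~half].reset_index(drop=True), population="B")
            for ra, rb in zip(res_a, res_b):
                if ra.evaluable and rb.evaluable:
                    ses_single.append(ra.se)
                    ses_meta.append(meta_fixed([ra, rb]).se)
        ratio = np.mean(np.array(ses_meta) / np.array(ses_single))
        assert ratio == pytest.approx(1 / np.sqrt(2), rel=0.05)


class TestEffectiveTests:
    def test_identity_full_rank(self):
        m = effective_tests({"r": np.eye(50)})
        assert m.meff_by_region["r"] == 50
        assert m.threshold == pytest.approx(0.05 / 50)

    def test_perfect_ld_rank_one(self):
        m = effective_tests({"r": np.ones((5, 5))})
        assert m.meff_by_region["r"] == 1

    def test_two_block_structure(self):
        R = np.zeros((5, 5))
        R[:3, :3] = 1.0
        R[3:, 3:] = 1.0
        assert effective_tests({"r": R}).meff_by_region["r"] == 2

    def test_total_sums_over_regions(self):
        m = effective_tests({"a": np.eye(3), "b": np.ones((4, 4))}, alpha=0.05)
        assert m.total_meff == 4 and m.threshold == pytest.approx(0.0125)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="no evaluable"):
            effective_tests({"r": np.empty((0, 0))})


class TestComputePcs:
    def test_pc1_separates_diverged_subgroups(self):
        region = RegionSpec("r", 400, founder_haplotypes=200, switch_prob=0.5, common_fraction=1.0)
        pops = [PopulationSpec("A", 60, 60, 0.1), PopulationSpec("B", 60, 60, 0.1)]
        panel = simulate_panel(region, pops, seed=3)
        gm, sheet = simulate_cohort(panel, DiseaseModel(), pops, seed=4, read_stats=None)
        pcs = compute_pcs(gm, k=3)
        label = (sheet["population"] == "A").to_numpy().astype(float)
        assert abs(np.corrcoef(pcs[:, 0], label)[0, 1]) > 0.9

    def test_structureless_data_has_flat_spectrum(self):
        region = RegionSpec("r", 40, founder_haplotypes=1000, switch_prob=0.5, common_fraction=1.0)
        pop = PopulationSpec("A", 250, 250, 0.05)
        ratios = []
        for seed in range(20):
            panel = simulate_panel(region, [pop], seed=seed)
            gm, _ = simulate_cohort(panel, DiseaseModel(), [pop], seed=500 + seed, read_stats=None)
            f = np.nanmean(gm.dosage, axis=0) / 2
            keep = np.minimum(f, 1 - f) > 0.05
            Z = (gm.dosage[:, keep] - 2 * f[keep]) / np.sqrt(2 * f[keep] * (1 - f[keep]))
            lam = np.linalg.svd(Z, compute_uv=False) ** 2
            ratios.append(lam[0] / lam.mean())
        assert np.mean(ratios) < 2

    def test_duplicating_every_sample_leaves_scores_unchanged(self, small_cohort):
        gm, _, _ = small_cohort
        pcs = compute_pcs(gm, k=3)
        dup = make_gm(
            np.vstack([gm.dosage, gm.dosage]),
            samples=[f"a{i}" for i in range(gm.n_samples)] + [f"b{i}" for i in range(gm.n_samples)],
        )
        pcs_dup = compute_pcs(dup, k=3)[: gm.n_samples]
        for c in range(3):
            diff = min(np.max(np.abs(pcs_dup[:, c] - pcs[:, c])),
                       np.max(np.abs(pcs_dup[:, c] + pcs[:, c])))
            assert diff < 1e-6

    def test_k_exceeding_rank_rejected(self):
        gm = make_gm(np.tile([[0.0, 1.0, 2.0, 1.0]], (6, 1)).T)
        with pytest.raises(ValueError):
            compute_pcs(gm, k=4)


class TestScanRegion:
    def _sheet(self, gm, n_cases):
        return pd.DataFrame(
            {
                "sample_id": gm.samples,
                "population": "P",
                "status": ["case"] * n_cases + ["control"] * (gm.n_samples - n_cases),
                "er_status": ["negative"] * (n_cases // 2)
                + ["positive"] * (n_cases - n_cases // 2)
                + ["unknown"] * (gm.n_samples - n_cases),
            }
        )

    def test_self_conditioning_not_evaluable(self, small_cohort):
        gm, sheet, causal = small_cohort
        vid = gm.variant_ids[causal]
        res = scan_region(gm, sheet, condition_on=[vid])
        assert not res[causal].evaluable
        assert res[causal].note == "conditioned on"

    def test_collinear_conditioning_rejected(self):
        rng = default_rng(0)
        dosage = rng.integers(0, 3, (40, 3)).astype(float)
        dosage[:, 1] = dosage[:, 0]
        gm = make_gm(dosage)
        sheet = self._sheet(gm, 20)
        ids = list(gm.variant_ids)
        with pytest.raises(ValueError, match="collinear"):
            scan_region(gm, sheet, condition_on=[ids[0], ids[1]])

    def test_maf_floor_flags_rare_variants(self):
        dosage = np.zeros((200, 2))
        dosage[30:80, 0] = 1.0  # common, carried by cases and controls
        dosage[120:160, 0] = 1.0
        dosage[0, 1] = 1.0  # singleton, MAF 0.0025
        gm = make_gm(dosage)
        res = scan_region(gm, self._sheet(gm, 100))
        assert res[0].evaluable
        assert not res[1].evaluable and "maf" in res[1].note

    def test_er_negative_phenotype_excludes_other_cases(self):
        dosage = default_rng(1).integers(0, 3, (40, 1)).astype(float)
        gm = make_gm(dosage)
        sheet = self._sheet(gm, 20)
        mask, y = phenotype_selection(sheet, "er_neg")
        assert mask.sum() == 10 + 20  # ER- cases + controls
        assert y.sum() == 10
        res = scan_region(gm, sheet, phenotype="er_neg")
        assert res[0].n == 30

    def test_conditioning_absorbs_ld_signal(self):
        """Conditioning on the causal variant suppresses its LD proxies."""
        suppressed, unconditioned = [], []
        for seed in range(6):
            gm, sheet, causal = simulate_single_causal_region(
                seed=3000 + seed, n_cases=800, n_controls=800,
                founder_haplotypes=6, switch_prob=0.001)
            vid = gm.variant_ids[causal]
            d = gm.dosage
            cc = d[:, causal]
            r2 = np.array([np.corrcoef(d[:, j], cc)[0, 1] ** 2 if j != causal else 1.0
                           for j in range(gm.n_variants)])
            proxies = [j for j in range(gm.n_variants) if j != causal and r2[j] > 0.8]
            if not proxies:
                continue
            plain = scan_region(gm, sheet)
            cond = scan_region(gm, sheet, condition_on=[vid])
            for j in proxies:
                if plain[j].evaluable and cond[j].evaluable:
                    unconditioned.append(abs(plain[j].z))
                    suppressed.append(abs(cond[j].z))
        assert len(suppressed) > 0
        assert np.mean(suppressed) < 2 < np.mean(unconditioned)


class TestRegionCorrelation:
    def test_missing_dosages_mean_imputed(self):
        rng = default_rng(3)
        dosage = rng.integers(0, 3, (100, 5)).astype(float)
        dosage[rng.random((100, 5)) < 0.05] = np.nan
        R = region_correlation(make_gm(dosage))
        assert R.shape == (5, 5)
        assert np.all(np.isfinite(R))
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)
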