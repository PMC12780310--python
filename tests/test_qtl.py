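import numpy as np
import pandas as pd
import pytest

import hybmap as h
from hybmap.mapfun import map_function
from hybmap.qtl import (
    effect_distribution,
    forward_qtl_search,
    genotype_probabilities,
    hk_scan,
    lod_support_interval,
    permutation_threshold,
    residualize,
)


class TestResidualize:
    def test_no_covariate_effect_is_plain_standardization(self, qtl_cross):
        table, pheno = qtl_cross
        df = pheno.copy()
        df["dummy"] = "x"  # constant covariate
        res = residualize(df, "FT", covariates=("dummy",))
        y = df["FT"].to_numpy(float)
        expect = (y - y.mean()) / np.std(y - y.mean(), ddof=1)
        assert np.allclose(res.to_numpy(), expect, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, qtl_cross):
        table, pheno = qtl_cross
        res = residualize(pheno, "FT")
        for cov in ("cross_direction", "tray"):
            d = pd.get_dummies(pheno[cov], drop_first=True)
            for c in d.columns:
                r = np.corrcoef(res.to_numpy(), d[c].to_numpy(float))[0, 1]
                assert abs(r) < 1e-8

    def test_injected_tray_effect_removed(self, small_map):
        cfg = h.CrossConfig(n_individuals=700, gmap=small_map, seed=31)
        table = h.simulate_f2_cross(cfg)
        arch = h.TraitArchitecture("y", qtls=[], residual_sd=1.0)
        pheno = h.simulate_phenotypes(
            table, [arch], covariate_effects={"tray_sd": 1.0}, seed=32
        )
        res = residualize(pheno, "y")
        tray = pd.get_dummies(pheno["tray"]).to_numpy(float)
        beta, _, _, _ = np.linalg.lstsq(tray, res.to_numpy(), rcond=None)
        r2 = 1 - np.sum((res.to_numpy() - tray @ beta) ** 2) / np.sum(res**2)
        assert r2 < 0.001

    def test_too_few_observations_rejected(self, qtl_cross):
        table, pheno = qtl_cross
        with pytest.raises(ValueError):
            residualize(pheno.iloc[:5], "FT")


class TestGenotypeProbabilities:
    def test_typed_marker_mass_on_observed_code(self, mendelian_cross):
        probs = genotype_probabilities(mendelian_cross, step_cM=0.0, error_prob=0.0)
        g = mendelian_cross.genotypes
        for i in (0, 17, 211):
            for k in range(probs.n_positions):
                obs = g[i, k]
                if obs >= 0:
                    assert probs.probs[i, k, obs] == pytest.approx(1.0, abs=1e-9)

    def test_untyped_chromosome_returns_prior(self, small_map):
        cfg = h.CrossConfig(n_individuals=30, gmap=small_map, seed=41)
        t = h.simulate_f2_cross(cfg)
        t.genotypes[0, :11] = -1  # wipe chromosome 1 for one individual
        probs = genotype_probabilities(t, step_cM=1.0)
        on1 = (probs.positions["chrom"] == 1).to_numpy()
        assert np.allclose(probs.probs[0, on1], [0.25, 0.5, 0.25], atol=1e-9)

    def test_normalization_everywhere(self, mendelian_cross):
        probs = genotype_probabilities(mendelian_cross, step_cM=1.0,
                                       error_prob=1e-4)
        assert np.allclose(probs.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_midpoint_matches_enumeration_oracle(self):
        """Midpoint between two NN markers 20 cM apart: posterior equals
        exhaustive enumeration over two-interval gamete configurations."""
        gm = h.GeneticMap(pd.DataFrame(
            {"marker": ["a", "b"], "chrom": [1, 1], "cM": [0.0, 20.0]}
        ))
        genos = np.zeros((1, 2), dtype=np.int8)  # NN at both ends
        t = h.F2GenotypeTable(ids=["i1"], genotypes=genos, gmap=gm,
                              covariates=pd.DataFrame(index=["i1"]))
        probs = genotype_probabilities(t, step_cM=10.0)
        mid = probs.positions.index[probs.positions["cM"] == 10.0][0]
        # oracle: per gamete, P(allele at mid | N at both ends)
        r1 = map_function(10.0)
        r12 = map_function(20.0)
        pN = (1 - r1) * (1 - r1) / (1 - r12)  # no double recombination path
        pS = r1 * r1 / (1 - r12)
        assert pN + pS == pytest.approx(1.0, abs=1e-12)
        expect = np.array([pN * pN, 2 * pN * pS, pS * pS])
        assert np.allclose(probs.probs[0, mid], expect, atol=1e-9)


class TestHKScan:
    def test_estimates_match_ols_at_typed_marker(self, qtl_cross):
        table, pheno = qtl_cross
        res = residualize(pheno, "FT")
        probs = genotype_probabilities(table, step_cM=0.0)
        scan = hk_scan(probs, res)
        j = table.gmap.nearest_marker(1, 25.0)
        # direct regression on observed codes (no missing data here)
        g = table.genotypes[:, j].astype(float)
        x = g - 1.0
        z = (g == 1).astype(float)
        X = np.column_stack([np.ones(len(g)), x, z])
        beta, _, _, _ = np.linalg.lstsq(X, res.to_numpy(), rcond=None)
        row = scan.scan[scan.scan["marker"] == table.gmap.table["marker"].iloc[j]]
        assert row["a"].iloc[0] == pytest.approx(beta[1], abs=1e-9)
        assert row["d"].iloc[0] == pytest.approx(beta[2], abs=1e-9)

    def test_lod_invariant_to_affine_residual_transform(self, qtl_cross):
        table, pheno = qtl_cross
        res = residualize(pheno, "FT")
        probs = genotype_probabilities(table, step_cM=2.0)
        lod1 = hk_scan(probs, res).scan["lod"]
        lod2 = hk_scan(probs, 3.0 * res + 7.0).scan["lod"]
        assert np.allclose(lod1, lod2, atol=1e-8)

    def test_degenerate_perfect_fit_capped(self, mendelian_cross):
        probs = genotype_probabilities(mendelian_cross, step_cM=0.0)
        j = 4
        g = mendelian_cross.genotypes[:, j].astype(float)
        y = pd.Series(g - 1.0, index=mendelian_cross.ids)
        scan = hk_scan(probs, y)
        assert scan.scan["lod"].iloc[j] == 50.0
        assert bool(scan.scan["flagged"].iloc[j])

    def test_qtl_recovery(self, small_map):
        errs, ahats = [], []
        for s in range(15):
            cfg = h.CrossConfig(n_individuals=600, gmap=small_map, seed=100 + s)
            t = h.simulate_f2_cross(cfg)
            arch = h.TraitArchitecture(
                "y", qtls=[h.QTL(1, 25.0, a=0.35, d=0.1)], residual_sd=1.0
            )
            ph = h.simulate_phenotypes(t, [arch], seed=200 + s)
            res = residualize(ph, "y")
            probs = genotype_probabilities(t, step_cM=1.0)
            scan = hk_scan(probs, res).scan
            pk = scan.loc[scan["lod"].idxmax()]
            errs.append(abs(pk["cM"] - 25.0) if pk["chrom"] == 1 else np.inf)
            ahats.append(pk["a"])
        assert np.median(errs) <= 5.0
        assert abs(np.mean(ahats) - 0.35) <= 0.1


class TestPermutationThreshold:
    def test_seeded_and_deterministic(self, mendelian_cross, null_residuals):
        probs = genotype_probabilities(mendelian_cross, step_cM=2.0)
        t1 = permutation_threshold(probs, null_residuals, n_perm=200, seed=3)
        t2 = permutation_threshold(probs, null_residuals, n_perm=200, seed=3)
        assert t1 == t2
        t3 = permutation_threshold(probs, null_residuals, n_perm=200, seed=4)
        assert t1 != t3

    def test_alpha_one_gives_min_of_maxima(self, mendelian_cross, null_residuals):
        probs = genotype_probabilities(mendelian_cross, step_cM=2.0)
        tmin = permutation_threshold(probs, null_residuals, n_perm=100,
                                     alpha=1.0, seed=5)
        t05 = permutation_threshold(probs, null_residuals, n_perm=100,
                                    alpha=0.05, seed=5)
        assert tmin < t05

    def test_constant_residuals_rejected(self, mendelian_cross):
        y = pd.Series(np.ones(mendelian_cross.n_individuals),
                      index=mendelian_cross.ids)
        probs = genotype_probabilities(mendelian_cross, step_cM=5.0)
        with pytest.raises(ValueError):
            permutation_threshold(probs, y, n_perm=100)

    def test_null_threshold_in_expected_band(self):
        """Full-scale intercross null scan: the 5% genome-wide LOD
        threshold sits in the canonical 2.5-4.5 band."""
        gm = h.default_map()
        cfg = h.CrossConfig(n_individuals=742, gmap=gm, seed=51)
        t = h.simulate_f2_cross(cfg)
        rng = np.random.default_rng(52)
        y = pd.Series(rng.normal(size=742), index=t.ids)
        probs = genotype_probabilities(t, step_cM=1.0)
        thr = permutation_threshold(probs, y, n_perm=300, seed=53)
        assert 2.5 <= thr <= 4.5


class TestLodSupportInterval:
    def _scan_df(self, cm, lod):
        return pd.DataFrame({"chrom": 1, "cM": cm, "lod": lod})

    def test_single_point_spike(self):
        cm = np.arange(0.0, 11.0)
        lod = np.zeros(11)
        lod[5] = 8.0
        lo, hi = lod_support_interval(self._scan_df(cm, lod), 1, 5.0)
        assert (lo, hi) == (4.0, 6.0)

    def test_flat_curve_spans_chromosome(self):
        cm = np.arange(0.0, 11.0)
        lo, hi = lod_support_interval(self._scan_df(cm, np.full(11, 3.0)), 1, 5.0)
        assert (lo, hi) == (0.0, 10.0)

    def test_quadratic_crossings_within_one_step(self):
        cm = np.arange(0.0, 40.25, 0.25)
        peak, curv = 20.0, 0.06
        lod = 10.0 - curv * (cm - peak) ** 2
        lo, hi = lod_support_interval(self._scan_df(cm, lod), 1, peak, drop=1.5)
        half = np.sqrt(1.5 / curv)
        assert abs(lo - (peak - half)) <= 0.5
        assert abs(hi - (peak + half)) <= 0.5


class TestForwardSearch:
    def test_null_truth_gives_empty_model(self, small_map):
        empty = 0
        for s in range(12):
            cfg = h.CrossConfig(n_individuals=400, gmap=small_map, seed=300 + s)
            t = h.simulate_f2_cross(cfg)
            rng = np.random.default_rng(400 + s)
            y = pd.Series(rng.normal(size=400), index=t.ids)
            probs = genotype_probabilities(t, step_cM=2.0)
            thr = permutation_threshold(probs, y, n_perm=300, seed=500 + s)
            peaks = forward_qtl_search(probs, y, thr)
            empty += len(peaks) == 0
        assert empty >= 11

    def test_two_unlinked_qtls_recovered(self, small_map):
        both = 0
        reps = 20
        for s in range(reps):
            cfg = h.CrossConfig(n_individuals=742, gmap=small_map, seed=600 + s)
            t = h.simulate_f2_cross(cfg)
            arch = h.TraitArchitecture(
                "y", qtls=[h.QTL(1, 25.0, a=0.4), h.QTL(2, 25.0, a=0.3)],
                residual_sd=1.0,
            )
            ph = h.simulate_phenotypes(t, [arch], seed=700 + s)
            res = residualize(ph, "y")
            probs = genotype_probabilities(t, step_cM=1.0)
            peaks = forward_qtl_search(probs, res, threshold=3.4)
            ok = 0
            for chrom in (1, 2):
                sub = peaks[peaks["chrom"] == chrom]
                ok += (not sub.empty) and (abs(sub["cM"] - 25.0).min() <= 10.0)
            both += ok == 2
        assert both / reps >= 0.8

    def test_single_qtl_matches_single_scan(self, qtl_cross):
        table, pheno = qtl_cross
        res = residualize(pheno, "FT")
        probs = genotype_probabilities(table, step_cM=1.0)
        scan = hk_scan(probs, res)
        peaks = forward_qtl_search(probs, res, threshold=3.5, max_qtl=1)
        assert len(peaks) == 1
        g = int(scan.scan["lod"].idxmax())
        assert peaks["cM"].iloc[0] == scan.scan["cM"].iloc[g]
        assert peaks["a"].iloc[0] == pytest.approx(scan.scan["a"].iloc[g], abs=1e-6)
        assert peaks["d"].iloc[0] == pytest.approx(scan.scan["d"].iloc[g], abs=1e-6)
        assert peaks["lod"].iloc[0] == pytest.approx(scan.scan["lod"].iloc[g], abs=1e-6)


class TestEffectDistribution:
    def test_moments_match_brute_force(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        peaks = pd.DataFrame(
            {"trait": "x", "chrom": 1, "a": v, "d": v}
        )
        out = effect_distribution(peaks, distortion_chroms=(), fertility_trait="WS")
        m = v.mean()
        mu2 = np.mean((v - m) ** 2)
        mu3 = np.mean((v - m) ** 3)
        mu4 = np.mean((v - m) ** 4)
        assert out["a"]["skewness"] == pytest.approx(mu3 / mu2**1.5, rel=1e-9)
        assert out["a"]["kurtosis"] == pytest.approx(mu4 / mu2**2, rel=1e-9)
        assert out["a"]["count"] == 5

    def test_outlier_inflates_kurtosis_and_drops_w(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.05, size=30)
        with_out = np.append(base, -0.366)
        clean = effect_distribution(
            pd.DataFrame({"trait": "x", "chrom": 1, "a": base, "d": base}),
            distortion_chroms=(),
        )
        spiked = effect_distribution(
            pd.DataFrame({"trait": "x", "chrom": 1, "a": with_out, "d": with_out}),
            distortion_chroms=(),
        )
        assert spiked["d"]["kurtosis"] > 3.0
        assert spiked["d"]["shapiro_W"] < clean["d"]["shapiro_W"] - 0.05

    def test_exclusion_rules(self):
        peaks = pd.DataFrame(
            {
                "trait": ["FT", "FT", "WS", "SH"],
                "chrom": [4, 8, 8, 8],
                "a": [0.1, 0.2, 0.3, 0.4],
                "d": [0.0, 0.1, 0.2, 0.3],
                "interval_lo": [0, 10, 12, 40],
                "interval_hi": [5, 20, 22, 50],
            }
        )
        # chr4 row excluded (distortion), WS row excluded (fertility trait),
        # FT chr8 row excluded (interval overlaps the WS interval) -> 1 left
        with pytest.raises(ValueError):
            effect_distribution(peaks)
        peaks2 = pd.concat([peaks] * 3, ignore_index=True)
        out = effect_distribution(peaks2)
        assert out["retained"] == 3 and out["excluded"] == 9
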