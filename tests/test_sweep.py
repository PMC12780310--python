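import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybmap.pop_sim import DemographyConfig, HaplotypeMatrix, SweepConfig
from hybmap.pop_sim import neutral_replicates, simulate_population
from hybmap.sweep import (
    OmegaConfig,
    calibrate_threshold,
    omega_grid_scan,
    omega_statistic,
    pairwise_r2,
    qtl_sweep_overlap,
    r2_matrix,
)


def brute_force_omega(m, split, epsilon=1e-12, cap=1000.0):
    """Independent naive double-loop implementation."""
    S = m.shape[1]
    l = split

    def r2(i, j):
        a = m[:, i].astype(float)
        b = m[:, j].astype(float)
        pa, pb = a.mean(), b.mean()
        va, vb = pa * (1 - pa), pb * (1 - pb)
        if va == 0 or vb == 0:
            return 0.0
        return ((a * b).mean() - pa * pb) ** 2 / (va * vb)

    w = sum(r2(i, j) for i in range(l) for j in range(i + 1, l))
    w += sum(r2(i, j) for i in range(l, S) for j in range(i + 1, S))
    c = sum(r2(i, j) for i in range(l) for j in range(l, S))
    n_w = l * (l - 1) / 2 + (S - l) * (S - l - 1) / 2
    n_c = l * (S - l)
    if c / n_c < epsilon:
        return cap
    return min((w / n_w) / (c / n_c), cap)


class TestPairwiseR2:
    def test_identical_and_complementary_columns(self):
        a = np.array([0, 0, 1, 1, 0, 1])
        assert pairwise_r2(a, a) == pytest.approx(1.0)
        assert pairwise_r2(a, 1 - a) == pytest.approx(1.0)

    def test_independent_pattern_is_zero(self):
        assert pairwise_r2([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_missing_dropped_pairwise_and_monomorphic_nan(self):
        a = np.array([0.0, 1.0, np.nan, 1.0, 0.0])
        b = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        assert pairwise_r2(a, b) == pytest.approx(1.0)
        mono = np.array([1.0, 1.0, np.nan, 1.0, 1.0])
        assert np.isnan(pairwise_r2(mono, b))


class TestOmegaStatistic:
    def test_constant_r2_gives_one(self):
        # identical columns everywhere: every pairwise r2 is 1
        col = np.array([0, 1, 1, 0, 1, 0, 0, 1])
        m = np.tile(col[:, None], (1, 6))
        assert omega_statistic(m, 3) == pytest.approx(1.0)

    def test_perfect_sweep_signature_capped(self):
        left = np.array([0, 0, 1, 1])
        right = np.array([0, 1, 0, 1])  # r2(left, right) = 0
        m = np.column_stack([left, left, right, right])
        assert omega_statistic(m, 2, cap=1000.0) == 1000.0

    def test_too_few_sites_rejected(self):
        m = np.random.default_rng(0).integers(0, 2, size=(10, 3))
        with pytest.raises(ValueError):
            omega_statistic(m, 1)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(60):
            S = int(rng.integers(5, 18))
            H = int(rng.integers(6, 30))
            m = rng.integers(0, 2, size=(H, S))
            split = int(rng.integers(2, S - 1))
            if split < 2 or S - split < 2:
                continue
            assert omega_statistic(m, split) == pytest.approx(
                brute_force_omega(m, split), abs=1e-10
            )

    def test_invariances(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 2, size=(24, 10))
        base = omega_statistic(m, 5)
        perm = m[rng.permutation(24)]
        assert omega_statistic(perm, 5) == pytest.approx(base, abs=1e-12)
        flipped = m.copy()
        flipped[:, 4] = 1 - flipped[:, 4]
        assert omega_statistic(flipped, 5) == pytest.approx(base, abs=1e-12)


class TestGridScan:
    def _hm(self, m, pos, L):
        return HaplotypeMatrix(m.astype(np.uint8), np.asarray(pos, np.int64),
                               ["p1"] * m.shape[0], {"demography": {"L": L}})

    def test_sparse_region_undefined(self):
        rng = np.random.default_rng(5)
        m = rng.integers(0, 2, size=(20, 4))
        hm = self._hm(m, [100, 200, 48_000, 48_100], 50_000)
        cfg = OmegaConfig(grid_spacing=10_000, minwin=2_000, maxwin=5_000)
        scan = omega_grid_scan(hm, cfg)
        # interior grid points have no admissible flank pair
        mid = scan.table[(scan.table["position"] > 5_000)
                         & (scan.table["position"] < 45_000)]
        assert mid["omega"].isna().all()
        assert (mid["flag"] == "undefined").all()

    def test_grid_scan_equals_exhaustive_oracle(self):
        rng = np.random.default_rng(17)
        cfg = OmegaConfig(grid_spacing=5_000, minwin=1_000, maxwin=8_000)
        for _ in range(10):
            S = int(rng.integers(10, 40))
            pos = np.sort(rng.choice(np.arange(1, 20_001), size=S, replace=False))
            m = rng.integers(0, 2, size=(24, S))
            seg = (m.sum(0) > 0) & (m.sum(0) < 24)
            m, pos = m[:, seg], pos[seg]
            hm = self._hm(m, pos, 20_000)
            scan = omega_grid_scan(hm, cfg)
            for _, row in scan.table.iterrows():
                g = row["position"]
                best = -np.inf
                lc = [i for i, p in enumerate(pos) if g - cfg.maxwin <= p < g]
                rc = [i for i, p in enumerate(pos) if g < p <= g + cfg.maxwin]

                def sizes(dists):
                    out = set()
                    base = sum(1 for d in dists if d <= cfg.minwin)
                    if base >= 2:
                        out.add(base)
                    for k, dd in enumerate(sorted(dists)):
                        if cfg.minwin < dd <= cfg.maxwin and k + 1 >= 2:
                            out.add(k + 1)
                    return sorted(out)

                for ls, rs in itertools.product(
                    sizes([g - pos[i] for i in lc]), sizes([pos[i] - g for i in rc])
                ):
                    idx = lc[len(lc) - ls:] + rc[:rs]
                    best = max(best, brute_force_omega(m[:, idx], ls))
                if best == -np.inf:
                    assert not np.isfinite(row["omega"])
                else:
                    assert row["omega"] == pytest.approx(best, abs=1e-9)

    def test_empty_matrix_rejected(self):
        hm = self._hm(np.zeros((5, 0)), [], 10_000)
        with pytest.raises(ValueError):
            omega_grid_scan(hm, OmegaConfig())

    def test_sweep_elevates_omega_over_neutral(self):
        d = DemographyConfig(
            N_anc=200, N1=200, N2=20, t_split=80, pulses=(),
            mu=2e-6, rho=2e-6, L=50_000,
            sample_sizes={"p1": 30, "p2": 0}, burnin_factor=5,
        )
        sw = SweepConfig(position_bp=25_000, s_adv=0.6, t_intro=50, pop="p1")
        cfg = OmegaConfig(grid_spacing=5_000, minwin=2_000, maxwin=10_000,
                          cap=100.0)
        swept, neutral = [], []
        for s in range(6):
            swept.append(omega_grid_scan(simulate_population(d, sweep=sw, seed=s),
                                         cfg).max_omega)
            neutral.append(
                omega_grid_scan(simulate_population(d, seed=100 + s), cfg).max_omega
            )
        assert np.median(swept) > np.median(neutral)


class TestThresholdCalibration:
    def test_degenerate_and_order_statistics(self):
        assert calibrate_threshold([5.0] * 150) == 5.0
        v = list(range(1, 101)) * 2
        thr = calibrate_threshold(v, percentile=99)
        assert 99.0 <= thr <= 100.0
        with pytest.raises(ValueError):
            calibrate_threshold([])

    def test_exceedance_rate_near_nominal(self):
        """Fresh neutral replicates exceed a threshold calibrated on
        independent replicates at ~1%."""
        d = DemographyConfig(
            N_anc=150, N1=150, N2=30, t_split=300,
            pulses=((290, "p2", "p1", 0.1), (20, "p2", "p1", 0.05)),
            mu=8e-7, rho=5.5e-8, L=40_000,
            sample_sizes={"p1": 16, "p2": 12},
        )
        cfg = OmegaConfig(grid_spacing=8_000, minwin=2_000, maxwin=4_000)
        cal = [omega_grid_scan(hm, cfg).max_omega
               for hm in neutral_replicates(d, 150, seed=31)]
        thr = calibrate_threshold(cal, percentile=99)
        fresh = [omega_grid_scan(hm, cfg).max_omega
                 for hm in neutral_replicates(d, 250, seed=32)]
        exceed = int(np.sum(np.asarray(fresh) > thr))
        lo, hi = stats.binom.interval(0.999, 250, 0.01)
        assert lo <= exceed <= hi


class TestOverlapTest:
    def _lens(self):
        return {1: 1_000_000}

    def test_sweep_on_every_peak_gives_extreme_p(self):
        qtl = pd.DataFrame(
            {"chrom": 1, "peak_bp": [200_000, 500_000, 800_000],
             "interval_lo_bp": [150_000, 450_000, 750_000],
             "interval_hi_bp": [250_000, 550_000, 850_000]}
        )
        sweeps = pd.DataFrame(
            {"chrom": 1, "start": qtl["peak_bp"] - 1_000,
             "end": qtl["peak_bp"] + 1_000}
        )
        res = qtl_sweep_overlap(qtl, sweeps, self._lens(), n_perm=500, seed=1)
        assert res.observed_mean_distance == 0.0
        assert res.observed_overlap == 3
        assert res.p_distance == pytest.approx(1 / 501, abs=1e-9)

    def test_no_sweeps_undefined(self):
        qtl = pd.DataFrame({"chrom": [1], "peak_bp": [100], "interval_lo_bp": [50],
                            "interval_hi_bp": [150]})
        res = qtl_sweep_overlap(qtl, qtl.iloc[0:0].assign(start=1, end=1),
                                self._lens(), n_perm=10)
        assert np.isnan(res.p_overlap) and "undefined" in res.note

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(40):
            qtl = pd.DataFrame(
                {"chrom": 1, "peak_bp": rng.uniform(0, 1e6, 3),
                 "interval_lo_bp": 0.0, "interval_hi_bp": 200_000.0}
            )
            starts = rng.uniform(1, 9.5e5, 2)
            sweeps = pd.DataFrame(
                {"chrom": 1, "start": starts, "end": starts + 50_000}
            )
            res = qtl_sweep_overlap(qtl, sweeps, self._lens(), n_perm=200,
                                    seed=int(rng.integers(1e6)))
            ps.append(res.p_distance)
        # add-one empirical p-values: uniform-ish on (0, 1]
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_matches_exhaustive_relocation_oracle(self):
        """Discretized toy: permutation p agrees with exhaustive
        enumeration of sweep relocations."""
        qtl = pd.DataFrame(
            {"chrom": 1, "peak_bp": [300_000, 700_000],
             "interval_lo_bp": [200_000, 600_000],
             "interval_hi_bp": [400_000, 800_000]}
        )
        width = 60_000.0
        sweeps = pd.DataFrame(
            {"chrom": 1, "start": [280_000.0], "end": [280_000.0 + width]}
        )
        lens = self._lens()
        res = qtl_sweep_overlap(qtl, sweeps, lens, n_perm=4000, seed=2)
        # oracle: dense grid of relocations of the single sweep
        grid = np.linspace(1, lens[1] - width, 20_000)
        dists = []
        for s0 in grid:
            e0 = s0 + width
            d = [0.0 if s0 <= p <= e0 else min(abs(s0 - p), abs(e0 - p))
                 for p in qtl["peak_bp"]]
            dists.append(np.mean(d))  # mean over QTLs, single sweep
        obs = res.observed_mean_distance
        oracle_p = (1 + np.sum(np.asarray(dists) <= obs)) / (1 + len(grid))
        assert res.p_distance == pytest.approx(oracle_p, abs=0.03)
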