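"""Omega-statistic selective-sweep scanning.

A hard selective sweep leaves elevated linkage disequilibrium (LD) on
each side of the swept site but little LD across it.  The omega
statistic captures this as the ratio of mean within-flank r-squared to
mean cross-flank r-squared.  The scan evaluates omega on a bp grid,
maximizing over admissible flank windows (each flank spanning between
``minwin`` and ``maxwin`` from the grid point, with at least
``min_snps_per_flank`` SNPs); genome-wide significance comes from the
tail of max-omega values over neutral simulated replicates.  A
permutation test relates sweep windows to QTL peak positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pop_sim import HaplotypeMatrix

__all__ = [
    "OmegaConfig",
    "OmegaScan",
    "OverlapTestResult",
    "pairwise_r2",
    "r2_matrix",
    "omega_statistic",
    "omega_grid_scan",
    "calibrate_threshold",
    "qtl_sweep_overlap",
]


@dataclass(frozen=True)
class OmegaConfig:
    """Grid/window geometry of the omega scan (bp units)."""

    grid_spacing: int = 200_000
    minwin: int = 50_000
    maxwin: int = 100_000
    min_snps_per_flank: int = 2
    epsilon: float = 1e-12
    cap: float = 1_000.0

    def __post_init__(self):
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if self.minwin > self.maxwin:
            raise ValueError("minwin must be <= maxwin")
        if self.min_snps_per_flank < 2:
            raise ValueError("need at least 2 SNPs per flank")

    def scaled(self, factor: float) -> "OmegaConfig":
        """Same geometry shrunk by ``factor`` (for scaled-down replicates)."""
        return OmegaConfig(
            grid_spacing=max(1, int(self.grid_spacing / factor)),
            minwin=max(1, int(self.minwin / factor)),
            maxwin=max(1, int(self.maxwin / factor)),
            min_snps_per_flank=self.min_snps_per_flank,
            epsilon=self.epsilon,
            cap=self.cap,
        )


@dataclass
class OmegaScan:
    table: pd.DataFrame = field(repr=False)  # position, omega, flag
    threshold: Optional[float] = None

    @property
    def max_omega(self) -> float:
        vals = self.table["omega"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        return float(vals.max()) if vals.size else float("nan")

    def outlier_windows(self, cfg: OmegaConfig) -> pd.DataFrame:
        """Grid points above threshold, reported as +-maxwin spans."""
        if self.threshold is None:
            raise ValueError("no threshold set")
        hit = self.table[self.table["omega"] > self.threshold]
        return pd.DataFrame(
            {
                "start": (hit["position"] - cfg.maxwin).clip(lower=1).astype(int),
                "end": (hit["position"] + cfg.maxwin).astype(int),
                "omega": hit["omega"].to_numpy(),
            }
        )


# ---------------------------------------------------------------------------
# LD primitives
# ---------------------------------------------------------------------------
def pairwise_r2(h_i, h_j) -> float:
    """Squared allele-frequency correlation between two binary site
    columns; missing entries (NaN) are dropped pairwise.  Returns NaN if
    a site is monomorphic after the missing-drop."""
    a = np.asarray(h_i, dtype=float)
    b = np.asarray(h_j, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 2:
        return float("nan")
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        return float("nan")
    pab = np.mean(a * b)
    return float((pab - pa * pb) ** 2 / (va * vb))


def r2_matrix(m: np.ndarray) -> np.ndarray:
    """All-pairs r-squared for a complete binary haplotype block
    (haplotypes x sites)."""
    m = np.asarray(m, dtype=float)
    H = m.shape[0]
    p = m.mean(axis=0)
    cov = (m.T @ m) / H - np.outer(p, p)
    v = p * (1 - p)
    denom = np.outer(v, v)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov**2 / denom
    r2[denom == 0] = np.nan
    return r2


def omega_statistic(
    snps: np.ndarray,
    split: int,
    epsilon: float = 1e-12,
    cap: float = 1_000.0,
) -> float:
    """Omega for an ordered SNP block split after the first ``split`` sites.

    omega = [ (C(l,2)+C(S-l,2))^-1 (sum_within_left + sum_within_right) ]
            / [ (l(S-l))^-1 sum_cross ],
    with l = split and S the total number of sites.  A cross-flank LD sum
    below ``epsilon`` yields the capped maximum (perfect sweep signature).
    """
    m = np.asarray(snps)
    S = m.shape[1]
    l = int(split)
    if l < 2 or S - l < 2:
        raise ValueError("need at least 2 SNPs on each side of the split")
    r2 = r2_matrix(m)
    return _omega_from_r2(r2, l, epsilon, cap)


def _omega_from_r2(r2, l, epsilon, cap):
    S = r2.shape[0]
    iu = np.triu_indices(S, k=1)
    left = (iu[0] < l) & (iu[1] < l)
    right = iu[0] >= l
    cross = (iu[0] < l) & (iu[1] >= l)
    vals = r2[iu]
    w_sum = np.nansum(vals[left]) + np.nansum(vals[right])
    c_sum = np.nansum(vals[cross])
    n_within = l * (l - 1) // 2 + (S - l) * (S - l - 1) // 2
    n_cross = l * (S - l)
    num = w_sum / n_within
    den = c_sum / n_cross
    if den < epsilon:
        return float(cap)
    return float(min(num / den, cap))


# ---------------------------------------------------------------------------
# grid scan
# ---------------------------------------------------------------------------
def _flank_candidates(dist, minwin, maxwin, min_snps, nearest_first):
    """Candidate flank extents over sites ordered nearest-to-farthest.

    ``dist``: distances of candidate sites from the grid point, ordered
    nearest first.  Returns a list of site counts (set sizes) realizable
    as 'all sites within w' for some w in [minwin, maxwin]."""
    within_max = dist <= maxwin
    dist = dist[within_max]
    sizes = []
    base = int(np.sum(dist <= minwin))
    if base >= min_snps:
        sizes.append(base)
    for k in range(dist.size):
        if minwin < dist[k] <= maxwin and (k + 1) >= min_snps:
            sizes.append(k + 1)
    return sorted(set(sizes))


def omega_grid_scan(
    haps: HaplotypeMatrix, cfg: OmegaConfig, L: Optional[int] = None
) -> OmegaScan:
    """Maximize omega over admissible flank configurations on a bp grid.

    Positions where no configuration satisfies the window/SNP constraints
    are reported as NaN with flag ``undefined``; a vanishing cross-flank
    LD sum yields the capped omega with flag ``capped``.
    """
    if haps.n_sites == 0:
        raise ValueError("empty haplotype matrix")
    if L is None:
        L = haps.metadata.get("demography", {}).get("L") or int(haps.positions[-1])
    pos = haps.positions
    grid = np.arange(cfg.grid_spacing, L + 1, cfg.grid_spacing, dtype=int)
    rows = []
    for g in grid:
        lo = int(np.searchsorted(pos, g - cfg.maxwin))
        split = int(np.searchsorted(pos, g))  # sites strictly left of g
        hi = int(np.searchsorted(pos, g + cfg.maxwin, side="right"))
        left_pos = pos[lo:split]
        right_pos = pos[split:hi]
        ldist = g - left_pos[::-1]  # nearest first
        rdist = right_pos - g
        lsizes = _flank_candidates(ldist, cfg.minwin, cfg.maxwin,
                                   cfg.min_snps_per_flank, True)
        rsizes = _flank_candidates(rdist, cfg.minwin, cfg.maxwin,
                                   cfg.min_snps_per_flank, True)
        if not lsizes or not rsizes:
            rows.append((g, np.nan, "undefined"))
            continue
        block = haps.matrix[:, lo:hi].astype(float)
        A = np.nan_to_num(r2_matrix(block), nan=0.0)
        nL = split - lo
        nR = hi - split
        # cumulative pair sums: extending the left flank outward / the
        # right flank outward, O(W^2) for all flank sizes at once
        WL = np.zeros(nL + 1)
        for ls in range(1, nL + 1):
            i = nL - ls
            WL[ls] = WL[ls - 1] + A[i, i + 1 : nL].sum()
        WR = np.zeros(nR + 1)
        for rs in range(1, nR + 1):
            j = nL + rs - 1
            WR[rs] = WR[rs - 1] + A[j, nL : j].sum()
        right_cum = np.cumsum(A[:nL, nL:hi - lo], axis=1)  # (nL, nR)
        cross = np.cumsum(right_cum[::-1], axis=0)  # cross[ls-1, rs-1]
        ls_arr = np.array(lsizes)
        rs_arr = np.array(rsizes)
        within = (
            WL[ls_arr][:, None] + WR[rs_arr][None, :]
        ) / (
            ls_arr[:, None] * (ls_arr[:, None] - 1) / 2
            + rs_arr[None, :] * (rs_arr[None, :] - 1) / 2
        )
        cr_sum = cross[np.ix_(ls_arr - 1, rs_arr - 1)]
        cr_mean = cr_sum / (ls_arr[:, None] * rs_arr[None, :])
        omega = np.where(cr_sum < cfg.epsilon, cfg.cap, within / np.maximum(cr_mean, 1e-300))
        omega = np.minimum(omega, cfg.cap)
        best = float(omega.max())
        capped = bool(np.any(cr_sum < cfg.epsilon) and best >= cfg.cap)
        rows.append((g, best, "capped" if capped else "ok"))
    table = pd.DataFrame(rows, columns=["position", "omega", "flag"])
    return OmegaScan(table=table)


def calibrate_threshold(max_omegas, percentile: float = 99.0) -> float:
    """Empirical percentile of per-replicate maximum omega values.

    Uses linear interpolation between order statistics (numpy's default
    quantile rule); fewer than 100 replicates triggers a warning.
    """
    v = np.asarray([m for m in max_omegas if np.isfinite(m)], dtype=float)
    if v.size == 0:
        raise ValueError("no finite replicate maxima")
    if v.size < 100:
        import warnings

        warnings.warn("fewer than 100 replicates: threshold will be noisy")
    return float(np.percentile(v, percentile))


# ---------------------------------------------------------------------------
# QTL / sweep overlap
# ---------------------------------------------------------------------------
@dataclass
class OverlapTestResult:
    observed_overlap: int
    observed_mean_distance: float
    p_overlap: float
    p_distance: float
    n_perm: int
    seed: int
    n_qtl: int
    n_sweeps: int
    perm_overlap_mean: float = float("nan")
    perm_distance_mean: float = float("nan")
    note: str = ""


def _overlap_stats(qtl_regions, peaks, sweeps_by_chrom):
    """Overlap count and mean peak-to-nearest-sweep distance."""
    n_overlap = 0
    dists = []
    for (chrom, lo, hi), peak in zip(qtl_regions, peaks):
        sw = sweeps_by_chrom.get(chrom)
        if sw is None or not len(sw):
            continue
        starts, ends = sw
        if np.any((starts <= hi) & (ends >= lo)):
            n_overlap += 1
        d = np.where(
            (peak >= starts) & (peak <= ends),
            0.0,
            np.minimum(np.abs(starts - peak), np.abs(ends - peak)),
        )
        dists.append(float(d.min()))
    mean_d = float(np.mean(dists)) if dists else float("nan")
    return n_overlap, mean_d


def qtl_sweep_overlap(
    qtl: pd.DataFrame,
    sweeps: pd.DataFrame,
    chrom_lengths: dict,
    n_perm: int = 1000,
    seed: int = 0,
    region_fraction: float = 0.10,
) -> OverlapTestResult:
    """Permutation test of QTL-peak / sweep-window proximity.

    Each QTL contributes a peak-centered region spanning
    ``region_fraction`` of its support-interval length (default 10%,
    i.e. peak +- 5%).  Sweeps are relocated uniformly within their
    chromosome, preserving per-chromosome counts and widths; empirical
    p-values use the add-one rule (greater-or-equal overlap; smaller-or-
    equal mean distance).

    ``qtl`` needs columns chrom, peak_bp, interval_lo_bp, interval_hi_bp;
    ``sweeps`` needs chrom, start, end (1-based inclusive bp).
    """
    if len(sweeps) == 0:
        return OverlapTestResult(
            0, float("nan"), float("nan"), float("nan"), n_perm, seed,
            len(qtl), 0, note="no sweep windows: test undefined",
        )
    half = region_fraction / 2.0
    regions = []
    peaks = []
    for _, r in qtl.iterrows():
        width = float(r["interval_hi_bp"] - r["interval_lo_bp"])
        regions.append(
            (r["chrom"], r["peak_bp"] - half * width, r["peak_bp"] + half * width)
        )
        peaks.append(float(r["peak_bp"]))

    def _bychrom(df):
        out = {}
        for chrom, sub in df.groupby("chrom"):
            out[chrom] = (sub["start"].to_numpy(float), sub["end"].to_numpy(float))
        return out

    obs_overlap, obs_dist = _overlap_stats(regions, peaks, _bychrom(sweeps))

    rng = np.random.default_rng(seed)
    widths = (sweeps["end"] - sweeps["start"]).to_numpy(float)
    chroms = sweeps["chrom"].to_numpy()
    ge_overlap = 0
    le_dist = 0
    perm_overlaps = np.empty(n_perm)
    perm_dists = np.empty(n_perm)
    for p in range(n_perm):
        starts = np.empty(len(sweeps))
        for i, (c, w) in enumerate(zip(chroms, widths)):
            span = max(chrom_lengths[c] - w, 1.0)
            starts[i] = rng.uniform(1.0, span)
        perm = {"chrom": chroms, "start": starts, "end": starts + widths}
        ov, dist = _overlap_stats(regions, peaks, _bychrom(pd.DataFrame(perm)))
        perm_overlaps[p] = ov
        perm_dists[p] = dist
        if ov >= obs_overlap:
            ge_overlap += 1
        if np.isfinite(dist) and np.isfinite(obs_dist) and dist <= obs_dist:
            le_dist += 1
    return OverlapTestResult(
        observed_overlap=obs_overlap,
        observed_mean_distance=obs_dist,
        p_overlap=(1 + ge_overlap) / (1 + n_perm),
        p_distance=(1 + le_dist) / (1 + n_perm),
        n_perm=n_perm,
        seed=seed,
        n_qtl=len(qtl),
        n_sweeps=len(sweeps),
        perm_overlap_mean=float(np.nanmean(perm_overlaps)),
        perm_distance_mean=float(np.nanmean(perm_dists)),
    )
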