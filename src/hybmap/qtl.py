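"""Haley-Knott QTL scanning for F2 intercross populations.

The pipeline mirrors standard interval-mapping practice: phenotypes are
residualized on nuisance covariates, genotype probabilities are
reconstructed on a cM grid with a three-state hidden Markov model, and a
LOD curve is obtained by regressing residuals on the expected additive
and dominance scores (Haley-Knott regression).  Genome-wide significance
comes from permutation of the residuals; support intervals use the
1.5-LOD drop convention; multiple QTL are found by conditional forward
search with joint refitting.

Coding convention: additive score x in {-1 (NN), 0 (NS), +1 (SS)}, so a
positive additive effect means the S allele increases the trait;
dominance indicator z = 1 for NS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cross_sim import F2GenotypeTable
from .mapfun import map_function

__all__ = [
    "GenotypeProbabilities",
    "ScanResult",
    "residualize",
    "genotype_probabilities",
    "hk_scan",
    "permutation_threshold",
    "lod_support_interval",
    "forward_qtl_search",
    "effect_distribution",
]

LOD_CAP = 50.0
F2_PRIOR = np.array([0.25, 0.5, 0.25])


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------
def residualize(
    phenotypes: pd.DataFrame,
    trait: str,
    covariates=("cross_direction", "tray"),
    family: str = "gaussian",
) -> pd.Series:
    """Residuals of a trait on categorical covariates, standardized.

    Gaussian traits use least squares; count traits use a log-link
    Poisson fit and response residuals.  Residuals are centered and
    scaled to unit variance.  Collinear covariate columns are dropped by
    the least-squares solver (a warning is emitted when the design is
    rank-deficient).
    """
    y = phenotypes[trait]
    keep = y.notna()
    for c in covariates:
        keep &= phenotypes[c].notna()
    if int(keep.sum()) < 10:
        raise ValueError(f"trait {trait!r} has fewer than 10 complete observations")
    sub = phenotypes.loc[keep]
    yv = sub[trait].to_numpy(float)
    X = _dummy_design(sub, covariates)
    if family == "gaussian":
        beta, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
        if rank < X.shape[1]:
            warnings.warn("collinear covariates dropped from residualization")
        res = yv - X @ beta
    elif family == "count":
        import statsmodels.api as sm

        fit = sm.GLM(yv, X, family=sm.families.Poisson()).fit()
        res = yv - fit.mu
    else:
        raise ValueError("family must be 'gaussian' or 'count'")
    res = res - res.mean()
    sd = res.std(ddof=1)
    if sd == 0:
        raise ValueError("residuals are constant")
    return pd.Series(res / sd, index=sub.index, name=f"{trait}_resid")


def _dummy_design(df: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in covariates:
        d = pd.get_dummies(df[c], drop_first=True)
        if d.shape[1]:
            cols.append(d.to_numpy(float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# genotype probabilities (3-state HMM)
# ---------------------------------------------------------------------------
@dataclass
class GenotypeProbabilities:
    """Posterior genotype probabilities on a cM evaluation grid.

    ``positions``: DataFrame (chrom, cM, marker) where marker is the
    marker id or '' for pseudomarkers; ``probs``: array
    (n_individuals, n_positions, 3) with rows summing to 1.
    """

    ids: list
    positions: pd.DataFrame = field(repr=False)
    probs: np.ndarray = field(repr=False)

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def n_positions(self) -> int:
        return self.probs.shape[1]

    def subset(self, ids) -> "GenotypeProbabilities":
        idx = pd.Index(self.ids).get_indexer(ids)
        if np.any(idx < 0):
            raise KeyError("unknown individual id in subset")
        return GenotypeProbabilities(list(ids), self.positions, self.probs[idx])


def _transition(r: float) -> np.ndarray:
    q = 1.0 - r
    return np.array(
        [
            [q * q, 2 * r * q, r * r],
            [r * q, q * q + r * r, r * q],
            [r * r, 2 * r * q, q * q],
        ]
    )


def _grid_for_chrom(cm: np.ndarray, step_cM: float):
    """Evaluation positions: markers plus a step grid; returns sorted
    positions and, for each, the marker's local index or -1."""
    lo, hi = cm[0], cm[-1]
    if step_cM > 0:
        grid = np.arange(lo, hi + 1e-9, step_cM)
    else:
        grid = np.array([])
    pos = np.unique(np.round(np.concatenate([cm, grid]), 6))
    marker_of = np.full(pos.size, -1, dtype=int)
    ji = {round(c, 6): j for j, c in enumerate(np.round(cm, 6))}
    for k, p in enumerate(pos):
        marker_of[k] = ji.get(round(p, 6), -1)
    return pos, marker_of


def genotype_probabilities(
    table: F2GenotypeTable,
    step_cM: float = 1.0,
    error_prob: float = 0.0,
    map_kind: str = "haldane",
) -> GenotypeProbabilities:
    """Hidden-Markov genotype probabilities for every individual.

    Three latent states (NN, NS, SS) with transitions derived from the
    map function between adjacent evaluation positions; observed marker
    genotypes emit their own code with probability 1 - error_prob (the
    two alternatives share error_prob).  With error_prob = 0, a typed
    marker has all its mass on the observed code.
    """
    n = table.n_individuals
    all_pos = []
    blocks = []
    for chrom in table.gmap.chromosomes:
        sub = table.gmap.chrom_table(chrom)
        cm = sub["cM"].to_numpy(float)
        gidx = sub.index.to_numpy()
        pos, marker_of = _grid_for_chrom(cm, step_cM)
        K = pos.size
        r = map_function(np.diff(pos), kind=map_kind)

        # emissions: (K, n, 3); ones at pseudomarkers / missing genotypes
        emis = np.ones((K, n, 3))
        for k in range(K):
            if marker_of[k] >= 0:
                g = table.genotypes[:, gidx[marker_of[k]]]
                typed = g >= 0
                if typed.any():
                    e = np.full((typed.sum(), 3), error_prob / 2.0)
                    e[np.arange(typed.sum()), g[typed]] = 1.0 - error_prob
                    emis[k, typed] = e

        T = [_transition(float(ri)) for ri in r]
        alpha = np.empty((K, n, 3))
        a = F2_PRIOR * emis[0]
        a /= a.sum(axis=1, keepdims=True)
        alpha[0] = a
        for k in range(1, K):
            a = (a @ T[k - 1]) * emis[k]
            norm = a.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            a = a / norm
            alpha[k] = a
        beta = np.ones((n, 3))
        post = np.empty((K, n, 3))
        post[K - 1] = alpha[K - 1]
        for k in range(K - 2, -1, -1):
            beta = (emis[k + 1] * beta) @ T[k].T
            norm = beta.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            beta = beta / norm
            p = alpha[k] * beta
            p /= p.sum(axis=1, keepdims=True)
            post[k] = p

        blocks.append(np.transpose(post, (1, 0, 2)))
        names = ["" if mk < 0 else sub["marker"].iloc[mk] for mk in marker_of]
        all_pos.append(
            pd.DataFrame({"chrom": chrom, "cM": pos, "marker": names})
        )
    positions = pd.concat(all_pos, ignore_index=True)
    probs = np.concatenate(blocks, axis=1)
    return GenotypeProbabilities(list(table.ids), positions, probs)


# ---------------------------------------------------------------------------
# Haley-Knott scan
# ---------------------------------------------------------------------------
@dataclass
class ScanResult:
    """LOD curve with per-position effect estimates and peak list."""

    scan: pd.DataFrame = field(repr=False)
    n: int
    rss0: float
    threshold: float | None = None
    peaks: pd.DataFrame | None = None


def _hk_design(probs: GenotypeProbabilities):
    """Per-position HK regressors: x* = pSS - pNN, z* = pNS."""
    x = probs.probs[:, :, 2] - probs.probs[:, :, 0]
    z = probs.probs[:, :, 1]
    return x, z


def _align(probs: GenotypeProbabilities, residuals: pd.Series):
    ids = [i for i in probs.ids if i in residuals.index]
    if len(ids) < len(probs.ids):
        probs = probs.subset(ids)
    y = residuals.loc[ids].to_numpy(float)
    keep = np.isfinite(y)
    if not keep.all():
        probs = probs.subset([i for i, k in zip(ids, keep) if k])
        y = y[keep]
    return probs, y


def hk_scan(probs: GenotypeProbabilities, residuals: pd.Series) -> ScanResult:
    """Single-QTL Haley-Knott genome scan.

    At each grid position, regress residuals on the expected additive and
    dominance scores; LOD = (n/2) log10(RSS0/RSS1).  Degenerate fits
    (RSS1 = 0) are capped at LOD 50 and flagged.
    """
    probs, y = _align(probs, residuals)
    n = y.size
    if n < 30:
        raise ValueError("need at least 30 individuals with residuals")
    x, z = _hk_design(probs)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    G = probs.n_positions
    lod = np.zeros(G)
    a_hat = np.zeros(G)
    d_hat = np.zeros(G)
    flagged = np.zeros(G, dtype=bool)
    ones = np.ones(n)
    for g in range(G):
        X = np.column_stack([ones, x[:, g], z[:, g]])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = float(np.sum((y - X @ beta) ** 2))
        if rank < 3:
            flagged[g] = True
        if rss1 <= 0:
            lod[g] = LOD_CAP
        else:
            lod[g] = min((n / 2.0) * np.log10(rss0 / rss1), LOD_CAP)
        if lod[g] >= LOD_CAP:
            flagged[g] = True
        a_hat[g] = beta[1]
        d_hat[g] = beta[2]
    scan = probs.positions.copy()
    scan["lod"] = lod
    scan["a"] = a_hat
    scan["d"] = d_hat
    scan["flagged"] = flagged
    return ScanResult(scan=scan, n=n, rss0=rss0)


def permutation_threshold(
    probs: GenotypeProbabilities,
    residuals: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from residual permutations.

    The (1 - alpha) quantile of the per-permutation genome-wide maximum
    LOD.  Fully seeded; alpha = 1 returns the minimum of the permuted
    maxima.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    probs, y = _align(probs, residuals)
    n = y.size
    if np.allclose(y, y[0]):
        raise ValueError("constant residuals")
    x, z = _hk_design(probs)
    G = probs.n_positions
    # orthonormal basis per position -> RSS1 = y'y - ||Q'y||^2
    Qall = np.empty((n, 3 * G))
    for g in range(G):
        X = np.column_stack([np.ones(n), x[:, g], z[:, g]])
        Q, _ = np.linalg.qr(X, mode="reduced")
        Qall[:, 3 * g : 3 * g + 3] = Q
    rng = np.random.default_rng(seed)
    Y = np.empty((n, n_perm))
    for p in range(n_perm):
        Y[:, p] = y[rng.permutation(n)]
    yty = float(y @ y)
    rss0 = yty - n * float(y.mean()) ** 2
    proj = Qall.T @ Y  # (3G, P)
    ssq = (proj.reshape(G, 3, n_perm) ** 2).sum(axis=1)
    rss1 = np.maximum(yty - ssq, 1e-12)
    lod = (n / 2.0) * np.log10(rss0 / rss1)
    maxima = lod.max(axis=0)
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def lod_support_interval(
    scan: ScanResult | pd.DataFrame, chrom, peak_cM: float, drop: float = 1.5
) -> tuple[float, float]:
    """1.5-LOD support interval around a peak.

    The widest contiguous span around the peak where LOD stays within
    ``drop`` of the peak value, expanded by one grid point on each side
    and clipped to the chromosome ends.
    """
    df = scan.scan if isinstance(scan, ScanResult) else scan
    sub = df[df["chrom"] == chrom].reset_index(drop=True)
    if sub.empty:
        raise KeyError(f"no scan positions on chromosome {chrom!r}")
    cm = sub["cM"].to_numpy(float)
    lod = sub["lod"].to_numpy(float)
    k = int(np.argmin(np.abs(cm - peak_cM)))
    cut = lod[k] - drop
    lo = k
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = k
    while hi < lod.size - 1 and lod[hi + 1] >= cut:
        hi += 1
    lo = max(lo - 1, 0)
    hi = min(hi + 1, lod.size - 1)
    return float(cm[lo]), float(cm[hi])


def _conditional_scan(x, z, y, C):
    """LOD of adding (x_g, z_g) to covariates C at every position."""
    n, G = x.shape
    beta0, _, _, _ = np.linalg.lstsq(C, y, rcond=None)
    rss_base = float(np.sum((y - C @ beta0) ** 2))
    lod = np.zeros(G)
    for g in range(G):
        X = np.column_stack([C, x[:, g], z[:, g]])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = float(np.sum((y - X @ beta) ** 2))
        if rss1 <= 0:
            lod[g] = LOD_CAP
        else:
            lod[g] = min((n / 2.0) * np.log10(rss_base / rss1), LOD_CAP)
    return lod, rss_base


def forward_qtl_search(
    probs: GenotypeProbabilities,
    residuals: pd.Series,
    threshold: float,
    max_qtl: int = 5,
    drop: float = 1.5,
) -> pd.DataFrame:
    """Iterative forward search for a multiple-QTL model.

    Repeatedly adds the grid position with the highest conditional LOD
    (given the QTL terms already in the model) while it exceeds the
    permutation threshold, then refits all additive/dominance effects
    jointly.  Per-QTL percent variance uses drop-one RSS comparison
    against the null RSS; support intervals come from the final profile
    scan of each QTL conditional on the others.

    Returns a peaks DataFrame (possibly empty): chrom, cM, lod, a, d,
    pct_variance, interval_lo, interval_hi.
    """
    probs, y = _align(probs, residuals)
    n = y.size
    x, z = _hk_design(probs)
    pos = probs.positions
    rss0 = float(np.sum((y - y.mean()) ** 2))

    chosen: list[int] = []
    C = np.ones((n, 1))
    while len(chosen) < max_qtl:
        lod, _ = _conditional_scan(x, z, y, C)
        g = int(np.argmax(lod))
        if lod[g] <= threshold or g in chosen:
            break
        chosen.append(g)
        C = np.column_stack([C, x[:, g], z[:, g]])

    cols = ["chrom", "cM", "lod", "a", "d", "pct_variance", "interval_lo", "interval_hi"]
    if not chosen:
        return pd.DataFrame(columns=cols)

    X_full = np.column_stack(
        [np.ones(n)] + [np.column_stack([x[:, g], z[:, g]]) for g in chosen]
    )
    beta, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_full = float(np.sum((y - X_full @ beta) ** 2))

    rows = []
    for i, g in enumerate(chosen):
        others = [gg for gg in chosen if gg != g]
        C_others = np.column_stack(
            [np.ones(n)] + [np.column_stack([x[:, gg], z[:, gg]]) for gg in others]
        )
        b0, _, _, _ = np.linalg.lstsq(C_others, y, rcond=None)
        rss_drop = float(np.sum((y - C_others @ b0) ** 2))
        lod_i = (n / 2.0) * np.log10(rss_drop / max(rss_full, 1e-12))
        pct = 100.0 * (rss_drop - rss_full) / rss0
        # profile scan on this QTL's chromosome, conditional on the others
        chrom = pos["chrom"].iloc[g]
        on_chrom = (pos["chrom"] == chrom).to_numpy()
        lod_prof = np.full(pos.shape[0], -np.inf)
        lod_sub, _ = _conditional_scan(x[:, on_chrom], z[:, on_chrom], y, C_others)
        lod_prof[on_chrom] = lod_sub
        prof_df = pos.copy()
        prof_df["lod"] = lod_prof
        lo, hi = lod_support_interval(prof_df, chrom, float(pos["cM"].iloc[g]), drop)
        rows.append(
            {
                "chrom": chrom,
                "cM": float(pos["cM"].iloc[g]),
                "lod": min(lod_i, LOD_CAP),
                "a": float(beta[1 + 2 * i]),
                "d": float(beta[2 + 2 * i]),
                "pct_variance": pct,
                "interval_lo": lo,
                "interval_hi": hi,
            }
        )
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["chrom", "cM"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# effect-distribution summaries
# ---------------------------------------------------------------------------
def _moments(v: np.ndarray) -> dict:
    return {
        "count": int(v.size),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)),
        "median": float(np.median(v)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "skewness": float(stats.skew(v, bias=True)),
        "kurtosis": float(stats.kurtosis(v, fisher=False, bias=True)),
    }


def effect_distribution(
    peaks: pd.DataFrame,
    distortion_chroms=(4, 7),
    fertility_trait: str = "WS",
) -> dict:
    """Summary statistics and Shapiro-Wilk normality tests for the
    additive and dominance effect lists of a multi-trait peak table.

    Exclusions follow the mapping-study convention: QTLs on designated
    segregation-distortion chromosomes are removed, the fertility trait's
    own QTLs are removed, and (when interval columns are available) QTLs
    whose support intervals overlap a fertility QTL interval on the same
    chromosome are removed.

    ``peaks`` needs columns trait, chrom, a, d and optionally
    interval_lo/interval_hi.
    """
    df = peaks.copy()
    df = df[~df["chrom"].isin(distortion_chroms)]
    fert = peaks[peaks["trait"] == fertility_trait] if "trait" in peaks else peaks.iloc[0:0]
    if "trait" in df:
        df = df[df["trait"] != fertility_trait]
    if {"interval_lo", "interval_hi"}.issubset(df.columns) and not fert.empty:
        keep = []
        for _, row in df.iterrows():
            clash = False
            for _, f in fert.iterrows():
                if row["chrom"] == f["chrom"] and not (
                    row["interval_hi"] < f["interval_lo"]
                    or row["interval_lo"] > f["interval_hi"]
                ):
                    clash = True
                    break
            keep.append(not clash)
        df = df[np.asarray(keep, dtype=bool)]
    out = {"excluded": int(len(peaks) - len(df)), "retained": int(len(df))}
    for effect in ("a", "d"):
        v = df[effect].to_numpy(float)
        v = v[np.isfinite(v)]
        if v.size < 3:
            raise ValueError(f"fewer than 3 retained {effect}-effects")
        summ = _moments(v)
        w, p = stats.shapiro(v)
        summ["shapiro_W"] = float(w)
        summ["shapiro_p"] = float(p)
        out[effect] = summ
    return out
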