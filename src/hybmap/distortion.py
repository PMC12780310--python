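"""Segregation distortion and selection-coefficient inference.

Per-marker tests on an F2 genotype table:

* genotype test against the Mendelian 1:2:1 expectation (2 df),
* allele test against 1:1 transmission (1 df),
* Hardy-Weinberg test of observed genotype counts against expectations
  built from the observed allele frequencies (2 df by convention here;
  the textbook 1 df, which accounts for the estimated allele frequency,
  is switchable),

plus selection coefficients t (against NN) and s (against SS) from
observed/expected genotype ratios, Bonferroni and Benjamini-Hochberg
multiple-testing control, and a prezygotic/postzygotic classification.

The allele test detects *gametic* distortion (biased transmission, which
can leave genotype frequencies in HWE); the HWE test detects *zygotic*
(postzygotic) distortion such as heterozygote advantage or deficit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cross_sim import F2GenotypeTable

__all__ = [
    "GenotypeCounts",
    "hwe_expected_counts",
    "chi_square_tests",
    "selection_coefficients",
    "adjust_pvalues",
    "scan_and_classify",
    "interlocus_association",
    "interchromosome_scan",
]


@dataclass(frozen=True)
class GenotypeCounts:
    nNN: int
    nNS: int
    nSS: int

    def __post_init__(self):
        for v in (self.nNN, self.nNS, self.nSS):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.nNN + self.nNS + self.nSS

    @property
    def freqN(self) -> float:
        return (2 * self.nNN + self.nNS) / (2 * self.n)

    @property
    def freqS(self) -> float:
        return 1.0 - self.freqN


def hwe_expected_counts(counts: GenotypeCounts) -> tuple[float, float, float]:
    """HWE-expected genotype counts from observed allele frequencies.

    expNN = freqN^2 n, expNS = 2 freqN freqS n, expSS = freqS^2 n;
    the three sum to n exactly.
    """
    if counts.n < 1:
        raise ValueError("need at least one genotyped individual")
    p = counts.freqN
    q = counts.freqS
    n = counts.n
    return (p * p * n, 2 * p * q * n, q * q * n)


def _gof(observed, expected):
    """Goodness-of-fit chi-squared, excluding cells with expected 0."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    keep = e > 0
    dropped = int(np.sum(~keep))
    chi2 = float(np.sum((o[keep] - e[keep]) ** 2 / e[keep]))
    return chi2, dropped


def chi_square_tests(counts: GenotypeCounts, hwe_df: int = 2) -> dict:
    """Mendelian 1:2:1, allele 1:1 and HWE chi-squared tests.

    Returns a dict with chi2/p for each test plus the number of excluded
    zero-expectation cells of the HWE test.
    """
    n = counts.n
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    obs = (counts.nNN, counts.nNS, counts.nSS)

    chi2_m, _ = _gof(obs, (n / 4, n / 2, n / 4))
    p_m = float(stats.chi2.sf(chi2_m, 2))

    alleles = (2 * counts.nNN + counts.nNS, 2 * counts.nSS + counts.nNS)
    chi2_a, _ = _gof(alleles, (n, n))
    p_a = float(stats.chi2.sf(chi2_a, 1))

    exp = hwe_expected_counts(counts)
    chi2_h, dropped = _gof(obs, exp)
    p_h = float(stats.chi2.sf(chi2_h, hwe_df))

    return {
        "chi2_mendel": chi2_m,
        "p_mendel": p_m,
        "chi2_allele": chi2_a,
        "p_allele": p_a,
        "chi2_hwe": chi2_h,
        "p_hwe": p_h,
        "hwe_cells_dropped": dropped,
    }


def selection_coefficients(
    counts: GenotypeCounts, baseline: str = "hwe"
) -> tuple[float, float]:
    """Selection coefficients t (against NN) and s (against SS).

    t = 1 - ratioNN/ratioNS and s = 1 - ratioSS/ratioNS, where
    ratioG = observed/expected count of genotype G.  Positive values mean
    the homozygote is under-represented relative to heterozygotes.

    baseline="hwe" builds expectations from observed allele frequencies
    (this cancels purely gametic distortion, isolating postzygotic
    effects); baseline="mendelian" uses the F2 1:2:1 expectation, which
    is the consistent estimator of zygotic viability coefficients when
    transmission itself is unbiased.

    Returns (nan, nan) when heterozygote counts make the ratios
    undefined.
    """
    n = counts.n
    if baseline == "hwe":
        exp = hwe_expected_counts(counts)
    elif baseline == "mendelian":
        exp = (n / 4, n / 2, n / 4)
    else:
        raise ValueError("baseline must be 'hwe' or 'mendelian'")
    if counts.nNS == 0 or exp[1] == 0:
        return (float("nan"), float("nan"))
    ratio_ns = counts.nNS / exp[1]
    t = 1.0 - (counts.nNN / exp[0]) / ratio_ns if exp[0] > 0 else float("nan")
    s = 1.0 - (counts.nSS / exp[2]) / ratio_ns if exp[2] > 0 else float("nan")
    return (t, s)


def adjust_pvalues(pvalues, method: str = "bonferroni", alpha: float = 0.05):
    """Multiple-testing adjustment.

    method="bonferroni": returns (threshold alpha/m, boolean flags).
    method="bh": returns Benjamini-Hochberg adjusted p-values (monotone,
    capped at 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        thr = alpha / p.size
        return thr, p < thr
    if method == "bh":
        return multipletests(p, alpha=alpha, method="fdr_bh")[1]
    raise ValueError("method must be 'bonferroni' or 'bh'")


def _classify(row, alpha):
    gametic = bool(row["allele_bonf_sig"])
    zygotic = bool(row["q_hwe_fdr"] < alpha) if np.isfinite(row["q_hwe_fdr"]) else False
    t, s = row["t"], row["s"]
    if not gametic and not zygotic and not row["mendel_bonf_sig"]:
        return "mendelian"
    if gametic and not zygotic:
        return "gametic_distortion"
    if zygotic and np.isfinite(t) and np.isfinite(s):
        if t > 0 and s > 0:
            return "het_advantage"
        if t < 0 and s < 0:
            return "het_deficit"
    return "mixed"


def scan_and_classify(
    table: F2GenotypeTable, alpha: float = 0.05, hwe_df: int = 2
) -> pd.DataFrame:
    """Per-marker distortion scan of an F2 genotype table.

    Applies all three chi-squared tests at each marker, Bonferroni
    control (threshold alpha / n_markers) to the Mendelian, allele and
    HWE p-values, BH FDR to the HWE p-values (the significance flags for
    t/s), and classifies each marker as mendelian, gametic_distortion,
    het_advantage, het_deficit or mixed.  Markers with no genotyped
    individuals are flagged and skipped.
    """
    m = table.n_markers
    recs = []
    for j in range(m):
        cnt = table.counts_at(j)
        row = {
            "marker": table.gmap.table["marker"].iloc[j],
            "chrom": table.gmap.table["chrom"].iloc[j],
            "cM": table.gmap.table["cM"].iloc[j],
            "nNN": cnt[0],
            "nNS": cnt[1],
            "nSS": cnt[2],
            "n": sum(cnt),
        }
        if row["n"] == 0:
            row.update(
                freqN=np.nan, freqS=np.nan, expNN=np.nan, expNS=np.nan, expSS=np.nan,
                chi2_mendel=np.nan, p_mendel=np.nan, chi2_allele=np.nan,
                p_allele=np.nan, chi2_hwe=np.nan, p_hwe=np.nan,
                t=np.nan, s=np.nan, t_mendel=np.nan, s_mendel=np.nan, skipped=True,
            )
        else:
            gc = GenotypeCounts(*cnt)
            exp = hwe_expected_counts(gc)
            tests = chi_square_tests(gc, hwe_df=hwe_df)
            t_h, s_h = selection_coefficients(gc, baseline="hwe")
            t_m, s_m = selection_coefficients(gc, baseline="mendelian")
            row.update(
                freqN=gc.freqN, freqS=gc.freqS,
                expNN=exp[0], expNS=exp[1], expSS=exp[2],
                chi2_mendel=tests["chi2_mendel"], p_mendel=tests["p_mendel"],
                chi2_allele=tests["chi2_allele"], p_allele=tests["p_allele"],
                chi2_hwe=tests["chi2_hwe"], p_hwe=tests["p_hwe"],
                t=t_h, s=s_h, t_mendel=t_m, s_mendel=s_m, skipped=False,
            )
        recs.append(row)
    df = pd.DataFrame(recs)

    thr = alpha / m
    df["bonferroni_threshold"] = thr
    for test in ("mendel", "allele", "hwe"):
        df[f"{test}_bonf_sig"] = df[f"p_{test}"] < thr
    ok = df["p_hwe"].notna()
    q = np.full(m, np.nan)
    if ok.any():
        q[ok.to_numpy()] = adjust_pvalues(df.loc[ok, "p_hwe"].to_numpy(), "bh")
    df["q_hwe_fdr"] = q
    df["ts_fdr_sig"] = df["q_hwe_fdr"] < alpha
    df["classification"] = [_classify(r, alpha) for _, r in df.iterrows()]
    return df


def interlocus_association(table: F2GenotypeTable, marker_a: str, marker_b: str):
    """Pearson chi-squared on the 3x3 joint genotype table of two markers.

    Empty genotype rows/columns are dropped before the test; a marker
    left monomorphic is reported as undefined (nan statistic, df 0).
    Returns (chi2, df, p).
    """
    ja = table.gmap.marker_index(marker_a)
    jb = table.gmap.marker_index(marker_b)
    ga = table.genotypes[:, ja]
    gb = table.genotypes[:, jb]
    keep = (ga >= 0) & (gb >= 0)
    if not keep.any():
        raise ValueError("no individual genotyped at both markers")
    ct = np.zeros((3, 3), dtype=float)
    for a, b in zip(ga[keep], gb[keep]):
        ct[a, b] += 1
    ct = ct[ct.sum(axis=1) > 0][:, ct.sum(axis=0) > 0]
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        return float("nan"), 0, float("nan")
    chi2, p, dof, _ = stats.chi2_contingency(ct, correction=False)
    return float(chi2), int(dof), float(p)


def interchromosome_scan(
    table: F2GenotypeTable, chrom_a, chrom_b, stride: int = 1
) -> pd.DataFrame:
    """All-pairs interlocus association between two chromosomes.

    ``stride`` thins the marker grid on both chromosomes.
    """
    ta = table.gmap.chrom_table(chrom_a)["marker"].to_numpy()[::stride]
    tb = table.gmap.chrom_table(chrom_b)["marker"].to_numpy()[::stride]
    rows = []
    for a in ta:
        for b in tb:
            chi2, dof, p = interlocus_association(table, a, b)
            rows.append((a, b, chi2, dof, p))
    return pd.DataFrame(rows, columns=["marker_a", "marker_b", "chi2", "df", "p"])
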