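"""Recombinant-interval fine-mapping.

Narrows a QTL to one of several physical intervals using offspring
families that segregate across the region: interval genotypes are
assigned from flanking boundary markers, a flowering-time-like count
phenotype is residualized on the experimental design (family, trial,
tray nested in trial), and each interval is tested for association with
the residuals; the interval with the best model fit contains the causal
variant.  Expected recombinant counts provide a design-level sanity
check on the region's genetic length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mapfun import map_function

__all__ = [
    "FinemapResult",
    "assign_intervals",
    "residualize_flowering",
    "interval_association",
    "expected_recombinants",
]

_CODE = {"NN": -1.0, "NS": 0.0, "SS": 1.0}


def assign_intervals(markers: pd.DataFrame) -> pd.DataFrame:
    """Interval genotype codes from ordered boundary-marker genotypes.

    ``markers``: one column per boundary marker (values NN/NS/SS or
    missing), k columns defining k-1 intervals.  An interval's code is
    the genotype shared by its two boundaries, or ``ambiguous`` when
    they disagree (a crossover fell inside) or either is missing.  A
    plant is flagged ``recombinant`` when any two non-missing boundaries
    differ; plants with fewer than 2 typed boundaries are flagged
    ``excluded``.
    """
    k = markers.shape[1]
    if k < 2:
        raise ValueError("need at least 2 boundary markers")
    vals = markers.to_numpy(dtype=object)
    valid = np.isin(vals, ("NN", "NS", "SS"))
    out = pd.DataFrame(index=markers.index)
    for j in range(k - 1):
        left, right = vals[:, j], vals[:, j + 1]
        ok = valid[:, j] & valid[:, j + 1] & (left == right)
        out[f"interval{j + 1}"] = np.where(ok, left, "ambiguous")
    n_typed = valid.sum(axis=1)
    recomb = np.zeros(len(markers), dtype=bool)
    for i in range(len(markers)):
        typed = vals[i][valid[i]]
        recomb[i] = typed.size >= 2 and np.unique(typed).size > 1
    out["recombinant"] = recomb
    out["excluded"] = n_typed < 2
    return out


def residualize_flowering(
    phenotypes: pd.DataFrame,
    response: str = "flowering_time",
    family_col: str = "family",
    trial_col: str = "trial",
    tray_col: str = "tray",
) -> pd.Series:
    """Response residuals of a count phenotype on the experimental design.

    The design model is family x (trial with tray nested in trial), all
    interactions included.  Under a log-link Poisson (or quasi-Poisson,
    which shares the point estimates) this model is saturated in the
    (family, trial, tray) cells, so the fitted value of every
    observation is its cell mean; residuals are returned on the response
    scale.  Cells without observations never arise in the fit.
    """
    if phenotypes[family_col].nunique() < 2:
        raise ValueError("need at least 2 families")
    y = phenotypes[response].astype(float)
    cells = phenotypes.groupby(
        [family_col, trial_col, tray_col], sort=False, observed=True
    )[response].transform("mean")
    res = y - cells
    res.name = f"{response}_resid"
    return res


@dataclass
class FinemapResult:
    per_interval: pd.DataFrame = field(repr=False)
    best_interval: int
    joint: pd.DataFrame | None = field(default=None, repr=False)
    n_recombinants: int | None = None
    expected: dict | None = None


def interval_association(
    residuals: pd.Series, intervals: pd.DataFrame
) -> FinemapResult:
    """Per-interval Gaussian association of residuals with interval
    genotype.

    Interval genotypes are coded -1/0/+1 (NN/NS/SS); ambiguous intervals
    are treated as missing for that interval's fit.  The best interval
    has the lowest AIC relative to the intercept-only model on the same
    plants (delta-AIC, comparable across intervals that drop different
    ambiguous sets), with the per-interval p-value as tie-break;
    monomorphic intervals are excluded with a flag.  A joint fit on all
    intervals (complete rows) is also reported.
    """
    int_cols = [c for c in intervals.columns if c.startswith("interval")]
    if not int_cols:
        raise ValueError("no interval columns found")
    y_all = residuals.to_numpy(float)
    rows = []
    codes = {}
    for idx, c in enumerate(int_cols, start=1):
        x = intervals[c].map(_CODE).to_numpy(dtype=float)
        codes[c] = x
        keep = np.isfinite(x) & np.isfinite(y_all)
        if keep.sum() < 3 or np.unique(x[keep]).size < 2:
            rows.append((idx, np.nan, np.nan, np.nan, int(keep.sum()), "monomorphic"))
            continue
        X = sm.add_constant(x[keep])
        fit = sm.OLS(y_all[keep], X).fit()
        # delta-AIC vs the intercept-only model on the same plants:
        # comparable across intervals despite differing ambiguous-drops
        null = sm.OLS(y_all[keep], np.ones((int(keep.sum()), 1))).fit()
        rows.append(
            (idx, float(fit.params[1]), float(fit.pvalues[1]),
             float(fit.aic - null.aic), int(keep.sum()), "ok")
        )
    per = pd.DataFrame(
        rows, columns=["interval", "coef", "p", "delta_aic", "n", "flag"]
    )
    usable = per[per["flag"] == "ok"]
    if usable.empty:
        raise ValueError("no testable interval")
    best = usable.sort_values(["delta_aic", "p"]).iloc[0]

    jx = np.column_stack([codes[c] for c in int_cols])
    keep = np.all(np.isfinite(jx), axis=1) & np.isfinite(y_all)
    joint = None
    if keep.sum() >= len(int_cols) + 2:
        X = sm.add_constant(jx[keep])
        try:
            fit = sm.OLS(y_all[keep], X).fit()
            joint = pd.DataFrame(
                {
                    "interval": list(range(1, len(int_cols) + 1)),
                    "coef": fit.params[1:],
                    "p": fit.pvalues[1:],
                }
            )
        except Exception:  # collinear joint design on tiny inputs
            joint = None
    n_rec = (
        int(intervals["recombinant"].sum()) if "recombinant" in intervals else None
    )
    return FinemapResult(
        per_interval=per, best_interval=int(best["interval"]), joint=joint,
        n_recombinants=n_rec,
    )


def expected_recombinants(
    n_plants: int, region_cM: float, map_kind: str = "haldane"
) -> dict:
    """Expected recombinant counts across a region of given map length.

    per_gamete counts recombinant gametes (2 per plant at recombination
    fraction r); per_plant counts plants carrying at least one
    recombinant gamete, n (1 - (1-r)^2).
    """
    if region_cM < 0:
        raise ValueError("region length must be >= 0")
    r = map_function(region_cM, kind=map_kind)
    return {
        "r": r,
        "per_gamete": 2.0 * n_plants * r,
        "per_plant": n_plants * (1.0 - (1.0 - r) ** 2),
    }
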