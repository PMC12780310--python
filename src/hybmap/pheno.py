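"""Parental trait contrasts and the trait correlation network.

Species-level phenotype differences are assessed per trait with a model
controlling for tray (positional) effects; raw species means and their
absolute difference ("distance") are always reported, with BH FDR
control across traits.  Genetically based trait correlations in the F2
are summarized as a network of significant Spearman correlations among
covariate-corrected trait values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .distortion import adjust_pvalues

__all__ = ["ContrastResult", "CorrelationNetwork", "parental_contrasts", "spearman_network"]


@dataclass
class ContrastResult:
    trait: str
    mean_a: float
    mean_b: float
    distance: float
    ratio: float
    p: float
    q: float = float("nan")
    tier: str = ""


def _tier(q: float) -> str:
    if not np.isfinite(q):
        return ""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    if q < 0.1:
        return "."
    return ""


def parental_contrasts(
    phenotypes: pd.DataFrame,
    traits,
    species_col: str = "species",
    tray_col: str = "tray",
    families: dict | None = None,
) -> pd.DataFrame:
    """Per-trait species contrast with tray adjustment and BH FDR.

    ``families`` maps trait -> {"gaussian", "count", "categorical"}
    (default gaussian).  Gaussian traits use least squares (trait ~
    species + tray); count traits a log-link Poisson fit whose species
    effect is reported as a rate ratio; categorical traits a contingency
    chi-squared.  Raw means and |mean difference| are model-free.
    """
    families = families or {}
    levels = sorted(set(phenotypes[species_col]))
    if len(levels) != 2:
        raise ValueError("exactly two species labels are required")
    a_lab, b_lab = levels  # reference = lexicographically first label
    rows = []
    for trait in traits:
        sub = phenotypes[[trait, species_col, tray_col]].dropna()
        ga = sub.loc[sub[species_col] == a_lab, trait]
        gb = sub.loc[sub[species_col] == b_lab, trait]
        if len(ga) < 2 or len(gb) < 2:
            raise ValueError(f"trait {trait!r}: need >= 2 individuals per species")
        fam = families.get(trait, "gaussian")
        mean_a, mean_b = float(ga.mean()), float(gb.mean())
        distance = abs(mean_a - mean_b)
        ratio = mean_b / mean_a if mean_a != 0 else float("nan")
        if sub[trait].nunique() <= 1:
            p = 1.0  # constant trait in both species
        elif fam == "categorical":
            ct = pd.crosstab(sub[species_col], sub[trait]).to_numpy()
            if min(ct.shape) < 2:
                p = 1.0
            else:
                _, p, _, _ = stats.chi2_contingency(ct, correction=False)
        else:
            X = np.column_stack(
                [
                    np.ones(len(sub)),
                    (sub[species_col] == b_lab).to_numpy(float),
                    pd.get_dummies(sub[tray_col], drop_first=True).to_numpy(float),
                ]
            )
            y = sub[trait].to_numpy(float)
            if fam == "count":
                fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
                ratio = float(np.exp(fit.params[1]))
                p = float(fit.pvalues[1])
            else:
                fit = sm.OLS(y, X).fit()
                p = float(fit.pvalues[1])
        rows.append(ContrastResult(trait, mean_a, mean_b, distance, ratio, float(p)))
    q = adjust_pvalues([r.p for r in rows], method="bh")
    for r, qq in zip(rows, q):
        r.q = float(qq)
        r.tier = _tier(r.q)
    return pd.DataFrame([vars(r) for r in rows])


@dataclass
class CorrelationNetwork:
    """Traits as nodes, significant Spearman correlations as edges."""

    nodes: list
    edges: pd.DataFrame = field(repr=False)  # trait_i, trait_j, rho, p, sign

    def graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, e in self.edges.iterrows():
            g.add_edge(e["trait_i"], e["trait_j"], rho=e["rho"], p=e["p"], sign=e["sign"])
        return g


def spearman_network(
    residuals: pd.DataFrame, alpha: float = 0.05, min_pairs: int = 10
) -> CorrelationNetwork:
    """Pairwise Spearman correlations on pairwise-complete observations.

    Edges keep pairs with p < alpha (unadjusted, by design); constant
    traits are excluded with a warning.  Invariant to monotone per-trait
    transformations of the inputs.
    """
    traits = []
    for c in residuals.columns:
        v = residuals[c].dropna()
        if v.nunique() <= 1:
            warnings.warn(f"trait {c!r} is constant: excluded from network")
            continue
        traits.append(c)
    rows = []
    for i, ti in enumerate(traits):
        for tj in traits[i + 1 :]:
            sub = residuals[[ti, tj]].dropna()
            if len(sub) < min_pairs:
                continue
            rho, p = stats.spearmanr(sub[ti], sub[tj])
            if np.isfinite(p) and p < alpha:
                rows.append((ti, tj, float(rho), float(p), int(np.sign(rho))))
    edges = pd.DataFrame(rows, columns=["trait_i", "trait_j", "rho", "p", "sign"])
    return CorrelationNetwork(nodes=traits, edges=edges)
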