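"""Figure helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["distortion_tracks", "lod_curve", "qtl_segments", "network_figure"]


def _genome_x(df: pd.DataFrame):
    """Concatenated cM axis with chromosome offsets."""
    x = np.zeros(len(df))
    offset = 0.0
    bounds = []
    for chrom, sub in df.groupby("chrom", sort=False):
        x[sub.index] = sub["cM"].to_numpy(float) + offset
        span = float(sub["cM"].max())
        bounds.append((chrom, offset, offset + span))
        offset += span + 5.0
    return x, bounds


def distortion_tracks(dist: pd.DataFrame, alpha: float = 0.05):
    """Three-track distortion figure: allele-test and HWE-test
    -log10(p) plus selection coefficients with FDR-significant markers
    circled."""
    df = dist.reset_index(drop=True)
    x, bounds = _genome_x(df)
    thr = float(df["bonferroni_threshold"].iloc[0])
    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)
    with np.errstate(divide="ignore"):
        la = -np.log10(df["p_allele"].to_numpy(float))
        lh = -np.log10(df["p_hwe"].to_numpy(float))
    for ax, vals, sig, label in (
        (axes[0], la, df["allele_bonf_sig"], "allele 1:1 test"),
        (axes[1], lh, df["hwe_bonf_sig"], "HWE test"),
    ):
        ax.scatter(x, vals, s=4, c=np.where(sig, "red", "grey"))
        ax.axhline(-np.log10(thr), ls="--", lw=0.8, c="k")
        ax.set_ylabel(f"-log10 p\n{label}")
    ax = axes[2]
    ax.scatter(x, df["t"], s=4, c="purple", label="t (vs NN)")
    ax.scatter(x, df["s"], s=4, c="green", label="s (vs SS)")
    sig = df["ts_fdr_sig"].fillna(False).to_numpy(bool)
    ax.scatter(x[sig], df.loc[sig, "t"], s=14, facecolors="none", edgecolors="red")
    ax.scatter(x[sig], df.loc[sig, "s"], s=14, facecolors="none", edgecolors="blue")
    ax.axhline(0.0, lw=0.6, c="k")
    ax.set_ylabel("selection\ncoefficient")
    ax.legend(loc="upper right", fontsize=7)
    for chrom, lo, hi in bounds:
        axes[2].annotate(str(chrom), ((lo + hi) / 2, ax.get_ylim()[0]),
                         ha="center", fontsize=7)
    fig.tight_layout()
    return fig


def lod_curve(scan: pd.DataFrame, threshold: float | None = None):
    df = scan.reset_index(drop=True)
    x, bounds = _genome_x(df)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(x, df["lod"], lw=0.8)
    if threshold is not None:
        ax.axhline(threshold, ls="--", c="r", lw=0.8)
    for chrom, lo, hi in bounds:
        ax.axvline(hi + 2.5, c="grey", lw=0.4)
        ax.annotate(str(chrom), ((lo + hi) / 2, 0), ha="center", fontsize=7)
    ax.set_ylabel("LOD")
    ax.set_xlabel("map position")
    fig.tight_layout()
    return fig


def qtl_segments(peaks: pd.DataFrame, chrom_lengths: dict):
    """QTL support intervals drawn alongside their chromosomes."""
    fig, ax = plt.subplots(figsize=(8, 4))
    chroms = list(chrom_lengths)
    for i, c in enumerate(chroms):
        ax.plot([i, i], [0, chrom_lengths[c]], c="k", lw=3, solid_capstyle="round")
    traits = sorted(peaks["trait"].unique()) if "trait" in peaks else [""]
    cmap = plt.get_cmap("tab20")
    for _, r in peaks.iterrows():
        i = chroms.index(r["chrom"])
        k = traits.index(r["trait"]) if "trait" in peaks else 0
        off = 0.08 * (1 + k % 8)
        ax.plot([i + off, i + off], [r["interval_lo"], r["interval_hi"]],
                c=cmap(k % 20), lw=2)
        ax.plot(i + off, r["cM"], marker="o", ms=3, c=cmap(k % 20))
    ax.set_xticks(range(len(chroms)), [str(c) for c in chroms])
    ax.set_ylabel("cM")
    ax.invert_yaxis()
    fig.tight_layout()
    return fig


def network_figure(network):
    """Spring-layout drawing of a trait correlation network."""
    import networkx as nx

    g = network.graph()
    fig, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(g, seed=0)
    colors = ["tab:blue" if d.get("sign", 1) > 0 else "tab:red"
              for _, _, d in g.edges(data=True)]
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=250, font_size=7,
                     edge_color=colors, node_color="lightgrey")
    ax.axis("off")
    fig.tight_layout()
    return fig
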