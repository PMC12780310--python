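"""Genetic map container.

A :class:`GeneticMap` is an ordered marker table (marker id, linkage
group, cM position, optional bp position).  It is the shared coordinate
system for the cross simulator, the distortion scan and the QTL scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "default_map", "small_map"]


@dataclass
class GeneticMap:
    """Ordered markers with linkage-group, cM and optional bp coordinates.

    Invariants enforced at construction: unique marker ids, cM positions
    non-decreasing within a chromosome, bp (when present) strictly
    increasing within a chromosome.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if (t["cM"] < 0).any():
            raise ValueError("cM positions must be >= 0")
        for chrom, sub in t.groupby("chrom", sort=False):
            cm = sub["cM"].to_numpy(float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM not non-decreasing on chromosome {chrom}")
            if "bp" in sub.columns and sub["bp"].notna().all():
                bp = sub["bp"].to_numpy(float)
                if np.any(np.diff(bp) <= 0):
                    raise ValueError(f"bp not strictly increasing on chromosome {chrom}")
        self.table = t.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    @property
    def has_bp(self) -> bool:
        return "bp" in self.table.columns and self.table["bp"].notna().all()

    def chrom_table(self, chrom) -> pd.DataFrame:
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"no such chromosome {chrom!r}")
        return sub

    def chrom_length(self, chrom) -> float:
        cm = self.chrom_table(chrom)["cM"]
        return float(cm.iloc[-1] - cm.iloc[0])

    @property
    def total_length(self) -> float:
        return float(sum(self.chrom_length(c) for c in self.chromosomes))

    def marker_index(self, marker_id: str) -> int:
        idx = np.flatnonzero((self.table["marker"] == marker_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no such marker {marker_id!r}")
        return int(idx[0])

    def nearest_marker(self, chrom, pos_cM: float) -> int:
        """Global index of the marker nearest to (chrom, pos_cM)."""
        sub = self.chrom_table(chrom)
        cm = sub["cM"].to_numpy(float)
        local = int(np.argmin(np.abs(cm - pos_cM)))
        return int(sub.index[local])

    def __len__(self) -> int:
        return self.n_markers

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return self.table.equals(other.table)


# per-chromosome marker counts (sum 2082) and genetic lengths (sum 240 cM)
# mirroring the scale of a dense 8-linkage-group intercross map
_DEFAULT_COUNTS = (369, 160, 310, 250, 220, 180, 233, 360)
_DEFAULT_LEN_CM = (35.0, 20.0, 38.0, 30.0, 28.0, 22.0, 27.0, 40.0)
_DEFAULT_LEN_BP = (33, 20, 35, 39, 25, 22, 30, 27)  # Mb


def default_map(seed: int = 0, with_bp: bool = True) -> GeneticMap:
    """Default synthetic map: 8 chromosomes, 240 cM, 2082 markers.

    Marker spacing is drawn from a Dirichlet-flat distribution so spacing
    is irregular (as in empirical maps) but reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c, (n, length_cm, length_mb) in enumerate(
        zip(_DEFAULT_COUNTS, _DEFAULT_LEN_CM, _DEFAULT_LEN_BP), start=1
    ):
        gaps = rng.dirichlet(np.ones(n - 1)) * length_cm
        cm = np.concatenate([[0.0], np.cumsum(gaps)])
        cm = np.round(cm, 4)
        cm = np.maximum.accumulate(cm)  # guard against rounding inversions
        bp = np.round(np.linspace(1, length_mb * 1_000_000, n)).astype(int)
        for j in range(n):
            rows.append((f"c{c}_m{j + 1}", c, cm[j], bp[j]))
    table = pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp"])
    if not with_bp:
        table = table.drop(columns="bp")
    return GeneticMap(table)


def small_map(
    n_chrom: int = 2,
    markers_per_chrom: int = 11,
    length_cM: float = 50.0,
    with_bp: bool = True,
) -> GeneticMap:
    """Small evenly spaced map, convenient for simulations and tests."""
    rows = []
    for c in range(1, n_chrom + 1):
        cm = np.linspace(0.0, length_cM, markers_per_chrom)
        bp = np.round(np.linspace(1, length_cM * 2e5, markers_per_chrom)).astype(int)
        for j in range(markers_per_chrom):
            rows.append((f"c{c}_m{j + 1}", c, float(cm[j]), int(bp[j])))
    table = pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp"])
    if not with_bp:
        table = table.drop(columns="bp")
    return GeneticMap(table)
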