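"""F2/F3 intercross simulator.

Generates genotype tables for an F2 population descending from a cross
between two inbred parental lines (alleles ``N`` and ``S``), with
optional gametic drive (biased transmission during gamete formation),
zygotic viability selection, genotyping error and missing data; builds
quantitative phenotypes from additive/dominance QTL architectures; and
produces F3 families segregating across a fine-mapping region.

Genotypes are encoded internally as int8: 0 = NN, 1 = NS, 2 = SS,
-1 = missing.  Alleles: 0 = N, 1 = S.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gmap import GeneticMap, default_map
from .mapfun import map_function

__all__ = [
    "GENO_CODES",
    "DriveLocus",
    "ViabilityLocus",
    "CrossConfig",
    "F2GenotypeTable",
    "QTL",
    "TraitArchitecture",
    "simulate_gametes",
    "simulate_f2_cross",
    "simulate_phenotypes",
    "simulate_f3_families",
]

GENO_CODES = ("NN", "NS", "SS")
MISSING = -1


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class DriveLocus:
    """Biased transmission at a locus: the S allele is transmitted with
    probability ``k_female`` through eggs and ``k_male`` through pollen.
    ``k = 0.5`` is Mendelian."""

    chrom: object
    cM: float
    k_female: float = 0.5
    k_male: float = 0.5

    def __post_init__(self):
        for k in (self.k_female, self.k_male):
            if not 0.0 <= k <= 1.0:
                raise ValueError("transmission probability must be in [0, 1]")


@dataclass(frozen=True)
class ViabilityLocus:
    """Zygotic viability selection: relative survival 1-t (NN),
    1-u (NS), 1-s (SS)."""

    chrom: object
    cM: float
    t: float = 0.0
    s: float = 0.0
    u: float = 0.0

    def __post_init__(self):
        for v in (self.t, self.s, self.u):
            if not 0.0 <= v <= 1.0:
                raise ValueError("selection coefficients must be in [0, 1]")


@dataclass
class CrossConfig:
    """Full specification of a simulated F2 cross."""

    n_individuals: int = 742
    gmap: Optional[GeneticMap] = None
    drive_loci: Sequence[DriveLocus] = field(default_factory=tuple)
    viability_loci: Sequence[ViabilityLocus] = field(default_factory=tuple)
    missing_rate: float = 0.0
    error_rate: float = 0.0
    cross_direction_fractions: dict = field(
        default_factory=lambda: {"NxS": 0.5, "SxN": 0.5}
    )
    n_trays: int = 24
    map_kind: str = "haldane"
    seed: int = 0

    def __post_init__(self):
        if self.gmap is None:
            self.gmap = default_map()
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        chroms = set(self.gmap.chromosomes)
        for loc in list(self.drive_loci) + list(self.viability_loci):
            if loc.chrom not in chroms:
                raise ValueError(f"locus on chromosome {loc.chrom!r} is off the map")
        if all(v.t >= 1 and v.s >= 1 and v.u >= 1 for v in self.viability_loci) and self.viability_loci:
            raise ValueError("all genotypes inviable: population unattainable")

    def truth(self) -> dict:
        """Ground-truth manifest of the configured distortion regime."""
        return {
            "n_individuals": self.n_individuals,
            "seed": self.seed,
            "map_kind": self.map_kind,
            "drive_loci": [asdict(d) for d in self.drive_loci],
            "viability_loci": [asdict(v) for v in self.viability_loci],
            "missing_rate": self.missing_rate,
            "error_rate": self.error_rate,
        }


@dataclass
class F2GenotypeTable:
    """Individuals x markers genotype matrix plus covariates.

    ``genotypes`` is int8 with codes {0: NN, 1: NS, 2: SS, -1: missing};
    ``covariates`` carries cross_direction and tray labels indexed like
    ``ids``.
    """

    ids: list
    genotypes: np.ndarray
    gmap: GeneticMap
    covariates: pd.DataFrame

    def __post_init__(self):
        n, m = self.genotypes.shape
        if len(self.ids) != n:
            raise ValueError("ids length does not match genotype rows")
        if m != self.gmap.n_markers:
            raise ValueError("genotype columns do not match map")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def geno_strings(self) -> np.ndarray:
        """Genotypes as an object array of 'NN'/'NS'/'SS'/'-'."""
        lut = np.array(["NN", "NS", "SS"], dtype=object)
        out = np.empty(self.genotypes.shape, dtype=object)
        miss = self.genotypes < 0
        out[~miss] = lut[self.genotypes[~miss]]
        out[miss] = "-"
        return out

    def counts_at(self, j: int) -> tuple[int, int, int]:
        col = self.genotypes[:, j]
        return tuple(int(np.sum(col == g)) for g in (0, 1, 2))


# ---------------------------------------------------------------------------
# gamete simulation
# ---------------------------------------------------------------------------
def _chrom_gametes(rng, r, n):
    """n gametes over one chromosome given inter-marker recombination
    fractions r (length m-1); returns int8 (n, m) allele matrix."""
    m = len(r) + 1
    start = rng.integers(0, 2, size=(n, 1), dtype=np.int8)
    if m == 1:
        return start
    rec = (rng.random((n, m - 1)) < r).astype(np.int8)
    phase = np.cumsum(np.concatenate([start, rec], axis=1), axis=1, dtype=np.int32)
    return (phase % 2).astype(np.int8)


def _drive_accept(rng, alleles, drive_idx, ks):
    """Rejection-sampling mask: accept whole gametes with probability
    proportional to the transmission weight of the allele carried at each
    driver locus, so linkage to flanking markers is preserved."""
    if not drive_idx:
        return np.ones(alleles.shape[0], dtype=bool)
    w = np.ones(alleles.shape[0])
    wmax = 1.0
    for j, k in zip(drive_idx, ks):
        w *= np.where(alleles[:, j] == 1, k, 1.0 - k)
        wmax *= max(k, 1.0 - k)
    return rng.random(alleles.shape[0]) < w / wmax


def simulate_gametes(
    gmap: GeneticMap,
    n: int,
    rng,
    drive_loci: Sequence[DriveLocus] = (),
    sex: str = "female",
    map_kind: str = "haldane",
) -> np.ndarray:
    """Simulate n F1 gametes (allele matrix, 0=N / 1=S) over the whole map.

    Crossovers between adjacent markers occur with the recombination
    fraction given by the map function; chromosomes assort independently.
    Drive loci bias transmission via rejection sampling of whole gametes.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    blocks = []
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_table(chrom)
        cm = sub["cM"].to_numpy(float)
        r = map_function(np.diff(cm), kind=map_kind)
        drive_here = [d for d in drive_loci if d.chrom == chrom]
        didx, ks = [], []
        for d in drive_here:
            local = int(np.argmin(np.abs(cm - d.cM)))
            didx.append(local)
            ks.append(d.k_female if sex == "female" else d.k_male)
        out = np.empty((n, len(cm)), dtype=np.int8)
        got = 0
        while got < n:
            batch = max(2 * (n - got), 64)
            g = _chrom_gametes(rng, r, batch)
            keep = _drive_accept(rng, g, didx, ks)
            g = g[keep]
            take = min(len(g), n - got)
            out[got : got + take] = g[:take]
            got += take
        blocks.append(out)
    return np.concatenate(blocks, axis=1)


def _viability_weights(genos, gmap, viability_loci):
    w = np.ones(genos.shape[0])
    for v in viability_loci:
        j = gmap.nearest_marker(v.chrom, v.cM)
        surv = np.array([1.0 - v.t, 1.0 - v.u, 1.0 - v.s])
        w *= surv[genos[:, j]]
    return w


def simulate_f2_cross(config: CrossConfig) -> F2GenotypeTable:
    """Simulate an F2 genotype table under the configured regime.

    Each individual is the union of one maternal and one paternal gamete
    drawn from F1 heterozygotes; zygotes then survive viability selection
    (resampling until ``n_individuals`` are obtained); finally genotyping
    error flips codes and missingness masks entries.  Fully reproducible
    for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    gmap = config.gmap
    n = config.n_individuals
    rows = []
    got = 0
    while got < n:
        batch = max(n - got, 32)
        mat = simulate_gametes(gmap, batch, rng, config.drive_loci, "female", config.map_kind)
        pat = simulate_gametes(gmap, batch, rng, config.drive_loci, "male", config.map_kind)
        genos = (mat + pat).astype(np.int8)
        if config.viability_loci:
            w = _viability_weights(genos, gmap, config.viability_loci)
            genos = genos[rng.random(batch) < w]
        take = genos[: n - got]
        rows.append(take)
        got += len(take)
    genos = np.concatenate(rows, axis=0)

    if config.error_rate > 0:
        flip = rng.random(genos.shape) < config.error_rate
        shift = rng.integers(1, 3, size=genos.shape).astype(np.int8)
        genos = np.where(flip, (genos + shift) % 3, genos).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(genos.shape) < config.missing_rate
        genos = np.where(miss, np.int8(MISSING), genos)

    dirs = list(config.cross_direction_fractions)
    probs = np.array([config.cross_direction_fractions[d] for d in dirs], dtype=float)
    probs = probs / probs.sum()
    cross_dir = rng.choice(dirs, size=n, p=probs)
    tray = rng.integers(1, config.n_trays + 1, size=n)
    ids = [f"F2_{i + 1:04d}" for i in range(n)]
    cov = pd.DataFrame(
        {"cross_direction": cross_dir, "tray": [f"T{t:02d}" for t in tray]}, index=ids
    )
    return F2GenotypeTable(ids=ids, genotypes=genos, gmap=gmap, covariates=cov)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class QTL:
    """Additive/dominance effect of the S allele at a map position:
    genotype score x in {-1 (NN), 0 (NS), +1 (SS)}, dominance indicator
    z = 1 for NS."""

    chrom: object
    cM: float
    a: float
    d: float = 0.0


@dataclass
class TraitArchitecture:
    name: str
    qtls: Sequence[QTL] = field(default_factory=tuple)
    residual_sd: float = 1.0
    family: str = "gaussian"  # or "count"
    intercept: float = 0.0
    fertility_locus: Optional[tuple] = None  # (chrom, cM)
    het_fertility_penalty: float = 0.0  # delta in [0, 1)

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if not 0.0 <= self.het_fertility_penalty < 1.0:
            raise ValueError("het_fertility_penalty must be in [0, 1)")
        if self.family not in ("gaussian", "count"):
            raise ValueError("family must be 'gaussian' or 'count'")


def _qtl_scores(table: F2GenotypeTable, chrom, cM):
    """Additive (x) and dominance (z) scores at the marker nearest a QTL.

    Missing genotypes get the expected score under the marker's observed
    marginal genotype frequencies.
    """
    j = table.gmap.nearest_marker(chrom, cM)
    g = table.genotypes[:, j]
    x = np.where(g == 0, -1.0, np.where(g == 2, 1.0, 0.0))
    z = (g == 1).astype(float)
    miss = g == MISSING
    if miss.any():
        counts = np.array(table.counts_at(j), dtype=float)
        if counts.sum() == 0:
            fx, fz = 0.0, 0.5
        else:
            p = counts / counts.sum()
            fx = -p[0] + p[2]
            fz = p[1]
        x[miss] = fx
        z[miss] = fz
    return x, z


def simulate_phenotypes(
    table: F2GenotypeTable,
    architectures: Sequence[TraitArchitecture],
    covariate_effects: Optional[dict] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a phenotype table from QTL architectures and covariates.

    y = intercept + sum_q (a_q x_q + d_q z_q) + cross-direction effect
    + tray effect + residual noise.  For a trait with a fertility locus,
    the mean is multiplied by (1 - delta) for heterozygotes at that
    locus.  ``count`` traits are Poisson draws around exp-free means
    clipped at zero.
    """
    rng = np.random.default_rng(seed)
    cov_eff = covariate_effects or {}
    n = table.n_individuals
    out = pd.DataFrame(index=pd.Index(table.ids, name="id"))
    out["cross_direction"] = table.covariates["cross_direction"].to_numpy()
    out["tray"] = table.covariates["tray"].to_numpy()

    dir_eff = cov_eff.get("cross_direction", {})
    dir_term = np.array([dir_eff.get(d, 0.0) for d in out["cross_direction"]])
    tray_sd = float(cov_eff.get("tray_sd", 0.0))
    trays = sorted(out["tray"].unique())
    tray_values = dict(zip(trays, rng.normal(0.0, tray_sd or 0.0, size=len(trays))))
    tray_term = np.array([tray_values[t] for t in out["tray"]])

    for arch in architectures:
        mean = np.full(n, float(arch.intercept))
        for q in arch.qtls:
            x, z = _qtl_scores(table, q.chrom, q.cM)
            mean += q.a * x + q.d * z
        mean += dir_term + tray_term
        if arch.fertility_locus is not None and arch.het_fertility_penalty > 0:
            j = table.gmap.nearest_marker(*arch.fertility_locus)
            het = table.genotypes[:, j] == 1
            mean = np.where(het, mean * (1.0 - arch.het_fertility_penalty), mean)
        if arch.family == "gaussian":
            y = mean + rng.normal(0.0, arch.residual_sd, size=n)
        else:
            y = rng.poisson(np.clip(mean, 0.0, None)).astype(float)
        out[arch.name] = y
    return out


# ---------------------------------------------------------------------------
# F3 fine-mapping families
# ---------------------------------------------------------------------------
def simulate_f3_families(
    region_cM: Sequence[float],
    n_families: int = 15,
    seeds_per_family: int = 90,
    plants_per_family: int = 27,
    causal: tuple = (2, 0.10),
    n_trials: int = 2,
    trays_per_trial: int = 5,
    baseline_days: float = 200.0,
    family_sd: float = 0.05,
    trial_effect: float = 0.10,
    tray_sd: float = 0.03,
    map_kind: str = "haldane",
    seed: int = 0,
):
    """Simulate F3 families segregating across a 4-interval region.

    Each family descends from an F2 parent heterozygous across the whole
    region (the fine-mapping selection criterion); offspring arise by
    selfing: two independent gametes with recombination between the five
    ordered boundary markers.  ``seeds_per_family`` records the sowing
    design; ``plants_per_family`` is the number that reach genotyping and
    phenotyping.  The flowering-time-like phenotype is a Poisson count
    (days) with log-scale family, trial and nested-tray effects plus the
    causal interval's additive effect (``causal = (interval 1..4,
    log-scale effect per S allele)``).

    Returns (interval_genotypes, phenotypes, truth) where truth records
    the causal interval, per-plant causal genotypes and recombinant flags.
    """
    region_cM = np.asarray(region_cM, dtype=float)
    if region_cM.size < 2:
        raise ValueError("need at least 2 boundary markers")
    if np.any(np.diff(region_cM) < 0):
        raise ValueError("boundary marker positions must be non-decreasing")
    n_int = region_cM.size - 1
    c_idx, c_eff = int(causal[0]), float(causal[1])
    if not 1 <= c_idx <= n_int:
        raise ValueError(f"causal interval must be in 1..{n_int}")
    if plants_per_family > seeds_per_family:
        raise ValueError("cannot retain more plants than seeds sown")

    rng = np.random.default_rng(seed)
    # loci: boundary markers with causal point inserted at its interval midpoint
    causal_pos = 0.5 * (region_cM[c_idx - 1] + region_cM[c_idx])
    loci = np.concatenate([region_cM[:c_idx], [causal_pos], region_cM[c_idx:]])
    causal_col = c_idx
    marker_cols = [i for i in range(loci.size) if i != causal_col]
    r = map_function(np.diff(loci), kind=map_kind)

    n_total = n_families * plants_per_family
    fam = np.repeat(np.arange(1, n_families + 1), plants_per_family)
    g1 = _chrom_gametes(rng, r, n_total)
    g2 = _chrom_gametes(rng, r, n_total)
    genos = (g1 + g2).astype(np.int8)

    marker_genos = genos[:, marker_cols]
    causal_geno = genos[:, causal_col]
    # recombinant: any two boundary genotypes differ (single-generation look)
    recomb = np.any(marker_genos != marker_genos[:, [0]], axis=1)

    trial = rng.integers(1, n_trials + 1, size=n_total)
    # family-blocked sowing: a family's plants share a tray within a trial
    fam_per_tray = max(1, int(np.ceil(n_families / trays_per_trial)))
    tray = (fam - 1) // fam_per_tray + 1
    fam_eff = rng.normal(0.0, family_sd, size=n_families)
    trial_effs = np.linspace(0.0, trial_effect, n_trials)
    tray_effs = rng.normal(0.0, tray_sd, size=(n_trials, trays_per_trial))

    x = causal_geno.astype(float) - 1.0  # -1 NN, 0 NS, +1 SS
    log_mu = (
        np.log(baseline_days)
        + fam_eff[fam - 1]
        + trial_effs[trial - 1]
        + tray_effs[trial - 1, tray - 1]
        + c_eff * x
    )
    flowering = rng.poisson(np.exp(log_mu)).astype(int)

    ids = [f"F3_{i + 1:04d}" for i in range(n_total)]
    lut = np.array(["NN", "NS", "SS"], dtype=object)
    geno_df = pd.DataFrame(
        {
            "family": fam,
            "trial": trial,
            "tray": [f"t{a}_{b}" for a, b in zip(trial, tray)],
        },
        index=pd.Index(ids, name="id"),
    )
    for j in range(region_cM.size):
        geno_df[f"M{j + 1}"] = lut[marker_genos[:, j]]
    pheno_df = geno_df[["family", "trial", "tray"]].copy()
    pheno_df["flowering_time"] = flowering
    truth = {
        "causal_interval": c_idx,
        "causal_effect": c_eff,
        "causal_genotype": causal_geno.copy(),
        "recombinant": recomb.copy(),
        "seeds_per_family": seeds_per_family,
        "region_cM": region_cM.tolist(),
        "seed": seed,
    }
    return geno_df, pheno_df, truth
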