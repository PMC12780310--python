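"""Two-population Wright-Fisher simulator with admixture pulses.

A desk-scale, discrete-generation forward simulator of the two-species
demography used for sweep-threshold calibration: an ancestral population
splits into two descendant populations which later exchange migrants in
instantaneous pulses; mutation is infinite-sites (uniform bp positions
with collision rejection), recombination is Poisson along the sequence,
and an optional beneficial allele can be injected to produce selective
sweeps (trajectory conditioned on non-loss by retry).

Population sizes and times are meant to be *scaled down* relative to any
real system, with per-bp mutation and recombination rates scaled up
correspondingly; the realized parameters are recorded in the output
metadata.  For bulk neutral replicates an exact coalescent backend
(msprime) is also available and is the default there; the forward
simulator is the only backend that supports sweeps and is cross-checked
against the coalescent backend in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "DemographyConfig",
    "SweepConfig",
    "HaplotypeMatrix",
    "simulate_population",
    "neutral_replicates",
    "nucleotide_diversity",
    "site_frequency_spectrum",
]


@dataclass
class DemographyConfig:
    """Scaled-down two-population demography.

    Times are in generations ago; pulses are (time_ago, source, dest,
    fraction): at that generation, ``fraction`` of the destination
    population's parents are drawn from the source population.  The
    default pulse times/fractions are placeholders for a
    split-with-two-pulses history (one ancient pulse just after the
    split, one recent) and should be replaced when a fitted demography
    is available.
    """

    N_anc: int = 500
    N1: int = 500
    N2: int = 500
    t_split: int = 1000
    pulses: Sequence[tuple] = field(
        default_factory=lambda: ((990, "p2", "p1", 0.10), (50, "p2", "p1", 0.05))
    )
    mu: float = 5e-7
    rho: float = 5.5e-8
    L: int = 100_000
    sample_sizes: dict = field(default_factory=lambda: {"p1": 20, "p2": 17})
    burnin_factor: int = 8
    seed: int = 0

    def __post_init__(self):
        for t, src, dst, f in self.pulses:
            if not 0 < t < self.t_split:
                raise ValueError("pulse times must lie in (0, t_split)")
            if not 0.0 <= f <= 1.0:
                raise ValueError("pulse fractions must be in [0, 1]")
            if {src, dst} - {"p1", "p2"}:
                raise ValueError("pulse populations must be 'p1' or 'p2'")


@dataclass
class SweepConfig:
    """A beneficial allele: injected as a single copy ``t_intro``
    generations ago into ``pop``; genotype fitnesses 1 : 1+hs : 1+s."""

    position_bp: int
    s_adv: float
    h: float = 0.5
    t_intro: int = 200
    pop: str = "p1"
    max_retries: int = 200

    def __post_init__(self):
        if self.s_adv <= 0:
            raise ValueError("s_adv must be > 0")


@dataclass
class HaplotypeMatrix:
    """Binary haplotypes x segregating sites with bp positions."""

    matrix: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    pops: list = field(repr=False)
    metadata: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("positions do not match matrix columns")
        if len(self.pops) != self.matrix.shape[0]:
            raise ValueError("pop labels do not match matrix rows")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def subset_pop(self, pop) -> "HaplotypeMatrix":
        keep = np.array([p == pop for p in self.pops])
        m = self.matrix[keep]
        seg = (m.sum(axis=0) > 0) & (m.sum(axis=0) < keep.sum())
        return HaplotypeMatrix(
            m[:, seg], self.positions[seg], [pop] * int(keep.sum()), dict(self.metadata)
        )


# ---------------------------------------------------------------------------
# forward machinery
# ---------------------------------------------------------------------------
def _gametes(haps, parent_ids, rng, c_mean, positions):
    """One gamete per entry of parent_ids (individual indices into haps,
    which holds two rows per individual)."""
    G = len(parent_ids)
    S = haps.shape[1]
    h0 = haps[2 * parent_ids]
    h1 = haps[2 * parent_ids + 1]
    start = rng.integers(0, 2, size=G)
    out = np.where(start[:, None] == 0, h0, h1)
    if S == 0 or c_mean == 0:
        return out
    n_co = rng.poisson(c_mean, size=G)
    for g in np.flatnonzero(n_co):
        bk = np.sort(rng.uniform(0, positions[-1] + 1, size=n_co[g]))
        phase = (start[g] + np.searchsorted(bk, positions)) % 2
        out[g] = np.where(phase == 0, h0[g], h1[g])
    return out


def _new_mutations(rng, pops, positions, mu_total_per_gamete, L):
    """Append infinite-sites mutations; returns updated (pops, positions)."""
    sizes = {k: v.shape[0] for k, v in pops.items()}
    total_haps = sum(sizes.values())
    n_new = rng.poisson(mu_total_per_gamete * total_haps)
    if n_new == 0:
        return pops, positions
    existing = set(positions.tolist())
    new_pos = []
    while len(new_pos) < n_new:
        cand = int(rng.integers(1, L + 1))
        if cand not in existing:
            existing.add(cand)
            new_pos.append(cand)
    carriers = rng.integers(0, total_haps, size=n_new)
    new_cols = {k: np.zeros((v, n_new), dtype=np.uint8) for k, v in sizes.items()}
    offsets = {}
    off = 0
    for k, v in sizes.items():
        offsets[k] = off
        off += v
    for j, c in enumerate(carriers):
        for k, v in sizes.items():
            if offsets[k] <= c < offsets[k] + v:
                new_cols[k][c - offsets[k], j] = 1
                break
    positions = np.concatenate([positions, np.array(new_pos, dtype=np.int64)])
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    pops = {
        k: np.concatenate([v, new_cols[k]], axis=1)[:, order] for k, v in pops.items()
    }
    return pops, positions


def _prune(pops, positions, keep_pos=None):
    """Drop columns globally fixed or lost (optionally protecting one
    position); returns (pops, positions, dropped_fixed_positions)."""
    if positions.size == 0:
        return pops, positions, set()
    total = sum(v.sum(axis=0, dtype=np.int64) for v in pops.values())
    haps = sum(v.shape[0] for v in pops.values())
    seg = (total > 0) & (total < haps)
    if keep_pos is not None:
        seg |= positions == keep_pos
    fixed = set(positions[(total == haps) & ~seg].tolist())
    pops = {k: np.ascontiguousarray(v[:, seg]) for k, v in pops.items()}
    return pops, positions[seg], fixed


def _step_pop(pops, positions, name, N_child, parent_pools, rng, c_mean, fitness=None):
    """One WF generation for one population.

    parent_pools: list of (pool_name, probability) for pulse handling;
    each parent of each child is drawn independently from a pool.
    """
    gam = []
    for _ in range(2):  # maternal then paternal gamete sets
        pool_names = [p for p, _ in parent_pools]
        pool_probs = np.array([pr for _, pr in parent_pools])
        which = rng.choice(len(pool_names), size=N_child, p=pool_probs)
        g = np.empty((N_child, positions.size), dtype=np.uint8)
        for i_pool, pool in enumerate(pool_names):
            sel = which == i_pool
            n_sel = int(sel.sum())
            if n_sel == 0:
                continue
            haps = pops[pool]
            N_pool = haps.shape[0] // 2
            if fitness is not None and pool == name:
                pid = rng.choice(N_pool, size=n_sel, p=fitness)
            else:
                pid = rng.integers(0, N_pool, size=n_sel)
            g[sel] = _gametes(haps, pid, rng, c_mean, positions)
        gam.append(g)
    child = np.empty((2 * N_child, positions.size), dtype=np.uint8)
    child[0::2] = gam[0]
    child[1::2] = gam[1]
    return child


def _sweep_fitness(haps, positions, pos_bp, s, h):
    j = np.searchsorted(positions, pos_bp)
    if j >= positions.size or positions[j] != pos_bp:
        return None, 0  # allele fixed-and-pruned or absent
    dosage = haps[0::2, j].astype(int) + haps[1::2, j].astype(int)
    w = np.where(dosage == 0, 1.0, np.where(dosage == 1, 1.0 + h * s, 1.0 + s))
    return w / w.sum(), int(dosage.sum())


def _forward_simulation(demog: DemographyConfig, sweep, rng) -> HaplotypeMatrix:
    L = demog.L
    mu_gam = demog.mu * L
    c_mean = demog.rho * L
    pulse_by_gen = {}
    for t, src, dst, f in demog.pulses:
        pulse_by_gen.setdefault(int(t), []).append((src, dst, f))

    pops = {"anc": np.zeros((2 * demog.N_anc, 0), dtype=np.uint8)}
    positions = np.empty(0, dtype=np.int64)
    burnin = demog.burnin_factor * demog.N_anc
    for _ in range(burnin):
        child = _step_pop(pops, positions, "anc", demog.N_anc, [("anc", 1.0)], rng, c_mean)
        pops = {"anc": child}
        pops, positions = _new_mutations(rng, pops, positions, mu_gam, L)
        pops, positions, _ = _prune(pops, positions)

    # split: descendant founders drawn with replacement from the ancestor
    anc = pops["anc"]
    def _found(N):
        idx = rng.integers(0, anc.shape[0] // 2, size=N)
        out = np.empty((2 * N, positions.size), dtype=np.uint8)
        out[0::2] = anc[2 * idx]
        out[1::2] = anc[2 * idx + 1]
        return out

    pops = {"p1": _found(demog.N1), "p2": _found(demog.N2)}
    sizes = {"p1": demog.N1, "p2": demog.N2}

    sweep_active = False
    sweep_done = False
    snapshot = None
    retries = 0
    sweep_freq = 0
    gen_ago = demog.t_split
    while gen_ago >= 1:
        if sweep is not None and not sweep_done and gen_ago == sweep.t_intro:
            if not sweep_active:
                snapshot = (
                    {k: v.copy() for k, v in pops.items()},
                    positions.copy(),
                    np.random.default_rng(rng.integers(2**31)),
                )
            # inject a single copy on a random haplotype of the swept pop
            j = np.searchsorted(positions, sweep.position_bp)
            if not (j < positions.size and positions[j] == sweep.position_bp):
                col = {
                    k: np.zeros((v.shape[0], 1), dtype=np.uint8) for k, v in pops.items()
                }
                carrier = rng.integers(0, pops[sweep.pop].shape[0])
                col[sweep.pop][carrier, 0] = 1
                positions = np.insert(positions, j, sweep.position_bp)
                pops = {
                    k: np.concatenate([v[:, :j], col[k], v[:, j:]], axis=1)
                    for k, v in pops.items()
                }
            sweep_active = True

        fitness = {}
        if sweep_active:
            w, sweep_freq = _sweep_fitness(
                pops[sweep.pop], positions, sweep.position_bp, sweep.s_adv, sweep.h
            )
            if sweep_freq == 0:
                retries += 1
                if retries > sweep.max_retries:
                    raise RuntimeError(
                        f"sweep allele lost after {retries} retries"
                    )
                pops = {k: v.copy() for k, v in snapshot[0].items()}
                positions = snapshot[1].copy()
                rng = np.random.default_rng(snapshot[2].integers(2**31))
                snapshot = (snapshot[0], snapshot[1], snapshot[2])
                gen_ago = sweep.t_intro
                continue
            if sweep_freq == pops[sweep.pop].shape[0]:
                sweep_active = False
                sweep_done = True
            else:
                fitness[sweep.pop] = w

        pulses = pulse_by_gen.get(gen_ago, [])
        new_pops = {}
        for name in ("p1", "p2"):
            pools = [(name, 1.0)]
            for src, dst, f in pulses:
                if dst == name:
                    pools = [(name, 1.0 - f), (src, f)]
            new_pops[name] = _step_pop(
                pops, positions, name, sizes[name], pools, rng, c_mean,
                fitness=fitness.get(name),
            )
        pops = new_pops
        pops, positions = _new_mutations(rng, pops, positions, mu_gam, L)
        keep = sweep.position_bp if (sweep is not None and sweep_active) else None
        pops, positions, _ = _prune(pops, positions, keep_pos=keep)
        gen_ago -= 1

    # sample haplotypes per population, keep segregating sites only
    rows = []
    labels = []
    for name in ("p1", "p2"):
        n = int(demog.sample_sizes.get(name, 0))
        if n == 0:
            continue
        idx = rng.choice(pops[name].shape[0], size=n, replace=False)
        rows.append(pops[name][idx])
        labels += [name] * n
    m = np.concatenate(rows, axis=0) if rows else np.zeros((0, positions.size), np.uint8)
    tot = m.sum(axis=0)
    seg = (tot > 0) & (tot < m.shape[0])
    meta = {"backend": "forward", "demography": asdict(demog)}
    if sweep is not None:
        meta["sweep"] = asdict(sweep)
        meta["sweep_fixed"] = bool(sweep_done)
        meta["sweep_retries"] = retries
    return HaplotypeMatrix(
        np.ascontiguousarray(m[:, seg]), positions[seg].copy(), labels, meta
    )


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------
def simulate_population(
    demog: DemographyConfig,
    sweep: Optional[SweepConfig] = None,
    seed: Optional[int] = None,
    backend: str = "forward",
) -> HaplotypeMatrix:
    """Simulate one replicate of the two-population demography.

    ``backend="forward"`` runs the discrete-generation Wright-Fisher
    simulator (required for sweeps); ``backend="coalescent"`` delegates
    neutral simulation to msprime with the matched demography.
    """
    if seed is None:
        seed = demog.seed
    if backend == "forward":
        return _forward_simulation(demog, sweep, np.random.default_rng(seed))
    if backend == "coalescent":
        if sweep is not None:
            raise ValueError("the coalescent backend is neutral-only")
        return _coalescent_simulation(demog, seed)
    raise ValueError("backend must be 'forward' or 'coalescent'")


def _build_msprime_demography(demog: DemographyConfig):
    import msprime

    d = msprime.Demography()
    # haploid lineages: initial_size 2N matches the diploid WF timescale
    d.add_population(name="p1", initial_size=2 * demog.N1)
    d.add_population(name="p2", initial_size=2 * demog.N2)
    d.add_population(name="anc", initial_size=2 * demog.N_anc)
    for t, src, dst, f in sorted(demog.pulses, key=lambda p: p[0]):
        d.add_mass_migration(time=t, source=dst, dest=src, proportion=f)
    d.add_population_split(time=demog.t_split, derived=["p1", "p2"], ancestral="anc")
    d.sort_events()
    return d


def _ts_to_matrix(ts, demog: DemographyConfig, mut_seed: int) -> HaplotypeMatrix:
    import msprime

    ts = msprime.sim_mutations(
        ts, rate=demog.mu, model=msprime.BinaryMutationModel(), random_seed=mut_seed
    )
    G = ts.genotype_matrix()  # sites x haplotypes, values in {0, 1}
    pos = ts.tables.sites.position.astype(np.int64) + 1
    seg = (G.min(axis=1) != G.max(axis=1)) & (G.max(axis=1) == 1)
    G, pos = G[seg], pos[seg]
    if pos.size:  # collapse duplicate discrete positions (keep the first)
        keep = np.concatenate([[True], np.diff(pos) > 0])
        G, pos = G[keep], pos[keep]
    samples = {k: int(v) for k, v in demog.sample_sizes.items() if v}
    labels = []
    for name in samples:
        labels += [name] * samples[name]
    meta = {"backend": "coalescent", "demography": asdict(demog)}
    m = np.ascontiguousarray(G.T.astype(np.uint8))
    return HaplotypeMatrix(m, pos, labels, meta)


def _coalescent_simulation(demog: DemographyConfig, seed: int) -> HaplotypeMatrix:
    import msprime

    d = _build_msprime_demography(demog)
    samples = {k: int(v) for k, v in demog.sample_sizes.items() if v}
    seed = int(seed) % (2**31 - 2) + 1
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=d,
        sequence_length=demog.L,
        recombination_rate=demog.rho,
        ploidy=1,
        random_seed=seed,
    )
    return _ts_to_matrix(ts, demog, seed)


def neutral_replicates(
    demog: DemographyConfig,
    n_reps: int,
    seed: int = 0,
    backend: str = "coalescent",
) -> Iterator[HaplotypeMatrix]:
    """Stream of independent, seeded neutral replicates (order-deterministic)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = np.random.default_rng(seed)
    child_seeds = root.integers(1, 2**31 - 2, size=n_reps)
    if backend == "coalescent":
        # one parsed simulator, many replicates (much cheaper than
        # rebuilding the demography per replicate)
        import msprime

        d = _build_msprime_demography(demog)
        samples = {k: int(v) for k, v in demog.sample_sizes.items() if v}
        reps = msprime.sim_ancestry(
            samples=samples,
            demography=d,
            sequence_length=demog.L,
            recombination_rate=demog.rho,
            ploidy=1,
            random_seed=int(child_seeds[0]),
            num_replicates=n_reps,
        )
        for s, ts in zip(child_seeds, reps):
            yield _ts_to_matrix(ts, demog, int(s))
        return
    for s in child_seeds:
        yield simulate_population(demog, sweep=None, seed=int(s), backend=backend)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------
def nucleotide_diversity(hm: HaplotypeMatrix, per_bp: bool = True) -> float:
    """Unbiased mean pairwise difference (pi), per bp by default."""
    m = hm.matrix
    nh = m.shape[0]
    if nh < 2:
        raise ValueError("need at least 2 haplotypes")
    freq = m.sum(axis=0)
    pi = float(np.sum(2.0 * freq * (nh - freq)) / (nh * (nh - 1)))
    if per_bp:
        L = hm.metadata.get("demography", {}).get("L")
        if L is None:
            raise ValueError("sequence length unknown; cannot report per-bp pi")
        return pi / L
    return pi


def site_frequency_spectrum(hm: HaplotypeMatrix) -> np.ndarray:
    """Folded-free (derived) SFS: counts of sites at derived count i,
    i = 1..n-1."""
    nh = hm.n_haplotypes
    freq = hm.matrix.sum(axis=0)
    return np.bincount(freq, minlength=nh + 1)[1:nh]
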