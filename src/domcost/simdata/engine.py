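"""Discrete-generation Wright-Fisher forward simulator with selection.

Life cycle per generation: viability selection (multiplicative across loci,
genotype fitness 1 / 1-hs / 1-s), migration (each offspring is drawn from
the other population's parent pool with probability m), random mating with
multinomial resampling, uniform crossover recombination, and infinite-sites
mutation over the genome layout (effect class assigned from the overlapping
CDS and codon position).

The ancestral population is initialized from the stationary distribution of
the same discrete Wright-Fisher chain (expected number of segregating sites
per derived-allele-count class under mutation-selection-drift balance,
obtained by a direct linear solve of the transition system), so no burn-in
is required; sites are placed on haplotypes at linkage equilibrium.  The
selected-site DFE is a gamma distribution on the selection cost s,
discretized into equal-probability bins.

Only sites segregating in the union of the two final samples are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, gamma

from .config import SimulationConfig
from .layout import (
    EFFECT_NAMES,
    GenomeLayout,
    MISSENSE,
    NONCODING,
    build_genome_layout,
    effect_table,
)

__all__ = ["SimulatedDataset", "simulate_two_population", "discretize_gamma"]


@dataclass
class SimulatedDataset:
    """Ground-truthed output of one simulation run.

    haplotypes: (n_sites, n_haplotypes) 0/1 matrix over the two focal
    samples; columns 2i, 2i+1 belong to diploid individual i.  sites is a
    DataFrame with position, ancestral/derived base, true effect class and
    true selection cost s.  outgroup_genotypes counts derived alleles
    (0/1/2) in each outgroup diploid at the focal sites; outgroup_sites
    lists fixed outgroup-branch substitutions away from the focal set.
    """

    haplotypes: np.ndarray
    sites: pd.DataFrame
    sample_ids: list[str]
    populations: list[str]
    outgroup_ids: list[str]
    outgroup_genotypes: np.ndarray
    outgroup_alleles: np.ndarray  # base code carried by the outgroup per site
    outgroup_sites: pd.DataFrame
    layout: GenomeLayout
    truth: dict

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[0]

    def genotypes(self) -> np.ndarray:
        """(n_individuals, n_sites) derived-allele dosage matrix."""
        H = self.haplotypes
        return (H[:, 0::2] + H[:, 1::2]).T.astype(np.int8)

    def population_of(self) -> np.ndarray:
        return np.asarray(self.populations)


def discretize_gamma(shape: float, mean: float, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-probability discretization of a gamma DFE on the selection cost
    s; bin representatives at the quantile midpoints, clipped to [0, 1)."""
    if mean <= 0:
        return np.zeros(1), np.ones(1)
    q = (np.arange(n_bins) + 0.5) / n_bins
    vals = gamma.ppf(q, a=shape, scale=mean / shape)
    vals = np.minimum(vals, 0.999999)
    return vals, np.full(n_bins, 1.0 / n_bins)


_EQ_CACHE: dict[tuple[int, float, float], np.ndarray] = {}


def _wf_stationary(K: int, s: float, h: float) -> np.ndarray:
    """Expected segregating-site count per derived-count class (1..K-1) per
    unit mutation influx, for a constant population of K haploid genomes.

    Solves f = T' f + e_1 where T is the one-generation Wright-Fisher
    transition (selection then binomial resampling) restricted to
    non-absorbed classes.
    """
    key = (K, round(float(s), 12), round(float(h), 12))
    if key in _EQ_CACHE:
        return _EQ_CACHE[key]
    x = np.arange(1, K) / K
    if s != 0.0:
        w11, w01 = 1.0 - s, 1.0 - h * s
        num = x * x * w11 + x * (1 - x) * w01
        den = x * x * w11 + 2 * x * (1 - x) * w01 + (1 - x) ** 2
        xp = num / den
    else:
        xp = x
    j = np.arange(1, K)
    T = binom.pmf(j[None, :], K, xp[:, None])  # (from, to), interior only
    src = np.zeros(K - 1)
    src[0] = 1.0
    f = np.linalg.solve(np.eye(K - 1) - T.T, src)
    f = np.maximum(f, 0.0)
    _EQ_CACHE[key] = f
    return f


def _assign_equilibrium_haplotypes(
    counts: np.ndarray, K: int, rng: np.random.Generator
) -> np.ndarray:
    """(K, n_sites) matrix with column k carrying counts[k] derived alleles
    on uniformly random haplotypes (linkage-equilibrium initialization)."""
    n_sites = len(counts)
    if n_sites == 0:
        return np.zeros((K, 0), dtype=np.uint8)
    U = rng.random((n_sites, K))
    ranks = np.argsort(np.argsort(U, axis=1), axis=1)
    return (ranks < counts[:, None]).T.astype(np.uint8)


@dataclass
class _Sites:
    positions: np.ndarray  # int64
    alt: np.ndarray        # uint8 base code of the derived allele
    effect: np.ndarray     # int8 effect code
    s: np.ndarray          # float selection cost (negative = beneficial)

    def order(self) -> np.ndarray:
        return np.argsort(self.positions, kind="stable")

    def take(self, idx) -> "_Sites":
        return _Sites(
            self.positions[idx], self.alt[idx], self.effect[idx], self.s[idx]
        )

    @staticmethod
    def concat(a: "_Sites", b: "_Sites") -> "_Sites":
        return _Sites(
            np.concatenate([a.positions, b.positions]),
            np.concatenate([a.alt, b.alt]),
            np.concatenate([a.effect, b.effect]),
            np.concatenate([a.s, b.s]),
        )


class _ClassCatalog:
    """Enumerates (position, alt) pairs by effect class for mutation draws."""

    def __init__(self, layout: GenomeLayout, config: SimulationConfig):
        self.layout = layout
        cpos, ceff = effect_table(layout)
        self.coding_pos = cpos
        self.coding_eff = ceff
        self.coding_set = set(int(p) for p in cpos)
        self.pos_index = {int(p): i for i, p in enumerate(cpos)}
        L = layout.length
        self.coding_only = bool(config.coding_only)
        self.n_noncoding_pairs = 0 if self.coding_only else 3 * (L - len(cpos))
        self.pairs_by_class: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for eff_code in (1, 2, 3):
            rows, alts = np.nonzero(ceff == eff_code)
            self.pairs_by_class[eff_code] = (cpos[rows], alts.astype(np.uint8))
        if self.coding_only:
            self.noncoding_positions = np.empty(0, dtype=np.int64)
        else:
            noncoding_mask = np.ones(L, dtype=bool)
            noncoding_mask[cpos] = False
            self.noncoding_positions = np.flatnonzero(noncoding_mask)
        self.mutable_positions = cpos if self.coding_only else None
        self.mutable_bp = len(cpos) if self.coding_only else L

    def n_pairs(self, eff_code: int) -> int:
        if eff_code == NONCODING:
            return self.n_noncoding_pairs
        return len(self.pairs_by_class[eff_code][0])

    def sample_pairs(self, eff_code: int, n: int, rng: np.random.Generator):
        """n distinct (position, alt) pairs of the given class."""
        if eff_code == NONCODING:
            # distinct positions is enough (3 alts per position)
            pos = rng.choice(self.noncoding_positions, size=n, replace=False)
            ref = self.layout.seq_codes[pos]
            alt = (ref + rng.integers(1, 4, size=n)) % 4
            return pos.astype(np.int64), alt.astype(np.uint8)
        pool_pos, pool_alt = self.pairs_by_class[eff_code]
        idx = rng.choice(len(pool_pos), size=n, replace=False)
        return pool_pos[idx].astype(np.int64), pool_alt[idx]

    def effect_of(self, pos: np.ndarray, alt: np.ndarray) -> np.ndarray:
        eff = np.full(len(pos), NONCODING, dtype=np.int8)
        for k, (p, a) in enumerate(zip(pos, alt)):
            i = self.pos_index.get(int(p))
            if i is not None:
                eff[k] = self.coding_eff[i, int(a)]
        return eff


def _init_equilibrium(
    catalog: _ClassCatalog,
    config: SimulationConfig,
    K: int,
    s_vals: np.ndarray,
    s_probs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, _Sites]:
    """Ancestral population at mutation-selection-drift stationarity."""
    mu = config.mu
    h = config.dominance_h
    per_pair_influx = K * mu / 3.0

    all_pos, all_alt, all_eff, all_s, all_count = [], [], [], [], []

    def draw_class(eff_code: int, s_value: float, influx: float):
        f = _wf_stationary(K, s_value, h) * influx
        counts_per_class = rng.poisson(f)
        total = int(counts_per_class.sum())
        if total == 0:
            return
        total = min(total, catalog.n_pairs(eff_code))
        derived = np.repeat(np.arange(1, K), counts_per_class)[:total]
        pos, alt = catalog.sample_pairs(eff_code, total, rng)
        all_pos.append(pos)
        all_alt.append(alt)
        all_eff.append(np.full(total, eff_code, dtype=np.int8))
        all_s.append(np.full(total, s_value))
        all_count.append(derived)

    # neutral classes: noncoding and synonymous
    for eff_code in (0, 1):
        influx = per_pair_influx * catalog.n_pairs(eff_code)
        if influx > 0:
            draw_class(eff_code, 0.0, influx)
    # selected classes: missense and nonsense share the DFE
    for eff_code in (2, 3):
        n_pairs = catalog.n_pairs(eff_code)
        if n_pairs == 0:
            continue
        for sv, pb in zip(s_vals, s_probs):
            influx = per_pair_influx * n_pairs * pb
            draw_class(eff_code, float(sv), influx)

    if not all_pos:
        sites = _Sites(
            np.empty(0, np.int64), np.empty(0, np.uint8), np.empty(0, np.int8), np.empty(0)
        )
        return np.zeros((K, 0), np.uint8), sites
    sites = _Sites(
        np.concatenate(all_pos),
        np.concatenate(all_alt),
        np.concatenate(all_eff),
        np.concatenate(all_s),
    )
    counts = np.concatenate(all_count)
    # deduplicate positions across classes (infinite-sites bookkeeping)
    _, first = np.unique(sites.positions, return_index=True)
    sites = sites.take(first)
    counts = counts[first]
    order = sites.order()
    sites = sites.take(order)
    counts = counts[order]
    H = _assign_equilibrium_haplotypes(counts, K, rng)
    return H, sites


def _fitness(
    H: np.ndarray, sel_cols: np.ndarray, s: np.ndarray, h: float | np.ndarray
) -> np.ndarray:
    """Multiplicative viability per diploid individual; h may be a per-site
    dominance array (the injected beneficial allele keeps its own h)."""
    n_ind = H.shape[0] // 2
    if len(sel_cols) == 0:
        return np.ones(n_ind)
    G = (H[0::2][:, sel_cols].astype(np.int16) + H[1::2][:, sel_cols]).astype(np.int8)
    ss = s[sel_cols]
    hh = h[sel_cols] if isinstance(h, np.ndarray) else h
    log_het = np.log(np.maximum(1.0 - hh * ss, 1e-12))
    log_hom = np.log(np.maximum(1.0 - ss, 1e-12))
    logw = (G == 1) @ log_het + (G == 2) @ log_hom
    logw -= logw.max()
    return np.exp(logw)


def _reproduce(
    H: np.ndarray,
    pop_slices: list[slice],
    new_sizes: list[int],
    mig: np.ndarray,
    positions: np.ndarray,
    rec_rate: float,
    L: int,
    w_by_pop: list[np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[slice]]:
    """One round of migration + fitness-weighted mating + recombination."""
    n_pops = len(pop_slices)
    child_slices = []
    offset = 0
    for Np in new_sizes:
        child_slices.append(slice(offset, offset + 2 * Np))
        offset += 2 * Np
    G_tot = offset
    S = H.shape[1]
    parent_ind_offsets = [sl.start // 2 for sl in pop_slices]
    n_par = [(sl.stop - sl.start) // 2 for sl in pop_slices]
    probs = [w / w.sum() if w.sum() > 0 else None for w in w_by_pop]
    parent_of = np.empty(G_tot, dtype=np.int64)
    for p in range(n_pops):
        Np = new_sizes[p]
        if Np == 0:
            continue
        src = np.full(Np, p)
        if n_pops == 2 and mig[p] > 0:
            src[rng.random(Np) < mig[p]] = 1 - p
        base = child_slices[p].start
        for q in range(n_pops):
            take = np.flatnonzero(src == q)
            if len(take) == 0:
                continue
            if probs[q] is None:
                raise RuntimeError(f"population {q + 1} has zero total fitness")
            par = parent_ind_offsets[q] + rng.choice(
                n_par[q], size=2 * len(take), p=probs[q]
            )
            slots = np.empty(2 * len(take), dtype=np.int64)
            slots[0::2] = base + 2 * take
            slots[1::2] = base + 2 * take + 1
            parent_of[slots] = par
    # recombination choice matrix
    start = rng.integers(0, 2, size=G_tot, dtype=np.int8)
    lam = rec_rate * L
    n_x = rng.poisson(lam, size=G_tot)
    tot_x = int(n_x.sum())
    # int8 is safe here: parity only needs the crossover count mod 2 and the
    # mod-256 wraparound preserves it
    C = np.zeros((G_tot, S + 1), dtype=np.int8)
    if tot_x > 0 and S > 0:
        gidx = np.repeat(np.arange(G_tot), n_x)
        xpos = rng.integers(0, L, size=tot_x)
        sidx = np.searchsorted(positions, xpos)
        np.add.at(C, (gidx, sidx), 1)
    parity = (start[:, None] + np.cumsum(C[:, :-1], axis=1)) % 2
    hapA = H[2 * parent_of]
    hapB = H[2 * parent_of + 1]
    newH = np.where(parity == 0, hapA, hapB).astype(np.uint8)
    return newH, child_slices


def _mutate(
    H: np.ndarray,
    sites: _Sites,
    catalog: _ClassCatalog,
    config: SimulationConfig,
    s_vals: np.ndarray,
    s_probs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, _Sites]:
    G_tot, S = H.shape
    n_new = rng.poisson(G_tot * config.mu * catalog.mutable_bp)
    if n_new == 0:
        return H, sites
    if catalog.mutable_positions is not None:
        pos = rng.choice(catalog.mutable_positions, size=n_new).astype(np.int64)
    else:
        pos = rng.integers(0, catalog.layout.length, size=n_new).astype(np.int64)
    existing = set(sites.positions.tolist())
    keep = np.array(
        [p not in existing for p in pos], dtype=bool
    )
    pos, uniq_idx = np.unique(pos[keep], return_index=True)
    n_new = len(pos)
    if n_new == 0:
        return H, sites
    ref = catalog.layout.seq_codes[pos]
    alt = ((ref + rng.integers(1, 4, size=n_new)) % 4).astype(np.uint8)
    eff = catalog.effect_of(pos, alt)
    s = np.zeros(n_new)
    sel = eff >= MISSENSE
    if sel.any() and len(s_vals) > 0:
        s[sel] = rng.choice(s_vals, size=int(sel.sum()), p=s_probs)
    carriers = rng.integers(0, G_tot, size=n_new)
    block = np.zeros((G_tot, n_new), dtype=np.uint8)
    block[carriers, np.arange(n_new)] = 1
    H = np.concatenate([H, block], axis=1)
    sites = _Sites.concat(sites, _Sites(pos, alt, eff, s))
    order = sites.order()
    return H[:, order], sites.take(order)


def _prune(H: np.ndarray, sites: _Sites) -> tuple[np.ndarray, _Sites]:
    tot = H.sum(axis=0, dtype=np.int64)
    keep = (tot > 0) & (tot < H.shape[0])
    if keep.all():
        return H, sites
    return np.ascontiguousarray(H[:, keep]), sites.take(keep)


def simulate_two_population(config: SimulationConfig) -> SimulatedDataset:
    """Run the full forward simulation described in the module docstring."""
    config.validate()
    root = np.random.SeedSequence([int(config.seed), 202])
    rng_init, rng_fwd, rng_out, rng_samp = [
        np.random.default_rng(s) for s in root.spawn(4)
    ]
    layout = build_genome_layout(config)
    catalog = _ClassCatalog(layout, config)
    dem = config.demography
    s_vals, s_probs = discretize_gamma(
        config.dfe_shape, config.dfe_mean_s, config.dfe_bins
    )

    N_anc = int(round(dem.N_anc))
    K_anc = 2 * N_anc
    H, sites = _init_equilibrium(catalog, config, K_anc, s_vals, s_probs, rng_init)
    pop_slices = [slice(0, K_anc)]
    sweep_h = config.sweep.h if config.sweep is not None else 0.5

    def h_of(sites):
        # beneficial (negative-s) sites carry the sweep's own dominance
        return np.where(sites.s < 0, sweep_h, config.dominance_h)

    def step(H, sites, pop_slices, new_sizes, mig, rng):
        w_by_pop = [
            _fitness(
                H[sl], np.flatnonzero(sites.s != 0.0), sites.s, h_of(sites)
            )
            for sl in pop_slices
        ]
        H, slices = _reproduce(
            H,
            pop_slices,
            new_sizes,
            mig,
            sites.positions,
            config.rec_rate,
            layout.length,
            w_by_pop,
            rng,
        )
        H, sites = _mutate(H, sites, catalog, config, s_vals, s_probs, rng)
        H, sites = _prune(H, sites)
        return H, sites, slices

    # optional pre-split burn-in in the ancestral population
    for _ in range(int(config.burnin_generations)):
        H, sites, pop_slices = step(
            H, sites, pop_slices, [N_anc], np.zeros(1), rng_fwd
        )

    t_split = int(round(dem.t_split))
    if t_split > 0:
        # the split generation: the ancestral pool parents both daughters
        sizes_at = lambda t: [
            max(2, int(round(dem.size_at(1, t)))),
            max(2, int(round(dem.size_at(2, t)))),
        ]
        first = sizes_at(t_split - 1) if t_split > 1 else sizes_at(0)
        w_anc = _fitness(
            H[pop_slices[0]], np.flatnonzero(sites.s != 0.0), sites.s, h_of(sites)
        )
        H, pop_slices = _reproduce(
            H,
            [pop_slices[0], pop_slices[0]],
            first,
            np.zeros(2),
            sites.positions,
            config.rec_rate,
            layout.length,
            [w_anc, w_anc],
            rng_fwd,
        )
        H, sites = _mutate(H, sites, catalog, config, s_vals, s_probs, rng_fwd)
        H, sites = _prune(H, sites)

        swept_position = None
        if config.sweep is not None:
            H, sites, swept_position = _inject_sweep(
                H, sites, pop_slices, catalog, config, rng_fwd
            )

        mig = np.array([dem.m12, dem.m21])
        for t in range(t_split - 1, 0, -1):
            new_sizes = sizes_at(t - 1)
            for p, n in enumerate(new_sizes):
                if n < 2:
                    raise RuntimeError(
                        f"population {p + 1} went extinct at {t - 1} generations"
                        " before present"
                    )
            H, sites, pop_slices = step(H, sites, pop_slices, new_sizes, mig, rng_fwd)
    else:
        swept_position = None

    return _finalize(
        H, sites, pop_slices, layout, catalog, config, swept_position, rng_out, rng_samp
    )


def _inject_sweep(H, sites, pop_slices, catalog, config, rng):
    sw = config.sweep
    pos = sw.position
    if pos is None:
        pool_pos, pool_alt = catalog.pairs_by_class[MISSENSE]
        if len(pool_pos) == 0:
            raise ValueError("sweep injection needs a missense-capable coding site")
        mid = catalog.layout.length // 2
        free = ~np.isin(pool_pos, sites.positions)
        cand_pos, cand_alt = pool_pos[free], pool_alt[free]
        k = int(np.argmin(np.abs(cand_pos - mid)))
        pos, alt = int(cand_pos[k]), cand_alt[k]
    else:
        pos = int(pos)
        if np.isin(pos, sites.positions):
            raise ValueError("sweep position already segregating")
        ref = catalog.layout.seq_codes[pos]
        alt = np.uint8((ref + 1) % 4)
    eff = catalog.effect_of(np.array([pos]), np.array([alt]))[0]
    col = np.zeros((H.shape[0], 1), dtype=np.uint8)
    sl = pop_slices[sw.population - 1]
    k_pop = sl.stop - sl.start
    n_carriers = max(1, int(round(sw.start_freq * k_pop)))
    rows = sl.start + rng.choice(k_pop, size=n_carriers, replace=False)
    # hard sweep: every copy at the post-establishment frequency descends
    # from a single founder haplotype, so the carriers share the founder's
    # whole background (recombination erodes it during the sweep)
    founder = rows[0]
    H[rows[1:], :] = H[founder, :]
    col[rows, 0] = 1
    H = np.concatenate([H, col], axis=1)
    new = _Sites(
        np.array([pos], dtype=np.int64),
        np.array([alt], dtype=np.uint8),
        np.array([eff], dtype=np.int8),
        np.array([-abs(sw.s)]),
    )
    sites = _Sites.concat(sites, new)
    order = sites.order()
    return H[:, order], sites.take(order), pos


def _finalize(H, sites, pop_slices, layout, catalog, config, swept_position, rng_out, rng_samp):
    # sample diploids per population
    sample_cols = []
    populations = []
    sample_ids = []
    pop_names = ["wild", "domestic"]
    n_pops_present = len(pop_slices)
    for p, n_dip in enumerate(config.sample_sizes):
        if n_dip == 0:
            continue
        if p >= n_pops_present:
            raise ValueError("sample requested from a population that does not exist")
        sl = pop_slices[p]
        n_avail = (sl.stop - sl.start) // 2
        pick = np.sort(rng_samp.choice(n_avail, size=n_dip, replace=False))
        for j, ind in enumerate(pick):
            sample_cols.extend([sl.start + 2 * ind, sl.start + 2 * ind + 1])
            sample_ids.append(f"{pop_names[p][0]}{j + 1}")
            populations.append(pop_names[p])
    Hs = H[sample_cols]
    tot = Hs.sum(axis=0, dtype=np.int64)
    seg = (tot > 0) & (tot < Hs.shape[0])
    Hs = Hs[:, seg]
    fsites = sites.take(seg)

    # outgroup: fixed differences on an independent branch
    L = layout.length
    n_subs = rng_out.poisson(config.outgroup_divergence * L)
    og_pos = np.unique(rng_out.integers(0, L, size=n_subs))
    og_base = (
        layout.seq_codes[og_pos] + rng_out.integers(1, 4, size=len(og_pos))
    ) % 4
    og_allele = layout.seq_codes[fsites.positions].copy()  # default: ancestral
    hit = np.isin(fsites.positions, og_pos)
    if hit.any():
        lookup = dict(zip(og_pos.tolist(), og_base.tolist()))
        og_allele[hit] = [lookup[int(p)] for p in fsites.positions[hit]]
    extra = ~np.isin(og_pos, fsites.positions)
    outgroup_sites = pd.DataFrame(
        {"position": og_pos[extra], "base": og_base[extra].astype(np.uint8)}
    )
    n_og = config.n_outgroup
    og_row = np.where(og_allele == fsites.alt, 2, 0).astype(np.int8)
    og_geno = np.tile(og_row, (n_og, 1))

    truth = {
        "config": config.truth_dict(),
        "seed": int(config.seed),
        "swept_position": None if swept_position is None else int(swept_position),
        "n_segregating": int(Hs.shape[1]),
    }
    base_lut = np.array(list("ACGT"))
    sites_df = pd.DataFrame(
        {
            "position": fsites.positions,
            "ancestral": base_lut[layout.seq_codes[fsites.positions]],
            "derived": base_lut[fsites.alt],
            "effect": [EFFECT_NAMES[int(e)] for e in fsites.effect],
            "s": fsites.s,
        }
    )
    return SimulatedDataset(
        haplotypes=np.ascontiguousarray(Hs.T),
        sites=sites_df,
        sample_ids=sample_ids,
        populations=populations,
        outgroup_ids=[f"og{k + 1}" for k in range(n_og)],
        outgroup_genotypes=og_geno,
        outgroup_alleles=og_allele,
        outgroup_sites=outgroup_sites,
        layout=layout,
        truth=truth,
    )
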