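"""Deterministic engine for the expected two-population joint SFS.

The engine integrates a closed system of ordinary differential equations for
the entries of the *sample* joint site-frequency spectrum Phi[i, j], the
expected number of segregating sites whose derived allele is carried by i of
n1 sampled chromosomes in population 1 and j of n2 in population 2.  Time is
measured in units of 2*Nref generations and population sizes nu are relative
to the reference (ancestral) size; theta = 4*Nref*mu*L is profiled out, so
the engine always works at unit theta.

Under the Wright-Fisher diffusion the genetic-drift term closes exactly at
sample order n: with B(n,i;x) the binomial kernel, x(1-x) B''(n,i;x) is a
tridiagonal combination of B(n,i-1), B(n,i), B(n,i+1).  Migration couples the
two frequencies through E[x2 * .] terms which require one extra sampled
chromosome in the source population; that extra order is closed with a
quadratic jackknife (exact whenever the underlying frequency density is
locally quadratic).  New mutations enter as a constant source on the
single-copy entries.  The resulting linear ODE is integrated with
Crank-Nicolson steps.

A Monte-Carlo coalescent engine (branch-length averaging over simulated
ancestries) is available as an independent alternative; it requires msprime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.special import betaln, gammaln

__all__ = [
    "EngineConfig",
    "expected_sfs_from_epochs",
    "split_equilibrium",
    "equilibrium_1d",
    "jackknife_up",
    "projection_down",
]


@dataclass(frozen=True)
class EngineConfig:
    """Numerical settings for the deterministic engine.

    dt_max: largest Crank-Nicolson step, in 2*Nref-generation units.
    min_steps: minimum number of steps per demographic epoch.
    """

    dt_max: float = 0.01
    min_steps: int = 12


def _log_comb(n: int, k) -> np.ndarray:
    return gammaln(n + 1) - gammaln(np.asarray(k) + 1) - gammaln(n - np.asarray(k) + 1)


def _poly_moment(n: int, j, p: int) -> np.ndarray:
    """E-contribution of f(x)=x^p to Phi_n[j]: C(n,j) * Beta(j+p+1, n-j+1)."""
    j = np.asarray(j, dtype=float)
    return np.exp(_log_comb(n, j) + betaln(j + p + 1, n - j + 1))


@lru_cache(maxsize=None)
def jackknife_up(n: int) -> np.ndarray:
    """(n+2, n+1) matrix J with Phi_{n+1} ~= J @ Phi_n.

    Weights use three consecutive source entries and are exact for
    underlying densities in span{1, x, x^2}.
    """
    if n < 2:
        raise ValueError("jackknife closure requires sample size >= 2")
    J = np.zeros((n + 2, n + 1))
    for ip in range(n + 2):
        jstar = ip * n / (n + 1)
        j0 = int(np.clip(round(jstar) - 1, 0, n - 2))
        js = np.arange(j0, j0 + 3)
        A = np.array([_poly_moment(n, js, p) for p in range(3)])
        b = np.array([float(_poly_moment(n + 1, ip, p)) for p in range(3)])
        J[ip, js] = np.linalg.solve(A, b)
    return J


@lru_cache(maxsize=None)
def projection_down(n: int) -> np.ndarray:
    """(n, n+1) hypergeometric projection from sample size n to n-1 (exact)."""
    P = np.zeros((n, n + 1))
    i = np.arange(n)
    P[i, i] = (n - i) / n
    P[i, i + 1] = (i + 1) / n
    return P


@lru_cache(maxsize=None)
def _drift_matrix(n: int) -> np.ndarray:
    """Tridiagonal drift operator at sample size n (time unit 2*Nref gens).

    d Phi_i/dt = (1/(2 nu)) * [ (i-1)(n-i+1) Phi_{i-1} - 2 i (n-i) Phi_i
                                + (i+1)(n-i-1) Phi_{i+1} ]
    The stationary state with the mutation source is Phi_i = theta*nu/i.
    """
    D = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        if i >= 1:
            D[i, i - 1] = (i - 1) * (n - i + 1)
        D[i, i] = -2 * i * (n - i)
        if i + 1 <= n:
            D[i, i + 1] = (i + 1) * (n - i - 1)
    return D


@lru_cache(maxsize=None)
def _operators(n1: int, n2: int):
    """Precompute the parameter-independent building blocks at (n1, n2).

    Returns dict with flattened (K x K) matrices, K = (n1+1)(n2+1):
      D1, D2   : drift in each population (to be scaled by 1/(2 nu));
      M12, M21 : migration operators (to be scaled by 2*Nref*m);
      source   : mutation influx vector at unit theta.
    """
    I1 = np.eye(n1 + 1)
    I2 = np.eye(n2 + 1)
    D1 = np.kron(_drift_matrix(n1), I2)
    D2 = np.kron(I1, _drift_matrix(n2))

    def migration_op(na: int, nb: int):
        # Population a receives migrants from population b, a indexed on
        # axis 0 of the (na+1, nb+1) spectrum.
        # term1: na * (j+1)/(nb+1) * (Psi[i-1, j+1] - Psi[i, j+1]),
        #        Psi = Phi at (na-1, nb+1)  [project a down, jackknife b up]
        # term2: -i Phi[i,j] + (i+1) Phi[i+1,j]
        R = np.zeros((na + 1, na))  # Psi[i-1] - Psi[i] along axis a
        for i in range(na + 1):
            if i >= 1:
                R[i, i - 1] = 1.0
            if i <= na - 1:
                R[i, i] = -1.0
        C = np.zeros((nb + 1, nb + 2))  # select column j+1, weight (j+1)
        for j in range(nb + 1):
            C[j, j + 1] = na * (j + 1) / (nb + 1)
        A0 = R @ projection_down(na)          # (na+1, na+1)
        A1 = C @ jackknife_up(nb)             # (nb+1, nb+1)
        T2 = np.zeros((na + 1, na + 1))
        for i in range(na + 1):
            T2[i, i] = -i
            if i + 1 <= na:
                T2[i, i + 1] = i + 1
        return np.kron(A0, A1) + np.kron(T2, np.eye(nb + 1))

    M12 = migration_op(n1, n2)

    # Mirror for population 2 receiving from population 1: build in the
    # transposed layout then permute axes back.
    M21_t = migration_op(n2, n1)
    K = (n1 + 1) * (n2 + 1)
    perm = np.arange(K).reshape(n1 + 1, n2 + 1).T.ravel()
    Pm = np.zeros((K, K))
    Pm[np.arange(K), perm] = 1.0
    M21 = Pm.T @ M21_t @ Pm

    source = np.zeros((n1 + 1, n2 + 1))
    source[1, 0] = n1 / 2.0
    source[0, 1] = n2 / 2.0
    return {"D1": D1, "D2": D2, "M12": M12, "M21": M21, "source": source.ravel()}


def equilibrium_1d(n: int, nu: float = 1.0, theta: float = 1.0) -> np.ndarray:
    """Stationary single-population sample SFS: Phi_i = theta*nu/i."""
    phi = np.zeros(n + 1)
    i = np.arange(1, n + 1)
    phi[i] = theta * nu / i
    return phi


def split_equilibrium(n1: int, n2: int, nu_anc: float = 1.0, theta: float = 1.0) -> np.ndarray:
    """Joint sample SFS at the instant of a clean split.

    Both populations carry the same ancestral frequency x, drawn from the
    stationary density f(x) = theta*nu_anc/x, so
    Phi[i, j] = theta*nu_anc * C(n1,i) C(n2,j) * Beta(i+j, n1+n2-i-j+1).
    """
    phi = np.zeros((n1 + 1, n2 + 1))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            k = i + j
            if k == 0 or k == n1 + n2 + 1:
                continue
            if k >= n1 + n2 + 1:
                continue
            lo = (
                _log_comb(n1, i)
                + _log_comb(n2, j)
                + betaln(k, n1 + n2 - k + 1)
            )
            phi[i, j] = theta * nu_anc * np.exp(lo)
    phi[0, 0] = 0.0
    return phi


def expected_sfs_from_epochs(
    n1: int,
    n2: int,
    epochs: list[tuple[float, float, float, float, float]],
    m12: float = 0.0,
    m21: float = 0.0,
    nu_anc: float = 1.0,
    config: EngineConfig | None = None,
) -> np.ndarray:
    """Integrate the joint-SFS ODE forward from a clean split.

    epochs: list of (duration T, nu1_start, nu1_end, nu2_start, nu2_end),
      ordered past -> present; sizes interpolate linearly within an epoch.
    m12, m21: scaled migration rates 2*Nref*m (m12 = fraction of population 1
      replaced by migrants from population 2 per generation, scaled).

    Returns the (n1+1, n2+1) expected spectrum at unit theta.
    """
    config = config or EngineConfig()
    ops = _operators(n1, n2)
    K = (n1 + 1) * (n2 + 1)
    phi = split_equilibrium(n1, n2, nu_anc=nu_anc).ravel().copy()
    src = ops["source"]
    Mconst = m12 * ops["M12"] + m21 * ops["M21"]
    eye = np.eye(K)

    for T, nu1_0, nu1_1, nu2_0, nu2_1 in epochs:
        if T <= 0:
            continue
        if min(nu1_0, nu1_1, nu2_0, nu2_1) <= 0:
            raise ValueError("population sizes must be positive")
        nsteps = max(config.min_steps, int(np.ceil(T / config.dt_max)))
        dt = T / nsteps
        constant = nu1_0 == nu1_1 and nu2_0 == nu2_1
        lu = None
        for step in range(nsteps):
            tm = (step + 0.5) / nsteps
            nu1 = nu1_0 + (nu1_1 - nu1_0) * tm
            nu2 = nu2_0 + (nu2_1 - nu2_0) * tm
            A = ops["D1"] / (2 * nu1) + ops["D2"] / (2 * nu2) + Mconst
            rhs = phi + 0.5 * dt * (A @ phi) + dt * src
            if constant:
                if lu is None:
                    lu = lu_factor(eye - 0.5 * dt * A)
                phi = lu_solve(lu, rhs)
            else:
                phi = np.linalg.solve(eye - 0.5 * dt * A, rhs)

    out = phi.reshape(n1 + 1, n2 + 1)
    out[0, 0] = 0.0
    out[n1, n2] = 0.0
    return np.maximum(out, 0.0)


def expected_sfs_coalescent(
    n1: int,
    n2: int,
    epochs: list[tuple[float, float, float, float, float]],
    m12: float = 0.0,
    m21: float = 0.0,
    nu_anc: float = 1.0,
    n_reps: int = 200,
    seed: int | None = None,
    nref: float = 5000.0,
) -> np.ndarray:
    """Monte-Carlo engine: average branch-mode joint AFS over coalescent
    simulations (requires msprime).  Linear size changes are approximated by
    piecewise-constant steps.  Returned at unit theta, same layout/masking as
    the deterministic engine.
    """
    try:
        import msprime
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "the coalescent engine requires msprime; install domcost[test]"
        ) from exc

    # Haploid bookkeeping: a population of relative size nu is represented by
    # 2*nref*nu haploid genomes; 1 time unit = 2*nref generations.
    dem = msprime.Demography()
    unit = 2.0 * nref

    # Build backward-in-time size histories from the forward epoch list.
    t_total = sum(e[0] for e in epochs)

    def size_at(tback: float, pop_idx: int) -> float:
        # tback: time before present in units of 2*Nref generations
        tfwd = t_total - tback
        acc = 0.0
        for T, a0, a1, b0, b1 in epochs:
            if tfwd <= acc + T or np.isclose(tfwd, acc + T):
                frac = np.clip((tfwd - acc) / T, 0.0, 1.0) if T > 0 else 1.0
                if pop_idx == 0:
                    return a0 + (a1 - a0) * frac
                return b0 + (b1 - b0) * frac
            acc += T
        if pop_idx == 0:
            return epochs[0][1]
        return epochs[0][3]

    dem.add_population(name="P1", initial_size=unit * size_at(0.0, 0))
    dem.add_population(name="P2", initial_size=unit * size_at(0.0, 1))
    dem.add_population(name="ANC", initial_size=unit * nu_anc)
    # piecewise-constant approximation of the size paths
    nslices = 16
    for k in range(1, nslices):
        tb = t_total * k / nslices
        dem.add_population_parameters_change(
            time=tb * unit, population="P1", initial_size=unit * size_at(tb, 0)
        )
        dem.add_population_parameters_change(
            time=tb * unit, population="P2", initial_size=unit * size_at(tb, 1)
        )
    if m12 > 0:
        dem.set_migration_rate(source="P1", dest="P2", rate=m12 / unit)
    if m21 > 0:
        dem.set_migration_rate(source="P2", dest="P1", rate=m21 / unit)
    dem.add_population_split(time=t_total * unit, derived=["P1", "P2"], ancestral="ANC")
    dem.sort_events()

    rng = np.random.default_rng(seed)
    acc = np.zeros((n1 + 1, n2 + 1))
    for _ in range(n_reps):
        ts = msprime.sim_ancestry(
            samples=[
                msprime.SampleSet(n1, population="P1", ploidy=1),
                msprime.SampleSet(n2, population="P2", ploidy=1),
            ],
            demography=dem,
            ploidy=1,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        afs = ts.allele_frequency_spectrum(
            sample_sets=[ts.samples(population=0), ts.samples(population=1)],
            mode="branch",
            span_normalise=True,
            polarised=True,
        )
        acc += afs
    acc /= n_reps
    # branch lengths are in generations; unit theta corresponds to
    # mu*L = 1/(4*nref)
    out = acc / (4.0 * nref)
    out[0, 0] = 0.0
    out[n1, n2] = 0.0
    return out
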