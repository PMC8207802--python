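"""Windowed diversity/differentiation statistics and selective-sweep calls.

Per-site nucleotide diversity uses the unbiased estimator
2*a*(n-a)/(n*(n-1)) for a derived alleles among n called; window pi divides
the summed site pi by the full window length (matching the conventional
--window-pi behaviour), with sliding windows (default 50 kb window, 25 kb
step).  FST is Hudson's estimator combined across sites as a ratio of
averages.  LSBL (locus-specific branch length) isolates the focal branch
from three pairwise distances: (d_AB + d_AC - d_BC)/2, floored at zero.
The pi-ratio pi_wild/pi_domestic flags diversity loss in the domestic
lineage.  Sweep regions are windows above an empirical quantile of a chosen
statistic, merged when overlapping or adjacent; the hSNP-in-sweep contrast
compares hSNP density and derived-allele frequency inside versus outside
sweeps against a null of randomly relocated sweep regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "site_pi",
    "windowed_pi",
    "site_fst",
    "window_fst",
    "lsbl",
    "scan_windows",
    "SweepSet",
    "call_sweeps",
    "SweepContrast",
    "sweep_load_contrast",
]


def site_pi(derived: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Per-site pi: expected pairwise difference among called alleles."""
    a = np.asarray(derived, float)
    n = np.asarray(called, float)
    out = np.zeros_like(a, dtype=float)
    ok = n >= 2
    out[ok] = 2.0 * a[ok] * (n[ok] - a[ok]) / (n[ok] * (n[ok] - 1.0))
    return out


def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    if length < window:
        return np.array([0], dtype=int) if length > 0 else np.array([], dtype=int)
    return np.arange(0, length - window + 1, step, dtype=int)


def windowed_pi(
    positions: np.ndarray,
    derived: np.ndarray,
    called: np.ndarray,
    contig_length: int,
    window: int = 50_000,
    step: int = 25_000,
) -> pd.DataFrame:
    """Sliding-window pi per bp; the denominator is the window length."""
    pis = site_pi(derived, called)
    starts = _window_starts(contig_length, window, step)
    rows = []
    pos = np.asarray(positions)
    for s in starts:
        e = min(s + window, contig_length)
        in_win = (pos >= s) & (pos < e)
        rows.append(
            {"start": int(s), "end": int(e), "n_sites": int(in_win.sum()),
             "pi": pis[in_win].sum() / window}
        )
    return pd.DataFrame(rows)


def site_fst(
    derived1: np.ndarray,
    called1: np.ndarray,
    derived2: np.ndarray,
    called2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson FST per-site numerator and denominator.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)
    Combine across sites as sum(num)/sum(den) (ratio of averages).
    """
    d1 = np.asarray(derived1, float)
    n1 = np.asarray(called1, float)
    d2 = np.asarray(derived2, float)
    n2 = np.asarray(called2, float)
    ok = (n1 >= 2) & (n2 >= 2)
    num = np.zeros(len(d1))
    den = np.zeros(len(d1))
    if len(d1) and not ok.any():
        raise ValueError("Hudson FST needs at least 2 called alleles per population")
    p1 = np.divide(d1, n1, out=np.zeros_like(d1), where=ok)
    p2 = np.divide(d2, n2, out=np.zeros_like(d2), where=ok)
    with np.errstate(divide="ignore", invalid="ignore"):
        num[ok] = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )[ok]
    den[ok] = (p1 * (1 - p2) + p2 * (1 - p1))[ok]
    return num, den


def window_fst(num: np.ndarray, den: np.ndarray) -> float:
    """Ratio-of-averages window FST, clamped to [0, 1]; NaN when the
    denominator vanishes (both populations monomorphic and identical)."""
    dsum = float(np.sum(den))
    if dsum == 0.0:
        return np.nan
    return float(np.clip(np.sum(num) / dsum, 0.0, 1.0))


def lsbl(fst_ab: float, fst_ac: float, fst_bc: float) -> float:
    """Branch length specific to population A, floored at zero."""
    return max(0.0, (fst_ab + fst_ac - fst_bc) / 2.0)


def scan_windows(
    positions: np.ndarray,
    counts: dict[str, tuple[np.ndarray, np.ndarray]],
    contig_length: int,
    focal: str,
    sister: str,
    outgroup: str | None = None,
    window: int = 50_000,
    step: int = 25_000,
) -> pd.DataFrame:
    """Per-window pi (both populations), pairwise Hudson FST, LSBL of the
    focal population, and pi-ratio sister/focal.

    counts maps population name -> (derived, called) per-site arrays.
    """
    pos = np.asarray(positions)
    starts = _window_starts(contig_length, window, step)
    pis = {p: site_pi(*counts[p]) for p in counts}
    pairs = [(focal, sister)]
    if outgroup is not None:
        pairs += [(focal, outgroup), (sister, outgroup)]
    fst_site = {pair: site_fst(*counts[pair[0]], *counts[pair[1]]) for pair in pairs}
    rows = []
    for s in starts:
        e = min(s + window, contig_length)
        w = (pos >= s) & (pos < e)
        row = {"start": int(s), "end": int(e), "n_sites": int(w.sum())}
        for p in counts:
            row[f"pi_{p}"] = pis[p][w].sum() / window
        for pair, (num, den) in fst_site.items():
            row[f"fst_{pair[0]}_{pair[1]}"] = window_fst(num[w], den[w])
        if outgroup is not None:
            row["lsbl"] = lsbl(
                row[f"fst_{focal}_{sister}"],
                row[f"fst_{focal}_{outgroup}"],
                row[f"fst_{sister}_{outgroup}"],
            ) if np.all(np.isfinite([
                row[f"fst_{focal}_{sister}"],
                row[f"fst_{focal}_{outgroup}"],
                row[f"fst_{sister}_{outgroup}"],
            ])) else np.nan
        pf = row[f"pi_{focal}"]
        row["pi_ratio"] = row[f"pi_{sister}"] / pf if pf > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SweepSet:
    statistic: str
    quantile: float
    threshold: float
    regions: list[tuple[int, int]] = field(default_factory=list)

    def total_bp(self) -> int:
        return sum(b - a for a, b in self.regions)

    def contains(self, positions: np.ndarray) -> np.ndarray:
        out = np.zeros(len(positions), dtype=bool)
        for a, b in self.regions:
            out |= (positions >= a) & (positions < b)
        return out


def call_sweeps(
    windows: pd.DataFrame, statistic: str, quantile: float = 0.99
) -> SweepSet:
    """Select windows at or above the empirical quantile of the statistic
    and merge overlapping/adjacent selections."""
    vals = windows[statistic].to_numpy(float)
    ok = np.isfinite(vals)
    if ok.sum() == 0:
        raise ValueError(f"statistic {statistic} is missing in every window")
    if ok.sum() < 10:
        raise ValueError("need at least 10 non-missing windows to call sweeps")
    thr = float(np.quantile(vals[ok], quantile))
    sel = windows.loc[ok & (vals >= thr), ["start", "end"]].sort_values("start")
    regions: list[list[int]] = []
    for a, b in sel.itertuples(index=False):
        if regions and a <= regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], b)
        else:
            regions.append([int(a), int(b)])
    return SweepSet(statistic, quantile, thr, [(a, b) for a, b in regions])


@dataclass
class SweepContrast:
    density_inside: float   # hSNPs per Mb
    density_outside: float
    freq_inside: dict[str, float]
    freq_outside: dict[str, float]
    p_density: float
    p_freq: dict[str, float]
    n_permutations: int
    seed: int | None
    degenerate: bool = False


def _relocate(regions, contig_length: int, rng) -> list[tuple[int, int]]:
    out = []
    for a, b in regions:
        ln = b - a
        if ln >= contig_length:
            out.append((0, contig_length))
            continue
        s = int(rng.integers(0, contig_length - ln))
        out.append((s, s + ln))
    return out


def sweep_load_contrast(
    sweeps: SweepSet,
    hsnp_positions: np.ndarray,
    hsnp_freqs: dict[str, np.ndarray],
    contig_length: int,
    n_perm: int = 1000,
    seed: int | None = None,
) -> SweepContrast:
    """hSNP density and derived-allele frequency inside vs outside sweeps,
    with permutation p-values from randomly relocated sweep regions
    (lengths preserved); two-sided empirical p = (k+1)/(n_perm+1)."""
    bp_in = sweeps.total_bp()
    if bp_in == 0:
        raise ValueError("sweep set covers zero bp; contrast undefined")
    bp_out = contig_length - bp_in
    pos = np.asarray(hsnp_positions)
    inside = sweeps.contains(pos)
    degenerate = bp_out == 0
    dens_in = inside.sum() / bp_in * 1e6
    dens_out = (len(pos) - inside.sum()) / bp_out * 1e6 if bp_out else np.nan
    freq_in, freq_out = {}, {}
    for popname, f in hsnp_freqs.items():
        f = np.asarray(f, float)
        freq_in[popname] = float(f[inside].mean()) if inside.any() else np.nan
        freq_out[popname] = float(f[~inside].mean()) if (~inside).any() else np.nan

    rng = np.random.default_rng(seed)
    if degenerate:
        return SweepContrast(
            dens_in, dens_out, freq_in, freq_out, 1.0,
            {p: 1.0 for p in hsnp_freqs}, 0, seed, degenerate=True,
        )
    obs_d = dens_in - dens_out
    obs_f = {
        p: freq_in[p] - freq_out[p] if np.isfinite(freq_in[p]) and np.isfinite(freq_out[p]) else np.nan
        for p in hsnp_freqs
    }
    k_d = 0
    k_f = {p: 0 for p in hsnp_freqs}
    n_f = {p: 0 for p in hsnp_freqs}
    for _ in range(n_perm):
        regs = _relocate(sweeps.regions, contig_length, rng)
        perm = SweepSet(sweeps.statistic, sweeps.quantile, sweeps.threshold, regs)
        bp_i = perm.total_bp()
        ins = perm.contains(pos)
        d = ins.sum() / bp_i * 1e6 - (len(pos) - ins.sum()) / (contig_length - bp_i) * 1e6
        if abs(d) >= abs(obs_d) - 1e-12:
            k_d += 1
        for p, f in hsnp_freqs.items():
            if not np.isfinite(obs_f[p]) or not ins.any() or ins.all():
                continue
            f = np.asarray(f, float)
            df = f[ins].mean() - f[~ins].mean()
            n_f[p] += 1
            if abs(df) >= abs(obs_f[p]) - 1e-12:
                k_f[p] += 1
    p_density = (k_d + 1) / (n_perm + 1)
    p_freq = {
        p: ((k_f[p] + 1) / (n_f[p] + 1)) if n_f[p] else np.nan for p in hsnp_freqs
    }
    return SweepContrast(
        dens_in, dens_out, freq_in, freq_out, p_density, p_freq, n_perm, seed
    )
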