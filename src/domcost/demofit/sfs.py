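"""Joint site-frequency spectra: neutral region masks, observed and expected
spectra.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .engine import EngineConfig, expected_sfs_from_epochs, expected_sfs_coalescent
from .models import DemographicModelSpec

__all__ = ["JointSFS", "build_neutral_mask", "joint_sfs", "expected_sfs"]


@dataclass
class JointSFS:
    """(n1+1) x (n2+1) matrix of site counts by derived allele count.

    The (0,0) and (n1,n2) corners are non-informative (invariant in the
    sample) and are excluded from likelihoods.
    """

    matrix: np.ndarray
    n1: int
    n2: int
    n_regions: int = 0
    total_bp: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("SFS matrix shape does not match sample sizes")
        if np.any(self.matrix < 0):
            raise ValueError("SFS entries must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of entries included in likelihoods."""
        m = np.ones_like(self.matrix, dtype=bool)
        m[0, 0] = False
        m[self.n1, self.n2] = False
        return m

    @property
    def n_sites(self) -> float:
        return float(self.matrix[self.mask].sum())

    def transpose(self) -> "JointSFS":
        return JointSFS(self.matrix.T.copy(), self.n2, self.n1, self.n_regions, self.total_bp)


def _merge_intervals(intervals) -> list[tuple[int, int]]:
    ivs = sorted((int(a), int(b)) for a, b in intervals if b > a)
    out: list[list[int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def build_neutral_mask(
    contig_length: int,
    exclude: list,
    min_len: int = 1000,
) -> tuple[list[tuple[int, int]], int]:
    """Putatively neutral regions: the complement of the excluded intervals
    (coding sequence, repeats, low-complexity masks), keeping pieces of at
    least ``min_len`` bp.

    Returns (regions, total_bp); regions are 0-based half-open and sorted.
    """
    merged = _merge_intervals(exclude)
    regions: list[tuple[int, int]] = []
    cursor = 0
    for a, b in merged:
        a = max(0, min(a, contig_length))
        b = max(0, min(b, contig_length))
        if a - cursor >= min_len:
            regions.append((cursor, a))
        cursor = max(cursor, b)
    if contig_length - cursor >= min_len:
        regions.append((cursor, contig_length))
    total = sum(b - a for a, b in regions)
    if not regions:
        raise ValueError(
            f"no neutral regions of >= {min_len} bp remain; lower min_len"
        )
    return regions, total


def _sites_in_regions(positions: np.ndarray, regions) -> np.ndarray:
    keep = np.zeros(len(positions), dtype=bool)
    if not len(positions):
        return keep
    ordered = sorted(regions)
    starts = np.array([a for a, _ in ordered])
    ends = np.array([b for _, b in ordered])
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    keep[ok] = positions[ok] < ends[idx[ok]]
    return keep


def _project_counts(d: np.ndarray, n: np.ndarray, n_to: int) -> np.ndarray:
    """Hypergeometric projection of per-site (derived, total) counts to a
    fixed sample size; returns (n_sites, n_to+1) probability rows."""
    j = np.arange(n_to + 1)
    return hypergeom.pmf(j[None, :], n[:, None], d[:, None], n_to)


def joint_sfs(
    derived1: np.ndarray,
    called1: np.ndarray,
    derived2: np.ndarray,
    called2: np.ndarray,
    positions: np.ndarray | None = None,
    regions=None,
    polarized: np.ndarray | None = None,
    project_to: tuple[int, int] | None = None,
) -> JointSFS:
    """Tally the observed joint SFS from per-site derived/called allele
    counts in the two populations.

    Default missing-data policy is strict: only sites at which every
    chromosome was called (called == max observed) enter the spectrum.  With
    ``project_to=(n1, n2)`` sites are instead projected down
    hypergeometrically to the requested sizes.
    Unpolarized sites and sites outside ``regions`` are excluded.
    """
    derived1 = np.asarray(derived1, int)
    derived2 = np.asarray(derived2, int)
    called1 = np.asarray(called1, int)
    called2 = np.asarray(called2, int)
    keep = np.ones(len(derived1), dtype=bool)
    if polarized is not None:
        keep &= np.asarray(polarized, bool)
    n_regions, total_bp = 0, 0
    if regions is not None:
        if positions is None:
            raise ValueError("regions given without site positions")
        keep &= _sites_in_regions(np.asarray(positions, int), regions)
        n_regions = len(regions)
        total_bp = sum(b - a for a, b in regions)

    d1, c1, d2, c2 = derived1[keep], called1[keep], derived2[keep], called2[keep]
    if project_to is None:
        n1 = int(called1.max(initial=0))
        n2 = int(called2.max(initial=0))
        if n1 == 0 or n2 == 0:
            raise ValueError("no called genotypes to build an SFS from")
        full = (c1 == n1) & (c2 == n2)
        d1, d2 = d1[full], d2[full]
        mat = np.zeros((n1 + 1, n2 + 1))
        np.add.at(mat, (d1, d2), 1.0)
    else:
        n1, n2 = project_to
        ok = (c1 >= n1) & (c2 >= n2)
        d1, c1, d2, c2 = d1[ok], c1[ok], d2[ok], c2[ok]
        if len(d1) == 0:
            raise ValueError("no sites with enough called alleles to project")
        P1 = _project_counts(d1, c1, n1)
        P2 = _project_counts(d2, c2, n2)
        mat = np.einsum("si,sj->ij", P1, P2)
    mat[0, 0] = 0.0
    mat[n1, n2] = 0.0
    sfs = JointSFS(mat, n1, n2, n_regions=n_regions, total_bp=total_bp)
    if sfs.n_sites == 0:
        raise ValueError("no usable (polarized, fully-called, in-region) sites")
    return sfs


def expected_sfs(
    spec: DemographicModelSpec,
    n1: int,
    n2: int,
    theta: float = 1.0,
    engine: str = "deterministic",
    config: EngineConfig | None = None,
    n_reps: int = 500,
    seed: int | None = None,
) -> np.ndarray:
    """Expected joint SFS under a model, linear in theta.

    engine="deterministic" uses the moment-closure ODE solver (default);
    engine="coalescent" averages branch-mode spectra over msprime ancestries.
    """
    spec.validate()
    m12, m21 = spec.migration()
    epochs = spec.epochs()
    if engine == "deterministic":
        out = expected_sfs_from_epochs(n1, n2, epochs, m12=m12, m21=m21, config=config)
    elif engine == "coalescent":
        out = expected_sfs_coalescent(
            n1, n2, epochs, m12=m12, m21=m21, n_reps=n_reps, seed=seed
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    if not np.all(np.isfinite(out)):
        raise RuntimeError(f"expected SFS not finite for parameters {spec.params}")
    return theta * out
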