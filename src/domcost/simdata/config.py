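"""Simulation configuration: demography truth, DFE, rescaling, presets.

Sizes and times are kept as floats so that population-size rescaling is an
exact algebraic operation (theta = 4*N*mu, N*s, N*m and t/N are preserved to
the last bit); rounding to whole individuals and generations happens only
inside the simulation engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

__all__ = [
    "Epoch",
    "DemographyTruth",
    "SweepInjection",
    "SimulationConfig",
    "rescale",
    "domestication_bottleneck",
]


@dataclass(frozen=True)
class Epoch:
    """Population-size segment; times in generations before present,
    t_start > t_end >= 0, size interpolating linearly from size_start (at
    t_start) to size_end (at t_end)."""

    t_start: float
    t_end: float
    size_start: float
    size_end: float

    def size_at(self, t: float) -> float:
        if self.t_start == self.t_end:
            return self.size_end
        frac = (self.t_start - t) / (self.t_start - self.t_end)
        return self.size_start + (self.size_end - self.size_start) * frac


@dataclass(frozen=True)
class DemographyTruth:
    """Two daughter populations splitting from a common ancestor.

    Epoch lists run from the split toward the present and must tile
    [0, t_split] without gaps or overlap.  m12 is the per-generation
    probability that an individual of population 1 is replaced by a migrant
    from population 2 (and vice versa for m21).
    """

    N_anc: float
    t_split: float
    epochs1: tuple[Epoch, ...] = ()
    epochs2: tuple[Epoch, ...] = ()
    m12: float = 0.0
    m21: float = 0.0

    def validate(self) -> None:
        if self.N_anc < 2:
            raise ValueError("ancestral size must be >= 2")
        if self.t_split < 0:
            raise ValueError("split time must be >= 0")
        if not (0 <= self.m12 < 1 and 0 <= self.m21 < 1):
            raise ValueError("migration proportions must be in [0, 1)")
        for name, epochs in (("1", self.epochs1), ("2", self.epochs2)):
            if self.t_split == 0:
                continue
            if not epochs:
                raise ValueError(f"population {name} has no epochs")
            t = self.t_split
            for ep in epochs:
                if not np.isclose(ep.t_start, t):
                    raise ValueError(
                        f"population {name}: epochs do not tile [0, t_split]"
                    )
                if ep.t_end >= ep.t_start:
                    raise ValueError(f"population {name}: epoch times not decreasing")
                if min(ep.size_start, ep.size_end) < 2:
                    raise ValueError(f"population {name}: size < 2 in epoch {ep}")
                t = ep.t_end
            if not np.isclose(t, 0.0):
                raise ValueError(f"population {name}: epochs do not reach the present")

    def size_at(self, pop: int, t: float) -> float:
        """Diploid size of population 1 or 2 at t generations before present."""
        epochs = self.epochs1 if pop == 1 else self.epochs2
        for ep in epochs:
            if ep.t_start >= t >= ep.t_end:
                return ep.size_at(t)
        raise ValueError(f"time {t} outside [0, t_split]")

    def final_sizes(self) -> tuple[float, float]:
        if self.t_split == 0:
            return self.N_anc, 0.0
        return self.size_at(1, 0.0), self.size_at(2, 0.0)


@dataclass(frozen=True)
class SweepInjection:
    """A single beneficial mutation pushed through one population.

    position=None picks a missense-capable coding site nearest the contig
    midpoint.  start_freq is the post-establishment frequency at injection
    (conditioning on establishment rather than simulating repeated loss).
    """

    s: float = 0.5
    h: float = 0.5
    population: int = 2
    start_freq: float = 0.05
    position: int | None = None


@dataclass(frozen=True)
class SimulationConfig:
    contig_length_bp: int = 1_000_000
    coding_fraction: float = 0.042
    mu: float = 1.91e-9
    rec_rate: float = 1.0e-8
    dfe_shape: float = 0.2
    dfe_mean_s: float = 0.0
    dominance_h: float = 0.25
    demography: DemographyTruth = field(
        default_factory=lambda: DemographyTruth(N_anc=100.0, t_split=0.0)
    )
    sample_sizes: tuple[int, int] = (10, 10)
    n_outgroup: int = 4
    outgroup_divergence: float = 0.02
    rescale_Q: float = 1.0
    seed: int = 0
    mask_fraction: float = 0.03
    dfe_bins: int = 16
    burnin_generations: int = 0
    sweep: SweepInjection | None = None
    contig_name: str = "sim1"
    # Restrict variation to coding sites.  Exact for every coding-site
    # statistic: neutral noncoding sites never feed back on coding-site
    # dynamics (multiplicative fitness, no epistasis), so omitting them only
    # removes columns the load analyses ignore while making large contigs
    # affordable.
    coding_only: bool = False

    def validate(self) -> None:
        if not 0 <= self.coding_fraction < 1:
            raise ValueError("coding_fraction must be in [0, 1)")
        if min(self.mu, self.rec_rate, self.dfe_mean_s) < 0:
            raise ValueError("mu, rec_rate and dfe_mean_s must be >= 0")
        if not 0 <= self.dominance_h <= 1:
            raise ValueError("dominance_h must be in [0, 1]")
        if self.rescale_Q < 1:
            raise ValueError("rescale_Q must be >= 1")
        self.demography.validate()
        n1f, n2f = self.demography.final_sizes()
        if self.sample_sizes[0] > n1f or (
            self.demography.t_split > 0 and self.sample_sizes[1] > n2f
        ):
            raise ValueError("sample sizes exceed final population sizes")
        if self.demography.t_split == 0 and self.sample_sizes[1] > 0:
            raise ValueError("no population 2 exists when t_split == 0")

    def truth_dict(self) -> dict:
        return asdict(self)


def rescale(config: SimulationConfig, Q: float) -> SimulationConfig:
    """Shrink population sizes and times by Q while scaling mu, rec, s and m
    up by Q, preserving theta = 4*N*mu, N*s, N*m and t/N exactly."""
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if Q == 1:
        return config
    dem = config.demography

    def scale_epochs(epochs):
        out = []
        for ep in epochs:
            if min(ep.size_start, ep.size_end) / Q < 2:
                raise ValueError(f"rescaled size < 2 diploids in epoch {ep}")
            out.append(
                Epoch(ep.t_start / Q, ep.t_end / Q, ep.size_start / Q, ep.size_end / Q)
            )
        return tuple(out)

    if dem.N_anc / Q < 2:
        raise ValueError("rescaled ancestral size < 2 diploids")
    new_dem = DemographyTruth(
        N_anc=dem.N_anc / Q,
        t_split=dem.t_split / Q,
        epochs1=scale_epochs(dem.epochs1),
        epochs2=scale_epochs(dem.epochs2),
        m12=min(dem.m12 * Q, 0.999),
        m21=min(dem.m21 * Q, 0.999),
    )
    sweep = config.sweep
    if sweep is not None:
        sweep = replace(sweep, s=sweep.s * Q)
    return replace(
        config,
        demography=new_dem,
        mu=config.mu * Q,
        rec_rate=config.rec_rate * Q,
        dfe_mean_s=config.dfe_mean_s * Q,
        sweep=sweep,
        rescale_Q=1.0,
    )


def domestication_bottleneck(
    seed: int = 0,
    rescale_Q: float = 600.0,
    N_anc: float = 180_000.0,
    m12: float = 1.0e-6,
    m21: float = 2.0e-6,
    contig_length_bp: int = 1_000_000,
    dfe_mean_s: float = 0.03,
    **overrides,
) -> SimulationConfig:
    """Domestication-bottleneck preset.

    Population 1 (wild) expands from the ancestral size to 257,000 by 10,300
    generations before present, then contracts to 154,000; population 2
    (domestic) starts at 138,000 at the 12,300-generation split, declines to
    52,000 by 6,990, then recovers to 152,000.  One generation per year.
    The pre-split ancestral size and the migration rates are user-set
    stand-ins (no published point estimates anchor them), as are the DFE
    parameters.  The preset is returned already rescaled by
    rescale_Q for desk-scale runs.
    """
    dem = DemographyTruth(
        N_anc=N_anc,
        t_split=12_300.0,
        epochs1=(
            Epoch(12_300.0, 10_300.0, N_anc, 257_000.0),
            Epoch(10_300.0, 0.0, 257_000.0, 154_000.0),
        ),
        epochs2=(
            Epoch(12_300.0, 6_990.0, 138_000.0, 52_000.0),
            Epoch(6_990.0, 0.0, 52_000.0, 152_000.0),
        ),
        m12=m12,
        m21=m21,
    )
    cfg = SimulationConfig(
        contig_length_bp=contig_length_bp,
        demography=dem,
        dfe_mean_s=dfe_mean_s,
        seed=seed,
        **overrides,
    )
    return rescale(cfg, rescale_Q)
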