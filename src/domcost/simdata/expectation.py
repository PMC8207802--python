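"""Deterministic expectations of load statistics under a two-population
demography.

For each selection coefficient the full allele-frequency density of the
discrete Wright-Fisher chain is propagated through the post-split epochs of
each population separately (migration ignored; the coupling is weak at the
preset rates), starting from the mutation-selection-drift stationary density
of the ancestral population, with new-mutation influx proportional to the
current population size.  Expected per-individual heterozygous and
homozygous derived-genotype counts then follow by integrating 2x(1-x) and
x^2 against the density.

This is the generator's own mean-field theory: it predicts the sign and
magnitude of the wild-vs-domestic load contrasts that the stochastic
simulator fluctuates around, and it is how the package documents that a
closed two-population model of the domestication bottleneck does *not*
produce a higher heterozygous-deleterious fraction in the domestic
population (the observed excess in real data plausibly requires
introgression from divergent taxa or wild population structure, neither of
which is part of this geometry).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

from .config import DemographyTruth, SimulationConfig
from .engine import _wf_stationary, discretize_gamma

__all__ = ["expected_het_hom", "expected_load_contrast"]


def expected_het_hom(
    dem: DemographyTruth, s: float, h: float
) -> dict[int, tuple[float, float]]:
    """Expected per-individual (het, hom) derived-genotype counts per unit
    ancestral mutation influx, for each population at the present day."""
    dem.validate()
    K_anc = 2 * int(round(dem.N_anc))
    f0 = _wf_stationary(K_anc, s, h)
    t_split = int(round(dem.t_split))
    out: dict[int, tuple[float, float]] = {}
    for pop in (1, 2):
        dens = f0.copy()
        K = K_anc
        for t in range(t_split - 1, -1, -1):
            K_new = 2 * max(2, int(round(dem.size_at(pop, t))))
            x = np.arange(1, K) / K
            if s != 0.0:
                w11, w01 = 1.0 - s, 1.0 - h * s
                num = x * x * w11 + x * (1 - x) * w01
                xp = num / (num + x * (1 - x) * w01 + (1 - x) ** 2)
            else:
                xp = x
            T = binom.pmf(np.arange(1, K_new)[None, :], K_new, xp[:, None])
            dens = dens @ T
            dens[0] += K_new / K_anc  # influx scales with population size
            K = K_new
        x = np.arange(1, K) / K
        out[pop] = (
            float((dens * 2 * x * (1 - x)).sum()),
            float((dens * x * x).sum()),
        )
    return out


def expected_load_contrast(config: SimulationConfig) -> dict[str, float]:
    """Domestic-vs-wild expected contrasts of the headline load statistics
    under the configured demography and DFE (positive = higher in domestic):
    relative excess of the per-individual deleterious allele count and of
    the deleterious/synonymous ratio, and the difference (percentage points)
    in the heterozygous fraction of deleterious genotypes."""
    dem = config.demography
    h = config.dominance_h
    neu = expected_het_hom(dem, 0.0, h)
    svals, sprobs = discretize_gamma(
        config.dfe_shape, config.dfe_mean_s, config.dfe_bins
    )
    agg = {1: np.zeros(2), 2: np.zeros(2)}
    for sv, pb in zip(svals, sprobs):
        r = expected_het_hom(dem, float(sv), h)
        for p in (1, 2):
            agg[p] += pb * np.array(r[p])
    ndel = {p: agg[p][0] + 2 * agg[p][1] for p in (1, 2)}
    nsyn = {p: neu[p][0] + 2 * neu[p][1] for p in (1, 2)}
    hetfrac = {p: agg[p][0] / (agg[p][0] + agg[p][1]) for p in (1, 2)}
    return {
        "ndel_excess": ndel[2] / ndel[1] - 1.0,
        "del_syn_ratio_excess": (ndel[2] / nsyn[2]) / (ndel[1] / nsyn[1]) - 1.0,
        "het_del_fraction_diff_pp": 100.0 * (hetfrac[2] - hetfrac[1]),
    }
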