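"""Per-individual and per-population genetic-load statistics.

Load is counted over polarized sites in two classes: deleterious (hSNPs:
high-impact non-synonymous variants) and synonymous.  The per-individual
deleterious allele count is the additive convention het + 2*hom; the
heterozygous-deleterious fraction n_het/(n_het + n_hom) quantifies how much
of the load is masked in heterozygotes.  Group contrasts use the unpaired
two-sided Wilcoxon-Mann-Whitney rank-sum test (comparisons of this kind are
often loosely labelled "Wilcoxon signed-rank" in the applied literature,
but the groups here are unpaired, so the rank-sum version is the
applicable test).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

__all__ = [
    "individual_load",
    "population_load_profile",
    "GroupComparison",
    "compare_groups",
    "load_excess",
    "score_by_chromosome_class",
]


def individual_load(
    genotypes: np.ndarray,
    is_deleterious: np.ndarray,
    is_synonymous: np.ndarray,
    sample_ids: list[str],
    populations: dict[str, str] | list[str],
) -> pd.DataFrame:
    """Per-sample load summary.

    genotypes: (n_samples, n_sites) derived-allele dosages 0/1/2, -1 missing
    (missing genotypes are excluded from all counts).  Sites should already
    be polarized; unpolarized sites must be excluded upstream.
    """
    G = np.asarray(genotypes)
    if isinstance(populations, dict):
        missing = [s for s in sample_ids if s not in populations]
        if missing:
            raise KeyError(f"samples absent from the population map: {missing}")
        pops = [populations[s] for s in sample_ids]
    else:
        if len(populations) != len(sample_ids):
            raise ValueError("populations list does not match sample_ids")
        pops = list(populations)
    is_del = np.asarray(is_deleterious, bool)
    is_syn = np.asarray(is_synonymous, bool)

    rows = []
    for i, sid in enumerate(sample_ids):
        g = G[i]
        gd = g[is_del & (g >= 0)]
        gs = g[is_syn & (g >= 0)]
        n_het_del = int((gd == 1).sum())
        n_hom_del = int((gd == 2).sum())
        n_het_syn = int((gs == 1).sum())
        n_hom_syn = int((gs == 2).sum())
        n_del = n_het_del + 2 * n_hom_del
        n_syn = n_het_syn + 2 * n_hom_syn
        rows.append(
            {
                "sample_id": sid,
                "population": pops[i],
                "n_del_alleles": n_del,
                "n_het_del": n_het_del,
                "n_hom_del": n_hom_del,
                "n_syn_alleles": n_syn,
                "n_het_syn": n_het_syn,
                "n_hom_syn": n_hom_syn,
                "del_syn_ratio": n_del / n_syn if n_syn else np.nan,
                "het_del_fraction": (
                    n_het_del / (n_het_del + n_hom_del)
                    if (n_het_del + n_hom_del)
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def population_load_profile(
    summaries: pd.DataFrame,
    genotypes: np.ndarray | None = None,
    is_deleterious: np.ndarray | None = None,
    is_synonymous: np.ndarray | None = None,
    sample_populations: list[str] | None = None,
) -> pd.DataFrame:
    """Population means of the per-individual summaries, plus (when the
    genotype matrix is supplied) the mean derived allele frequency of each
    site class; frequencies use called alleles only.

    Both the mean of per-individual het_del fractions (primary) and the
    pooled-count fraction are reported.
    """
    if summaries.empty:
        raise ValueError("no load summaries supplied")
    rows = []
    for pop, grp in summaries.groupby("population", sort=True):
        row = {
            "population": pop,
            "n_samples": len(grp),
            "mean_del_alleles": grp["n_del_alleles"].mean(),
            "mean_syn_alleles": grp["n_syn_alleles"].mean(),
            "mean_del_syn_ratio": grp["del_syn_ratio"].mean(),
            "mean_het_del_fraction": grp["het_del_fraction"].mean(),
            "pooled_het_del_fraction": (
                grp["n_het_del"].sum() / (grp["n_het_del"].sum() + grp["n_hom_del"].sum())
                if (grp["n_het_del"].sum() + grp["n_hom_del"].sum())
                else np.nan
            ),
        }
        if genotypes is not None:
            pops = np.asarray(sample_populations)
            Gp = np.asarray(genotypes)[pops == pop]
            for name, mask in (
                ("del", np.asarray(is_deleterious, bool)),
                ("syn", np.asarray(is_synonymous, bool)),
            ):
                sub = Gp[:, mask]
                called = (sub >= 0).sum(axis=0) * 2
                derived = np.where(sub > 0, sub, 0).sum(axis=0)
                ok = called > 0
                row[f"mean_{name}_freq"] = (
                    float(np.mean(derived[ok] / called[ok])) if ok.any() else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    statistic_name: str
    mean_a: float
    mean_b: float
    W: float  # rank sum of group A
    p_value: float
    test_type: str  # "exact" | "normal_approximation"
    direction: str  # "A>B" | "B>A" | "tied"


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p for the rank-sum of A under the permutation null
    (all label assignments equally likely); assumes no ties."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    n = len(pooled)
    total = comb(n, na)
    count_le = 0
    count_ge = 0
    for combo in itertools.combinations(range(n), na):
        w = ranks[list(combo)].sum()
        if w <= w_obs + 1e-9:
            count_le += 1
        if w >= w_obs - 1e-9:
            count_ge += 1
    p = 2.0 * min(count_le, count_ge) / total
    return w_obs, min(1.0, p)


def compare_groups(
    values_a, values_b, statistic_name: str = "statistic", exact_max_n: int = 12
) -> GroupComparison:
    """Two-sided rank-sum comparison of two independent groups.

    Exact enumeration of all label assignments when n_A + n_B <= exact_max_n
    and the pooled data carry no ties; otherwise the normal approximation
    with tie correction and continuity correction.  Constant pooled data
    yield p = 1 with a warning.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    W = float(ranks[: len(a)].sum())
    mean_a, mean_b = float(a.mean()), float(b.mean())
    direction = "A>B" if mean_a > mean_b else ("B>A" if mean_b > mean_a else "tied")
    if np.all(pooled == pooled[0]):
        warnings.warn("constant pooled data; rank-sum test is uninformative")
        return GroupComparison(statistic_name, mean_a, mean_b, W, 1.0, "degenerate", "tied")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= exact_max_n and not has_ties:
        W, p = _exact_ranksum_p(a, b)
        return GroupComparison(statistic_name, mean_a, mean_b, float(W), p, "exact", direction)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=True)
    return GroupComparison(
        statistic_name,
        mean_a,
        mean_b,
        W,
        float(res.pvalue),
        "normal_approximation",
        direction,
    )


def load_excess(mean_a: float, mean_b: float) -> float:
    """Percentage excess of A's mean per-individual count over B's:
    100 * (mean_A - mean_B) / mean_B."""
    if mean_b == 0:
        return np.nan
    return 100.0 * (mean_a - mean_b) / mean_b


def score_by_chromosome_class(annotations: pd.DataFrame) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Mean deleteriousness score per chromosome class with pairwise
    rank-sum comparisons; classes without scored variants are skipped."""
    scored = annotations.dropna(subset=["delta_score"])
    means = (
        scored.groupby("chromosome_class")["delta_score"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_delta_score", "count": "n_variants"})
    )
    comparisons = []
    classes = list(means["chromosome_class"])
    for i, ci in enumerate(classes):
        for cj in classes[i + 1 :]:
            vi = scored.loc[scored["chromosome_class"] == ci, "delta_score"].values
            vj = scored.loc[scored["chromosome_class"] == cj, "delta_score"].values
            comparisons.append(
                compare_groups(vi, vj, statistic_name=f"delta_score:{ci}_vs_{cj}")
            )
    return means, comparisons
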