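"""Annotation tests: codon-aware effect classification against brute-force
translation, alignment delta scores against hand-computed values, threshold
behaviour, and outgroup polarization."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from domcost import simdata, varianno
from domcost.simdata.config import SimulationConfig
from domcost.simdata.layout import CDS, GenomeLayout, build_genome_layout
from domcost._codon import encode, revcomp
from domcost.varianno import (
    DeltaScoreModel,
    classify_coding_effect,
    classify_deleterious,
    delta_score,
    make_homologs,
    polarize,
)


def layout_from_seq(seq: str, cds: list[CDS]) -> GenomeLayout:
    return GenomeLayout("toy", len(seq), encode(seq), cds, [])


def brute_force_effect(layout: GenomeLayout, pos: int, alt: str) -> str:
    """Oracle: translate every codon of the containing CDS before and after
    the substitution with Biopython."""
    hits = [c for c in layout.cds if c.start <= pos < c.end]
    if not hits:
        return "noncoding"
    c = hits[0]
    before = layout.sequence[c.start : c.end]
    after = (
        layout.sequence[c.start : pos] + alt + layout.sequence[pos + 1 : c.end]
    )
    if c.strand == "-":
        before, after = revcomp(before), revcomp(after)
    p_before = str(Seq(before).translate())
    p_after = str(Seq(after).translate())
    diff = [(a, b) for a, b in zip(p_before, p_after) if a != b]
    if not diff:
        return "synonymous"
    if diff[0][1] == "*":
        return "nonsense"
    return "missense"


class TestClassifyEffect:
    def test_third_position_synonymous(self):
        layout = layout_from_seq("GGATAA", [CDS(0, 6, "+", "g")])
        eff = classify_coding_effect(2, "A", "G", layout)
        assert eff.effect == "synonymous" and eff.aa_change == "G1G"

    def test_first_position_missense_gly_to_arg(self):
        # mirrors the chicken TSHR Gly->Arg case: GGA -> AGA
        layout = layout_from_seq("GGATAA", [CDS(0, 6, "+", "g")])
        eff = classify_coding_effect(0, "G", "A", layout)
        assert eff.effect == "missense"
        assert eff.aa_ref == "G" and eff.aa_alt == "R"

    def test_minus_strand_enumeration_oracle(self):
        # genome TCC; minus-strand codon revcomp(TCC) = GGA (Gly)
        layout = layout_from_seq("AAATCCAAA", [CDS(3, 6, "-", "g")])
        for pos in (3, 4, 5):
            ref = layout.sequence[pos]
            for alt in "ACGT":
                if alt == ref:
                    continue
                eff = classify_coding_effect(pos, ref, alt, layout)
                assert eff.effect == brute_force_effect(layout, pos, alt)

    def test_ref_mismatch_raises(self):
        layout = layout_from_seq("GGATAA", [CDS(0, 6, "+", "g")])
        with pytest.raises(ValueError, match="mismatch"):
            classify_coding_effect(0, "T", "A", layout)

    def test_out_of_bounds_raises(self):
        layout = layout_from_seq("GGATAA", [CDS(0, 6, "+", "g")])
        with pytest.raises(IndexError):
            classify_coding_effect(10, "G", "A", layout)

    def test_noncoding(self):
        layout = layout_from_seq("GGATAA", [CDS(0, 3, "+", "g")])
        assert classify_coding_effect(4, "A", "C", layout).effect == "noncoding"

    def test_random_layouts_against_oracle(self, rng):
        """Classification agrees with exhaustive translation on random
        two-strand layouts."""
        cfg = SimulationConfig(contig_length_bp=10_000, coding_fraction=0.3, seed=17)
        layout = build_genome_layout(cfg)
        assert {c.strand for c in layout.cds} == {"+", "-"}
        for _ in range(500):
            pos = int(rng.integers(layout.length))
            ref = layout.sequence[pos]
            alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
            assert (
                classify_coding_effect(pos, ref, alt, layout).effect
                == brute_force_effect(layout, pos, alt)
            )


class TestDeltaScore:
    def test_worked_example_gav(self):
        model = DeltaScoreModel(homologs=["GAV"])
        assert delta_score("GAV", (2, "A", "V"), model) == pytest.approx(-4.0)

    def test_identity_substitution_is_zero(self):
        model = DeltaScoreModel(homologs=["MKLV", "GAV"])
        assert delta_score("GAV", (2, "A", "A"), model) == 0.0

    def test_mean_over_homologs(self):
        # homolog GAV gives delta -4 (V:A=0 vs A:A=4); homolog GVV gives +4
        model = DeltaScoreModel(homologs=["GAV", "GVV"])
        assert delta_score("GAV", (2, "A", "V"), model) == pytest.approx(0.0)

    def test_empty_homolog_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            delta_score("GAV", (2, "A", "V"), DeltaScoreModel(homologs=[]))

    def test_nonstandard_residue_raises(self):
        model = DeltaScoreModel(homologs=["GAV"])
        with pytest.raises(ValueError):
            delta_score("GAX", (2, "A", "V"), model)

    def test_inconsistent_substitution_raises(self):
        model = DeltaScoreModel(homologs=["GAV"])
        with pytest.raises(ValueError, match="inconsistent"):
            delta_score("GAV", (2, "G", "V"), model)

    def test_antisymmetry_gap_free(self, rng):
        aas = sorted(varianno.STANDARD_AA)
        for _ in range(40):
            L = int(rng.integers(10, 30))
            ref = "".join(rng.choice(aas, L))
            pos = int(rng.integers(1, L + 1))
            alt = rng.choice([a for a in aas if a != ref[pos - 1]])
            var = ref[: pos - 1] + alt + ref[pos:]
            homs = make_homologs(ref, n=3, divergence=0.08, rng=rng)
            model = DeltaScoreModel(homologs=homs)
            d_fwd = delta_score(ref, (pos, ref[pos - 1], alt), model)
            d_rev = delta_score(var, (pos, alt, ref[pos - 1]), model)
            assert d_fwd == pytest.approx(-d_rev, abs=1e-9)


class TestThreshold:
    @pytest.mark.parametrize(
        "score,expected",
        [(-6.981, True), (-2.5, True), (0.0, False), (-2.499, False)],
    )
    def test_boundary_inclusive(self, score, expected):
        assert classify_deleterious(score) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_deleterious(float("nan"))


class TestPolarize:
    def test_fixed_reference(self):
        anc, ok = polarize("A", "G", np.array([0, 0, 0]))
        assert (anc, ok) == ("A", True)

    def test_fixed_alternate(self):
        anc, ok = polarize("A", "G", np.array([2, 2]))
        assert (anc, ok) == ("G", True)

    def test_het_or_polymorphic_unpolarized(self):
        assert polarize("A", "G", np.array([0, 1]))[1] is False
        assert polarize("A", "G", np.array([0, 2]))[1] is False

    def test_all_missing_unpolarized(self):
        assert polarize("A", "G", np.array([-1, -1]))[1] is False


@pytest.fixture(scope="module")
def annotated(small_dataset):
    df = small_dataset.sites.rename(columns={"ancestral": "ref", "derived": "alt"})[
        ["position", "ref", "alt"]
    ]
    og = small_dataset.outgroup_genotypes
    return (
        small_dataset,
        varianno.annotate_variants(
            df, small_dataset.layout, outgroup_dosages=og, seed=5
        ),
    )


class TestAnnotateVariants:
    def test_hsnp_implies_scored_nonsynonymous(self, annotated):
        _, ann = annotated
        h = ann[ann["is_hsnp"]]
        assert set(h["effect"]) <= {"missense", "nonsense"}
        assert (h["delta_score"] <= -2.5).all()
        neutral = ann[ann["effect"].isin(["synonymous", "noncoding"])]
        assert neutral["delta_score"].isna().all()

    def test_effect_classes_match_simulator_truth(self, annotated):
        ds, ann = annotated
        assert list(ann["effect"]) == list(ds.sites["effect"])

    def test_threshold_monotonicity(self, annotated):
        ds, ann = annotated
        scored = ann.dropna(subset=["delta_score"])
        sets = []
        for thr in (-5.0, -2.5, -1.0):
            sets.append(set(scored.loc[scored["delta_score"] <= thr, "position"]))
        assert sets[0] <= sets[1] <= sets[2]

    def test_deleterious_recovery_reported(self, annotated):
        """The fraction of truly deleterious sites recovered as hSNPs is a
        finite, reported number (the score is a proxy, not the truth)."""
        ds, ann = annotated
        truly = ds.sites["s"].to_numpy() > 0.01
        if truly.sum() == 0:
            pytest.skip("no strongly deleterious sites segregating in this toy")
        recovered = ann["is_hsnp"].to_numpy() & truly
        frac = recovered.sum() / truly.sum()
        assert 0.0 <= frac <= 1.0

    def test_polarization_mostly_matches_truth(self, annotated):
        ds, ann = annotated
        pol = ann[ann["polarized"]]
        agree = (pol["ancestral"] == pol["ref"]).mean()
        # outgroup-branch homoplasy can flip a small minority of sites
        assert agree > 0.9
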