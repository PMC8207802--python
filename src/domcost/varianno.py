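"""Variant annotation: coding effect, alignment-based deleteriousness score,
and ancestral-allele polarization.

The deleteriousness score follows the PROVEAN idea: the effect of an amino
acid substitution is the change it causes in the alignment score of the
query protein against a set of homologous sequences (semi-global alignment,
BLOSUM62, affine gaps), averaged over the homolog set.  Scores at or below
the threshold (default -2.5) mark a variant as a high-impact SNP (hSNP).
Unlike the original tool there is no database search or identity-based
clustering of supporting sequences: the homolog set is an explicit input,
and a synthetic homolog generator is provided for simulated proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._codon import CODON_TABLE, revcomp
from .simdata.layout import GenomeLayout

__all__ = [
    "DeltaScoreModel",
    "CodingEffect",
    "classify_coding_effect",
    "delta_score",
    "classify_deleterious",
    "polarize",
    "make_homologs",
    "annotate_variants",
    "chromosome_class",
    "CHICKEN_CHROMOSOME_CLASSES",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# chicken convention: chromosomes 1-5 macro, 6-10 intermediate, 11-38 micro
CHICKEN_CHROMOSOME_CLASSES = {
    **{str(i): "macro" for i in range(1, 6)},
    **{str(i): "intermediate" for i in range(6, 11)},
    **{str(i): "micro" for i in range(11, 39)},
}


def chromosome_class(contig: str, table: dict[str, str] | None = None) -> str:
    """Map a contig name to macro/intermediate/micro, else 'unassigned'."""
    table = CHICKEN_CHROMOSOME_CLASSES if table is None else table
    name = contig[3:] if contig.lower().startswith("chr") else contig
    return table.get(name, "unassigned")


@dataclass
class DeltaScoreModel:
    """Scoring model: substitution matrix, affine gap penalties, homologs."""

    homologs: list[str]
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    threshold: float = -2.5
    _aligner: Align.PairwiseAligner | None = field(default=None, repr=False)

    def aligner(self) -> Align.PairwiseAligner:
        if self._aligner is None:
            al = Align.PairwiseAligner()
            al.substitution_matrix = substitution_matrices.load(self.matrix_name)
            al.open_gap_score = -self.gap_open
            al.extend_gap_score = -self.gap_extend
            # semi-global: terminal gaps are free
            try:
                al.end_insertion_score = 0.0
                al.end_deletion_score = 0.0
            except AttributeError:  # older Biopython naming
                al.target_end_gap_score = 0.0
                al.query_end_gap_score = 0.0
            al.mode = "global"
            self._aligner = al
        return self._aligner


@dataclass(frozen=True)
class CodingEffect:
    effect: str  # synonymous | missense | nonsense | noncoding
    gene_id: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    aa_pos: int | None = None  # 1-based position in the protein

    @property
    def aa_change(self) -> str | None:
        if self.aa_ref is None:
            return None
        return f"{self.aa_ref}{self.aa_pos}{self.aa_alt}"


def classify_coding_effect(
    position: int, ref: str, alt: str, layout: GenomeLayout
) -> CodingEffect:
    """Codon-aware effect of a single-nucleotide variant (0-based position).

    The affected codon is translated on the annotated strand (reverse
    complement for minus-strand CDS) with the standard genetic code.
    When two CDS annotations overlap the position, the first in sorted
    order is used and a warning is emitted.
    """
    if not 0 <= position < layout.length:
        raise IndexError(f"position {position} beyond contig of {layout.length} bp")
    if layout.sequence[position] != ref:
        raise ValueError(
            f"reference mismatch at {position}: variant says {ref}, "
            f"reference has {layout.sequence[position]}"
        )
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    hits = [c for c in layout.cds if c.start <= position < c.end]
    if not hits:
        return CodingEffect("noncoding")
    if len(hits) > 1:
        warnings.warn(
            f"position {position} overlaps {len(hits)} CDS; using the first",
            stacklevel=2,
        )
    c = hits[0]
    if c.strand == "+":
        offset = position - c.start
        codon_start = c.start + 3 * (offset // 3)
        codon = layout.sequence[codon_start : codon_start + 3]
        within = position - codon_start
        mutated = codon[:within] + alt + codon[within + 1 :]
        aa_pos = offset // 3 + 1
    else:
        offset = (c.end - 1) - position  # position along the coding strand
        codon_start_t = 3 * (offset // 3)  # transcript coordinates
        transcript = revcomp(layout.sequence[c.start : c.end])
        codon = transcript[codon_start_t : codon_start_t + 3]
        within = offset - codon_start_t
        alt_t = revcomp(alt)
        mutated = codon[:within] + alt_t + codon[within + 1 :]
        aa_pos = offset // 3 + 1
    aa_ref = CODON_TABLE[codon]
    aa_alt = CODON_TABLE[mutated]
    if aa_alt == "*":
        effect = "nonsense" if aa_ref != "*" else "synonymous"
    elif aa_ref == aa_alt:
        effect = "synonymous"
    else:
        effect = "missense"
    return CodingEffect(effect, c.gene_id, aa_ref, aa_alt, aa_pos)


def _validate_protein(seq: str) -> None:
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues in protein: {sorted(bad)}")


def delta_score(
    ref_protein: str,
    substitution: tuple[int, str, str],
    model: DeltaScoreModel,
) -> float:
    """Mean alignment-score change caused by one amino acid substitution.

    substitution = (pos, aa_ref, aa_alt) with pos 1-based in ref_protein;
    aa_alt='*' (premature stop) truncates the protein at the substituted
    residue.  Identity substitutions score exactly 0.
    """
    if not model.homologs:
        raise ValueError("homolog set is empty")
    pos, aa_ref, aa_alt = substitution
    if not 1 <= pos <= len(ref_protein):
        raise ValueError(f"substitution position {pos} outside protein")
    if ref_protein[pos - 1] != aa_ref:
        raise ValueError(
            f"substitution inconsistent with protein: expected {aa_ref} at "
            f"{pos}, found {ref_protein[pos - 1]}"
        )
    _validate_protein(ref_protein)
    if aa_alt == aa_ref:
        return 0.0
    if aa_alt == "*":
        variant = ref_protein[: pos - 1]
        if not variant:
            variant = "M"  # degenerate: immediate stop; score against a stub
    else:
        if aa_alt not in STANDARD_AA:
            raise ValueError(f"non-standard substituting residue {aa_alt!r}")
        variant = ref_protein[: pos - 1] + aa_alt + ref_protein[pos:]
    al = model.aligner()
    deltas = []
    for hom in model.homologs:
        _validate_protein(hom)
        deltas.append(al.score(variant, hom) - al.score(ref_protein, hom))
    return float(np.mean(deltas))


def classify_deleterious(score: float, threshold: float = -2.5) -> bool:
    """High-impact call: score at or below the threshold."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return bool(score <= threshold)


def polarize(ref: str, alt: str, outgroup_dosages: np.ndarray) -> tuple[str | None, bool]:
    """Infer the ancestral allele from outgroup genotypes.

    outgroup_dosages counts the alt allele per outgroup diploid (0/1/2),
    with -1 for missing (including third-allele carriers).  The outgroup
    must be fixed: all-reference => ancestral = ref, all-alternate =>
    ancestral = alt; anything else (polymorphic, heterozygous, missing)
    returns (None, False) = unpolarized.
    """
    d = np.asarray(outgroup_dosages)
    d = d[d >= 0]
    if len(d) == 0:
        return None, False
    if np.all(d == 0):
        return ref, True
    if np.all(d == 2):
        return alt, True
    return None, False


def make_homologs(
    protein: str,
    n: int = 8,
    divergence: float = 0.1,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Synthetic homolog set: substitution-only mutants of the reference
    protein at the given per-residue divergence (a stand-in for a database
    search, suitable for simulated genomes)."""
    rng = rng or np.random.default_rng(0)
    aas = sorted(STANDARD_AA)
    out = []
    arr = np.array(list(protein))
    for _ in range(n):
        hom = arr.copy()
        hit = rng.random(len(hom)) < divergence
        for i in np.flatnonzero(hit):
            choices = [a for a in aas if a != hom[i]]
            hom[i] = choices[rng.integers(len(choices))]
        out.append("".join(hom))
    return out


def _cds_protein(layout: GenomeLayout, cds) -> str:
    seq = layout.sequence[cds.start : cds.end]
    if cds.strand == "-":
        seq = revcomp(seq)
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def annotate_variants(
    variants: pd.DataFrame,
    layout: GenomeLayout,
    model: DeltaScoreModel | None = None,
    outgroup_dosages: np.ndarray | None = None,
    homolog_divergence: float = 0.1,
    n_homologs: int = 8,
    threshold: float = -2.5,
    seed: int = 0,
    chrom_class_table: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Annotate a table of bi-allelic SNVs (columns: position, ref, alt).

    Adds effect class, amino-acid change, delta score (missense/nonsense
    only), hSNP flag, ancestral allele (from outgroup dosages when given,
    one row per variant), and chromosome class.  When no DeltaScoreModel is
    supplied, per-gene synthetic homolog sets are generated from the layout
    proteins.
    """
    rng = np.random.default_rng(seed)
    protein_cache: dict[str, str] = {}
    model_cache: dict[str, DeltaScoreModel] = {}
    cds_by_gene = {c.gene_id: c for c in layout.cds}

    rows = []
    for k, rec in enumerate(variants.itertuples(index=False)):
        eff = classify_coding_effect(int(rec.position), rec.ref, rec.alt, layout)
        score = np.nan
        if eff.effect in ("missense", "nonsense"):
            if model is not None:
                mdl = model
                prot = _cds_protein(layout, cds_by_gene[eff.gene_id])
            else:
                if eff.gene_id not in model_cache:
                    prot = _cds_protein(layout, cds_by_gene[eff.gene_id])
                    protein_cache[eff.gene_id] = prot
                    model_cache[eff.gene_id] = DeltaScoreModel(
                        homologs=make_homologs(
                            prot, n=n_homologs, divergence=homolog_divergence, rng=rng
                        ),
                        threshold=threshold,
                    )
                mdl = model_cache[eff.gene_id]
                prot = protein_cache[eff.gene_id]
            aa_alt = "*" if eff.effect == "nonsense" else eff.aa_alt
            score = delta_score(prot, (eff.aa_pos, eff.aa_ref, aa_alt), mdl)
        ancestral, polarized = (None, False)
        if outgroup_dosages is not None:
            ancestral, polarized = polarize(rec.ref, rec.alt, outgroup_dosages[:, k])
        rows.append(
            {
                "position": int(rec.position),
                "ref": rec.ref,
                "alt": rec.alt,
                "effect": eff.effect,
                "gene_id": eff.gene_id,
                "aa_change": eff.aa_change,
                "delta_score": score,
                "is_hsnp": bool(
                    eff.effect in ("missense", "nonsense")
                    and np.isfinite(score)
                    and classify_deleterious(score, threshold)
                ),
                "ancestral": ancestral,
                "polarized": polarized,
                "chromosome_class": chromosome_class(layout.contig, chrom_class_table),
            }
        )
    return pd.DataFrame(rows)
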