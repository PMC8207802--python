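"""Synthetic genome layout: reference sequence, CDS annotation, masks.

Coordinates are 0-based half-open.  CDS intervals are whole numbers of
codons in phase 0 and their coding-strand sequence contains no internal stop
codons, so every coding site has a well-defined amino-acid context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._codon import AA_BY_CODON_INDEX, COMPLEMENT_CODE, decode
from .config import SimulationConfig

__all__ = ["CDS", "GenomeLayout", "build_genome_layout", "effect_table"]

# effect codes used in truth tables and annotation cross-checks
NONCODING, SYNONYMOUS, MISSENSE, NONSENSE = 0, 1, 2, 3
EFFECT_NAMES = {
    NONCODING: "noncoding",
    SYNONYMOUS: "synonymous",
    MISSENSE: "missense",
    NONSENSE: "nonsense",
}

_STOP_INDICES = np.flatnonzero(AA_BY_CODON_INDEX == b"*")
_NONSTOP_INDICES = np.flatnonzero(AA_BY_CODON_INDEX != b"*")


@dataclass(frozen=True)
class CDS:
    start: int
    end: int
    strand: str  # '+' or '-'
    gene_id: str

    def __post_init__(self):
        if (self.end - self.start) % 3:
            raise ValueError("CDS length must be a multiple of 3")


@dataclass
class GenomeLayout:
    contig: str
    length: int
    seq_codes: np.ndarray  # uint8, 0..3 = ACGT
    cds: list[CDS] = field(default_factory=list)
    masks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return decode(self.seq_codes)

    def coding_bp(self) -> int:
        return sum(c.end - c.start for c in self.cds)

    def validate(self) -> None:
        prev_end = -1
        for c in self.cds:
            if not (0 <= c.start < c.end <= self.length):
                raise ValueError("CDS outside contig")
            if c.start < prev_end:
                raise ValueError("overlapping CDS intervals")
            prev_end = c.end


def _random_coding_codes(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Coding-strand base codes for n_codons codons, no stop codons."""
    idx = rng.choice(_NONSTOP_INDICES, size=n_codons)
    out = np.empty(3 * n_codons, dtype=np.uint8)
    out[0::3] = (idx >> 4) & 3
    out[1::3] = (idx >> 2) & 3
    out[2::3] = idx & 3
    return out


def build_genome_layout(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenomeLayout:
    """Place CDS intervals to hit the configured coding fraction (within
    0.5 percentage points), assign random strands, fill in sequence and drop
    a few repeat-style mask intervals.  Deterministic given the config seed.
    """
    L = int(config.contig_length_bp)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    cds_list: list[CDS] = []

    if config.coding_fraction > 0:
        if L < 3000:
            raise ValueError(
                f"contig of {L} bp is too short to lay out codon-multiple CDS"
            )
        target = int(round(config.coding_fraction * L))
        if target < 30:
            raise ValueError("coding fraction places less than one small CDS")
        lengths: list[int] = []
        while sum(lengths) < target:
            lengths.append(int(rng.integers(60, 400)) * 3)
        excess = sum(lengths) - target
        trimmed = lengths[-1] - 3 * int(np.ceil(excess / 3))
        if trimmed >= 30:
            lengths[-1] = trimmed
        else:
            lengths.pop()
        n = len(lengths)
        noncoding = L - sum(lengths)
        gaps = rng.multinomial(noncoding, np.ones(n + 1) / (n + 1))
        pos = 0
        for k, ln in enumerate(lengths):
            pos += int(gaps[k])
            strand = "+" if rng.random() < 0.5 else "-"
            cds_list.append(CDS(pos, pos + ln, strand, f"gene{k + 1}"))
            codes = _random_coding_codes(ln // 3, rng)
            if strand == "-":
                codes = COMPLEMENT_CODE[codes[::-1]]
            seq[pos : pos + ln] = codes
            pos += ln

    masks: list[tuple[int, int]] = []
    if config.mask_fraction > 0:
        n_masks = max(1, int(round(config.mask_fraction * L / 2000)))
        for _ in range(n_masks):
            a = int(rng.integers(0, max(1, L - 2000)))
            masks.append((a, min(L, a + 2000)))
        masks = _merge(masks)

    layout = GenomeLayout(config.contig_name, L, seq, cds_list, masks)
    layout.validate()
    if config.coding_fraction > 0:
        realized = layout.coding_bp() / L
        if abs(realized - config.coding_fraction) > 0.005:
            raise RuntimeError(
                f"coding fraction {realized:.4f} missed target {config.coding_fraction}"
            )
    return layout


def _merge(intervals):
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def effect_table(layout: GenomeLayout):
    """Vectorized lookup of the coding effect of every possible SNV.

    Returns (coding_pos, effect) where coding_pos is the sorted array of CDS
    positions and effect is an (n_coding, 4) int8 array giving the effect
    code of mutating each position to each base (-1 where alt == ref).
    Positions outside coding_pos are noncoding by definition.
    """
    pos_chunks: list[np.ndarray] = []
    eff_chunks: list[np.ndarray] = []
    for c in layout.cds:
        g = layout.seq_codes[c.start : c.end]
        if c.strand == "+":
            coding = g.copy()
        else:
            coding = COMPLEMENT_CODE[g[::-1]]
        n_cod = len(coding) // 3
        cidx = (
            (coding[0::3].astype(np.int32) << 4)
            | (coding[1::3].astype(np.int32) << 2)
            | coding[2::3].astype(np.int32)
        )
        ref_aa = AA_BY_CODON_INDEX[cidx]
        eff_coding = np.full((len(coding), 4), -1, dtype=np.int8)
        offsets = np.tile([0, 1, 2], n_cod)
        codon_of = np.repeat(np.arange(n_cod), 3)
        shift = (2 - offsets) * 2  # bit shift of this position in the codon index
        for alt in range(4):
            valid = coding != alt
            new_idx = (
                cidx[codon_of] & ~(3 << shift)
            ) | (alt << shift)
            alt_aa = AA_BY_CODON_INDEX[new_idx]
            eff = np.where(
                alt_aa == b"*",
                NONSENSE,
                np.where(alt_aa == ref_aa[codon_of], SYNONYMOUS, MISSENSE),
            ).astype(np.int8)
            eff_coding[valid, alt] = eff[valid]
        # map coding-strand rows/alt-bases back to genome strand
        if c.strand == "+":
            eff_genome = eff_coding
        else:
            eff_genome = eff_coding[::-1][:, COMPLEMENT_CODE]
        pos_chunks.append(np.arange(c.start, c.end))
        eff_chunks.append(eff_genome)
    if pos_chunks:
        return np.concatenate(pos_chunks), np.concatenate(eff_chunks)
    return np.empty(0, dtype=int), np.empty((0, 4), dtype=np.int8)
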