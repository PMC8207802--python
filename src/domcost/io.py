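"""Format readers and writers for the pipeline.

All coordinate conversion happens here: VCF and GFF3 are 1-based on disk and
converted to the internal 0-based half-open convention on read; BED is
already 0-based half-open.  Downstream modules never see 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from ._codon import BASES
from .simdata.layout import CDS, GenomeLayout

__all__ = [
    "VariantData",
    "read_vcf",
    "read_popmap",
    "read_fasta_layout",
    "read_gff3_cds",
    "read_bed",
    "write_bed",
    "write_tsv",
]


@dataclass
class VariantData:
    """Bi-allelic SNVs with a genotype dosage matrix.

    variants: DataFrame with contig, position (0-based), ref, alt, aa
    (INFO/AA ancestral allele or None).  genotypes: (n_samples, n_sites)
    int8 dosages of the alt allele, -1 = missing.  Multi-allelic records are
    split into one row per alternate allele (sharing a position).
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    populations: dict[str, str] = field(default_factory=dict)

    def by_population(self) -> dict[str, np.ndarray]:
        """Population name -> (derived==alt) dosage submatrix."""
        pops = np.asarray([self.populations.get(s) for s in self.samples])
        return {
            p: self.genotypes[pops == p]
            for p in sorted(set(pops[pops != None]))  # noqa: E711
        }

    def counts(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """(alt-allele count, called-allele count) per site."""
        pops = np.asarray([self.populations.get(s) for s in self.samples])
        G = self.genotypes[pops == population]
        called = 2 * (G >= 0).sum(axis=0)
        alt = np.where(G > 0, G, 0).sum(axis=0)
        return alt.astype(int), called.astype(int)


def read_popmap(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "population"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"])
    return dict(zip(df["sample_id"].astype(str), df["population"].astype(str)))


def read_vcf(path, popmap: dict[str, str] | None = None) -> VariantData:
    """Read bi-allelic SNVs (multi-allelics split) with GT dosages.

    Positions convert from 1-based VCF to internal 0-based.  INFO/AA is
    parsed when present.  Samples listed in the population map must exist
    in the VCF header.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if popmap:
        missing = [s for s in popmap if s not in samples]
        if missing:
            raise ValueError(f"popmap samples not in VCF header: {missing}")
    rows = []
    dosages = []
    for k, rec in enumerate(vcf):
        if rec.REF is None or len(rec.REF) != 1 or rec.REF not in BASES:
            raise ValueError(f"malformed or non-SNV record at line for POS {rec.POS}")
        gt = np.asarray(rec.genotype.array())[:, :2]  # (n_samples, 2 alleles)
        for ai, alt in enumerate(rec.ALT, start=1):
            if len(alt) != 1 or alt not in BASES:
                continue  # indels/symbolic alleles are out of scope
            called = gt >= 0
            dos = np.where(called.all(axis=1), (gt == ai).sum(axis=1), -1).astype(np.int8)
            rows.append(
                {
                    "contig": rec.CHROM,
                    "position": rec.POS - 1,
                    "ref": rec.REF,
                    "alt": alt,
                    "aa": rec.INFO.get("AA"),
                }
            )
            dosages.append(dos)
    variants = pd.DataFrame(rows, columns=["contig", "position", "ref", "alt", "aa"])
    geno = (
        np.stack(dosages, axis=1) if dosages else np.zeros((len(samples), 0), np.int8)
    )
    return VariantData(variants, geno, samples, dict(popmap or {}))


def read_fasta_layout(fasta_path, gff3_path=None, bed_path=None) -> GenomeLayout:
    """Assemble a GenomeLayout from reference FASTA plus optional CDS GFF3
    and mask BED (single-contig references)."""
    recs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(recs) != 1:
        raise ValueError("expected a single-contig reference")
    from ._codon import encode

    rec = recs[0]
    layout = GenomeLayout(rec.id, len(rec.seq), encode(str(rec.seq).upper()))
    if gff3_path is not None:
        layout.cds = read_gff3_cds(gff3_path, contig=rec.id)
    if bed_path is not None:
        layout.masks = read_bed(bed_path, contig=rec.id)
    layout.validate()
    return layout


def read_gff3_cds(path, contig: str | None = None) -> list[CDS]:
    """CDS features from a GFF3 file (1-based inclusive -> 0-based
    half-open); attributes used: gene_id or ID."""
    cds = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            if contig is not None and f[0] != contig:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gene = attrs.get("gene_id") or attrs.get("ID") or f"cds{len(cds) + 1}"
            cds.append(CDS(int(f[3]) - 1, int(f[4]), f[6], gene))
    return sorted(cds, key=lambda c: c.start)


def read_bed(path, contig: str | None = None) -> list[tuple[int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if contig is not None and f[0] != contig:
                continue
            out.append((int(f[1]), int(f[2])))
    return sorted(out)


def write_bed(intervals, contig: str, path) -> None:
    with open(path, "w") as fh:
        for a, b in intervals:
            fh.write(f"{contig}\t{a}\t{b}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
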