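"""Serialize a simulated dataset into the standard interchange formats.

Internal coordinates are 0-based half-open; VCF and GFF3 are written
1-based, BED stays 0-based.  The VCF carries the true ancestral allele in
INFO/AA and phased GT fields; outgroup samples appear alongside the two
focal populations, and sites where the outgroup carries a third allele are
written as missing outgroup genotypes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .engine import SimulatedDataset
from .layout import GenomeLayout

__all__ = ["write_outputs"]

_VCF_HEADER = """##fileformat=VCFv4.2
##source=domcost-simdata
##contig=<ID={contig},length={length}>
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##INFO=<ID=EFFTRUE,Number=1,Type=String,Description="True effect class from the simulator">
##INFO=<ID=STRUE,Number=1,Type=Float,Description="True selection cost (negative = beneficial)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_fasta(layout: GenomeLayout, path: Path, width: int = 60) -> None:
    seq = layout.sequence
    with open(path, "w") as fh:
        fh.write(f">{layout.contig}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_gff3(layout: GenomeLayout, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {layout.contig} 1 {layout.length}\n")
        for k, c in enumerate(layout.cds):
            attrs = f"ID=cds{k + 1};gene_id={c.gene_id}"
            fh.write(
                "\t".join(
                    [
                        layout.contig,
                        "domcost",
                        "CDS",
                        str(c.start + 1),
                        str(c.end),
                        ".",
                        c.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_bed(intervals, contig: str, path: Path) -> None:
    with open(path, "w") as fh:
        for a, b in intervals:
            fh.write(f"{contig}\t{a}\t{b}\n")


def _gt(dosage: int, phased_pair=None) -> str:
    if dosage < 0:
        return "./."
    if phased_pair is not None:
        return f"{phased_pair[0]}|{phased_pair[1]}"
    return {0: "0/0", 1: "0/1", 2: "1/1"}[dosage]


def write_vcf(dataset: SimulatedDataset, path: Path) -> None:
    layout = dataset.layout
    samples = dataset.sample_ids + dataset.outgroup_ids
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contig=layout.contig, length=layout.length))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        H = dataset.haplotypes
        sites = dataset.sites
        og = dataset.outgroup_genotypes
        og_allele = dataset.outgroup_alleles
        alt_codes = np.array(["ACGT".index(b) for b in sites["derived"]])
        rows = []
        for k in range(dataset.n_sites):
            pos = int(sites["position"].iloc[k])
            ref = sites["ancestral"].iloc[k]
            alt = sites["derived"].iloc[k]
            info = (
                f"AA={ref};EFFTRUE={sites['effect'].iloc[k]};"
                f"STRUE={sites['s'].iloc[k]:.6g}"
            )
            gts = [
                f"{H[k, 2 * i]}|{H[k, 2 * i + 1]}"
                for i in range(len(dataset.sample_ids))
            ]
            ref_code = "ACGT".index(ref)
            third = og_allele[k] != alt_codes[k] and og_allele[k] != ref_code
            for j in range(len(dataset.outgroup_ids)):
                # a third outgroup allele cannot be represented against this
                # REF/ALT pair; emit missing (the polarizer treats it as such)
                gts.append("./." if third else _gt(int(og[j, k])))
            rows.append(
                (pos, f"{layout.contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts))
            )
        # outgroup-branch substitutions not segregating in the focal sample
        for _, r in dataset.outgroup_sites.iterrows():
            pos = int(r["position"])
            ref = layout.sequence[pos]
            alt = "ACGT"[int(r["base"])]
            gts = ["0|0"] * len(dataset.sample_ids) + ["1/1"] * len(dataset.outgroup_ids)
            rows.append(
                (pos, f"{layout.contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\tAA={ref};EFFTRUE=outgroup_branch;STRUE=0\tGT\t" + "\t".join(gts))
            )
        for _, line in sorted(rows, key=lambda t: t[0]):
            fh.write(line + "\n")


def write_popmap(dataset: SimulatedDataset, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for sid, pop in zip(dataset.sample_ids, dataset.populations):
            fh.write(f"{sid}\t{pop}\n")
        for sid in dataset.outgroup_ids:
            fh.write(f"{sid}\toutgroup\n")


def write_truth(dataset: SimulatedDataset, path: Path) -> None:
    dataset.sites.to_csv(path, sep="\t", index=False)


def write_outputs(dataset: SimulatedDataset, layout: GenomeLayout, out_dir) -> dict[str, Path]:
    """Write the full file set; returns the path of every artifact."""
    if layout.contig != dataset.layout.contig:
        raise ValueError("dataset and layout refer to different contigs")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fa",
        "cds": out / "annotation.gff3",
        "masks": out / "masks.bed",
        "vcf": out / "genotypes.vcf",
        "popmap": out / "popmap.tsv",
        "truth": out / "truth.tsv",
        "manifest": out / "simulation.json",
    }
    write_fasta(layout, paths["reference"])
    write_gff3(layout, paths["cds"])
    write_bed(layout.masks, layout.contig, paths["masks"])
    write_vcf(dataset, paths["vcf"])
    write_popmap(dataset, paths["popmap"])
    write_truth(dataset, paths["truth"])
    with open(paths["manifest"], "w") as fh:
        json.dump(dataset.truth, fh, indent=2, default=str)
    return paths
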