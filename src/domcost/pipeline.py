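"""End-to-end orchestration: simulate -> annotate -> load -> scan ->
demography, with a reproducibility manifest.

Each stage reads only files (or in-memory results of the previous stage's
files), so any stage can be re-run from disk.  A single root seed is fanned
out to named per-stage substreams; the manifest records seeds, wall-clock
and SHA-256 checksums of every artifact, and reruns with the same config
and seed produce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demofit, loadstats, sweepscan, varianno
from .io import (
    VariantData,
    read_bed,
    read_fasta_layout,
    read_popmap,
    read_vcf,
    write_bed,
    write_tsv,
)
from .simdata import SimulationConfig, domestication_bottleneck, simulate_two_population, write_outputs

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "STAGES"]

STAGES = ("simulate", "annotate", "load", "scan", "demography")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    roles: dict = field(
        default_factory=lambda: {
            "domestic": "domestic",
            "wild": "wild",
            "outgroup": "outgroup",
        }
    )
    simulate: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    load: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    demography: dict = field(default_factory=dict)
    # external inputs when the simulate stage is disabled
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if len(set(self.roles.values())) != len(self.roles):
            raise ValueError("population roles must be distinct")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


@dataclass
class RunManifest:
    tool: str
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _files(paths: dict) -> dict:
    return {k: _sha256(Path(p)) for k, p in paths.items() if Path(p).is_file()}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = RunManifest("domcost", cfg_hash, config.seed)

    paths = dict(config.inputs)  # may provide vcf/reference/cds/masks/popmap

    def require(key: str, stage: str):
        if key not in paths or not Path(paths[key]).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs '{key}' from an earlier stage or "
                "config.inputs, but it is missing"
            )
        return paths[key]

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        seed = _stage_seed(config.seed, stage)
        if stage == "simulate":
            sim_dir = out / "simulate"
            opts = dict(config.simulate)
            preset = opts.pop("preset", "domestication_bottleneck")
            if preset == "domestication_bottleneck":
                sim_cfg = domestication_bottleneck(seed=seed, **opts)
            else:
                sim_cfg = SimulationConfig(seed=seed, **opts)
            ds = simulate_two_population(sim_cfg)
            written = write_outputs(ds, ds.layout, sim_dir)
            paths.update({k: str(v) for k, v in written.items()})
            paths["annotation"] = paths.pop("cds")
            extra = {"n_sites": ds.n_sites}
        elif stage == "annotate":
            layout = read_fasta_layout(
                require("reference", stage),
                gff3_path=require("annotation", stage),
                bed_path=paths.get("masks"),
            )
            popmap = read_popmap(require("popmap", stage))
            data = read_vcf(require("vcf", stage), popmap)
            og_name = config.roles["outgroup"]
            pops = np.asarray([popmap.get(s) for s in data.samples])
            og_dos = data.genotypes[pops == og_name]
            ann = varianno.annotate_variants(
                data.variants.rename(columns={"aa": "aa_info"}),
                layout,
                outgroup_dosages=og_dos,
                seed=seed,
                **config.annotate,
            )
            paths["annotations"] = str(out / "annotations.tsv")
            write_tsv(ann, paths["annotations"])
            extra = {
                "n_variants": len(ann),
                "n_polarized": int(ann["polarized"].sum()),
                "n_hsnp": int(ann["is_hsnp"].sum()),
            }
        elif stage == "load":
            ann = pd.read_csv(require("annotations", stage), sep="\t")
            popmap = read_popmap(require("popmap", stage))
            data = read_vcf(require("vcf", stage), popmap)
            focal = [config.roles["wild"], config.roles["domestic"]]
            keep = np.asarray(ann["polarized"], bool)
            # derived dosage: flip where the ancestral allele is the alt
            flip = (ann["ancestral"] == ann["alt"]).to_numpy() & keep
            G = data.genotypes.copy()
            G[:, flip] = np.where(G[:, flip] >= 0, 2 - G[:, flip], -1)
            pops = np.asarray([popmap.get(s) for s in data.samples])
            focal_rows = np.isin(pops, focal)
            summaries = loadstats.individual_load(
                G[focal_rows][:, keep],
                (ann["is_hsnp"].to_numpy(bool))[keep],
                (ann["effect"] == "synonymous").to_numpy()[keep],
                [s for s, p in zip(data.samples, pops) if p in focal],
                {s: p for s, p in popmap.items() if p in focal},
            )
            profile = loadstats.population_load_profile(
                summaries,
                genotypes=G[focal_rows][:, keep],
                is_deleterious=(ann["is_hsnp"].to_numpy(bool))[keep],
                is_synonymous=(ann["effect"] == "synonymous").to_numpy()[keep],
                sample_populations=list(pops[focal_rows]),
            )
            comps = []
            for statistic in ("n_del_alleles", "del_syn_ratio", "het_del_fraction"):
                d = summaries.loc[
                    summaries["population"] == config.roles["domestic"], statistic
                ].dropna()
                w = summaries.loc[
                    summaries["population"] == config.roles["wild"], statistic
                ].dropna()
                c = loadstats.compare_groups(d, w, statistic_name=statistic)
                comps.append(asdict(c))
            paths["load_samples"] = str(out / "load_per_sample.tsv")
            paths["load_populations"] = str(out / "load_per_population.tsv")
            paths["load_comparisons"] = str(out / "load_comparisons.tsv")
            write_tsv(summaries, paths["load_samples"])
            write_tsv(profile, paths["load_populations"])
            write_tsv(pd.DataFrame(comps), paths["load_comparisons"])
            dom = profile.set_index("population")["mean_del_alleles"]
            extra = {
                "excess_pct": loadstats.load_excess(
                    dom.get(config.roles["domestic"], np.nan),
                    dom.get(config.roles["wild"], np.nan),
                )
            }
        elif stage == "scan":
            popmap = read_popmap(require("popmap", stage))
            data = read_vcf(require("vcf", stage), popmap)
            ann = pd.read_csv(require("annotations", stage), sep="\t")
            opts = dict(config.scan)
            window = int(opts.pop("window", 50_000))
            step = int(opts.pop("step", 25_000))
            quantile = float(opts.pop("quantile", 0.99))
            layout = read_fasta_layout(require("reference", stage))
            dom, wild, og = (
                config.roles["domestic"],
                config.roles["wild"],
                config.roles["outgroup"],
            )
            counts = {p: data.counts(p) for p in (dom, wild, og)}
            windows = sweepscan.scan_windows(
                data.variants["position"].to_numpy(),
                counts,
                layout.length,
                focal=dom,
                sister=wild,
                outgroup=og,
                window=window,
                step=step,
            )
            sweeps = sweepscan.call_sweeps(windows, "lsbl", quantile)
            hsnp = ann["is_hsnp"].to_numpy(bool) & ann["polarized"].to_numpy(bool)
            freqs = {}
            for p in (dom, wild):
                alt, called = counts[p]
                flip = (ann["ancestral"] == ann["alt"]).to_numpy()
                der = np.where(flip, called - alt, alt)
                with np.errstate(invalid="ignore"):
                    freqs[p] = (der / called)[hsnp]
            contrast = sweepscan.sweep_load_contrast(
                sweeps,
                data.variants["position"].to_numpy()[hsnp],
                freqs,
                layout.length,
                seed=seed,
                **opts,
            )
            paths["windows"] = str(out / "window_stats.tsv")
            paths["sweeps"] = str(out / "sweeps.bed")
            paths["sweep_contrast"] = str(out / "sweep_contrast.tsv")
            write_tsv(windows, paths["windows"])
            write_bed(sweeps.regions, layout.contig, paths["sweeps"])
            write_tsv(pd.DataFrame([asdict(contrast)]), paths["sweep_contrast"])
            extra = {"n_sweep_regions": len(sweeps.regions)}
        elif stage == "demography":
            layout = read_fasta_layout(
                require("reference", stage),
                gff3_path=paths.get("annotation"),
                bed_path=paths.get("masks"),
            )
            popmap = read_popmap(require("popmap", stage))
            data = read_vcf(require("vcf", stage), popmap)
            opts = dict(config.demography)
            min_len = int(opts.pop("min_len", 1000))
            models = tuple(opts.pop("models", ("A", "B", "C", "D")))
            project_to = opts.pop("project_to", None)
            exclude = [(c.start, c.end) for c in layout.cds] + list(layout.masks)
            regions, total_bp = demofit.build_neutral_mask(
                layout.length, exclude, min_len=min_len
            )
            wildn, domn = config.roles["wild"], config.roles["domestic"]
            d1, c1 = data.counts(wildn)
            d2, c2 = data.counts(domn)
            aa = data.variants["aa"].to_numpy()
            polarized = pd.notna(aa)
            flip = polarized & (aa == data.variants["alt"].to_numpy())
            d1 = np.where(flip, c1 - d1, d1)
            d2 = np.where(flip, c2 - d2, d2)
            sfs = demofit.joint_sfs(
                d1,
                c1,
                d2,
                c2,
                positions=data.variants["position"].to_numpy(),
                regions=regions,
                polarized=polarized,
                project_to=tuple(project_to) if project_to else None,
            )
            fits = demofit.fit.fit_models_nested(
                sfs, models, seed=seed, config=demofit.OptimizerConfig(**opts)
            )
            table = demofit.model_select(fits)
            paths["demography_fits"] = str(out / "demography_fits.json")
            paths["demography_table"] = str(out / "demography_models.tsv")
            with open(paths["demography_fits"], "w") as fh:
                json.dump([asdict(f) for f in fits], fh, indent=2, default=str)
            write_tsv(table, paths["demography_table"])
            extra = {"best_model": table.iloc[0]["model"], "n_sfs_sites": sfs.n_sites}
        manifest.stages[stage] = {
            "seed": seed,
            "seconds": round(time.time() - t0, 3),
            "outputs": _files(paths),
            **extra,
        }
    manifest.save(out / "manifest.json")
    return manifest
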