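"""End-to-end run: simulate -> BSA scan -> fine map -> panel -> summary.

One seed drives every stage through independent child generators, so a
run is fully reproducible: identical config + seed gives byte-identical
TSV/BED outputs and an identical summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import simulate as sim
from .bsa import BulkedSegregantScan
from .errors import ConfigError, StageError
from .mapping import (chisq_segregation, delimit_interval, find_recombinants,
                      panel_concordance)
from .simulate import SimConfig
from .variant_io import (SampleRoles, write_genotype_table, write_marker_info,
                         write_panel, write_phenotypes, write_vcf)

log = logging.getLogger("bulkmap.pipeline")


@dataclass(frozen=True)
class BsaParams:
    gq_min: int = 50
    window_bp: int = 200_000
    step_bp: int = 100_000
    threshold_mode: str = "quantile"
    n_sims: int = 2000
    level: int = 99
    require_ed2: bool = False
    merge_gap_bp: int = 2_000_000


@dataclass(frozen=True)
class FinemapParams:
    region_start_bp: int = 23_450_000
    region_end_bp: int = 24_220_000
    n_markers: int = 21
    n_f3: int = 847
    flank_left: str = "ST9"
    flank_right: str = "ST12"


@dataclass(frozen=True)
class PanelParams:
    n_green: int = 26
    n_yellow: int = 19
    discordant: int = 0


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (YAML-mirrorable)."""

    sim: SimConfig = field(default_factory=SimConfig)
    bsa: BsaParams = field(default_factory=BsaParams)
    finemap: FinemapParams = field(default_factory=FinemapParams)
    panel: PanelParams = field(default_factory=PanelParams)
    seed: int = 0
    out_dir: str = "bulkmap_run"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            kwargs = {}
            for name, sub_cls in (("sim", SimConfig), ("bsa", BsaParams),
                                  ("finemap", FinemapParams),
                                  ("panel", PanelParams)):
                if name in data:
                    kwargs[name] = sub_cls(**data[name])
            for name in ("seed", "out_dir"):
                if name in data:
                    kwargs[name] = data[name]
            unknown = set(data) - {"sim", "bsa", "finemap", "panel",
                                   "seed", "out_dir"}
            if unknown:
                raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def finemap_design(config: SimConfig, params: FinemapParams):
    """Regional marker map and heterozygous parent for the F3 stage.

    Builds a mini variant map holding the fine-mapping markers (evenly
    spaced over the region) plus the causal variant, and an F2 parent
    heterozygous across the whole region (the plants selected for selfing
    were heterozygous at the flanking markers).
    """
    if not (params.region_start_bp <= config.causal_pos_bp
            <= params.region_end_bp):
        raise ConfigError("fine-mapping region does not contain the causal locus")
    chrom = f"chr{config.causal_chrom + 1}"
    positions = np.round(np.linspace(params.region_start_bp,
                                     params.region_end_bp,
                                     params.n_markers)).astype(np.int64)
    labels = [f"ST{i + 1}" for i in range(len(positions))]
    all_pos = positions
    if config.causal_pos_bp not in positions:
        all_pos = np.sort(np.append(positions, config.causal_pos_bp))
    causal_index = int(np.searchsorted(all_pos, config.causal_pos_bp))
    vmap = sim.VariantMap(
        chrom_names=(chrom,),
        chrom_index=np.zeros(len(all_pos), dtype=np.int64),
        pos_bp=all_pos,
        pos_cM=all_pos / config.chrom_length_bp * config.chrom_length_cM,
        causal_index=causal_index,
    )
    marker_indices = np.array(
        [i for i, p in enumerate(all_pos) if p in set(positions.tolist())],
        dtype=np.int64)
    parent = sim.Individual(
        id="F2_het_parent",
        hap1=np.zeros(len(all_pos), dtype=np.int8),
        hap2=np.ones(len(all_pos), dtype=np.int8),
        phenotype="green",
    )
    return vmap, parent, marker_indices, labels


def run_all(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("bulkmap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler)
               and getattr(h, "stream", None) is sys.stderr
               for h in root.handlers):
        root.addHandler(logging.StreamHandler(sys.stderr))

    children = np.random.SeedSequence(config.seed).spawn(6)
    rngs = {name: np.random.default_rng(ss) for name, ss in
            zip(("f2", "bulks", "depths", "thresholds", "f3", "panel"),
                children)}
    roles = SampleRoles()
    summary: dict = {"seed": config.seed, "config": config.to_dict(),
                     "files": {}}
    files = summary["files"]

    def stage(name):
        log.info("stage %s", name)

    try:
        # ---- simulate --------------------------------------------------
        stage("simulate")
        population = sim.simulate_f2(config.sim, rng=rngs["f2"])
        green_ids, yellow_ids = sim.build_bulks(
            population.individuals, config.sim.bulk_size, rng=rngs["bulks"])
        records = sim.sample_pool_depths(green_ids, yellow_ids, population,
                                         rng=rngs["depths"], roles=roles)
        contigs = {name: config.sim.chrom_length_bp
                   for name in population.vmap.chrom_names}
        files["vcf"] = str(out / "variants.vcf")
        write_vcf(records, files["vcf"], sample_order=list(roles.as_tuple()),
                  contig_lengths=contigs)
        files["phenotypes"] = str(out / "f2_phenotypes.tsv")
        write_phenotypes(population.phenotypes(), files["phenotypes"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc

    try:
        # ---- segregation ----------------------------------------------
        stage("segregation")
        counts = population.phenotype_counts()
        chi2, p = chisq_segregation(counts["green"], counts["yellow"])
        summary["segregation"] = {
            "n_green": counts["green"], "n_yellow": counts["yellow"],
            "chi2": chi2, "p": p,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("segregation", str(exc)) from exc

    try:
        # ---- bsa -------------------------------------------------------
        stage("bsa")
        scan = BulkedSegregantScan(records, roles=roles,
                                   gq_min=config.bsa.gq_min,
                                   chrom_lengths=contigs)
        results = scan.fit(
            window_bp=config.bsa.window_bp, step_bp=config.bsa.step_bp,
            threshold_mode=config.bsa.threshold_mode,
            n_sims=config.bsa.n_sims, pool_size=config.sim.bulk_size,
            seed=rngs["thresholds"].integers(2 ** 31),
            require_ed2=config.bsa.require_ed2, level=config.bsa.level,
            merge_gap_bp=config.bsa.merge_gap_bp)
        files.update(results.save(out / "bsa"))
        files["plot"] = str(out / "bsa.manhattan.png")
        results.plot(path=files["plot"])
        summary["bsa"] = {
            "filter_report": results.filter_report.to_dict(),
            "threshold_mode": results.thresholds["mode"],
            "peaks": [{
                "chrom": pk.interval.chrom,
                "start": pk.interval.start, "end": pk.interval.end,
                "width_bp": pk.interval.width_bp,
                "max_mean_delta": pk.max_mean_delta,
                "max_mean_ed2": pk.max_mean_ed2,
                "n_windows": pk.n_windows,
            } for pk in results.peaks],
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("bsa", str(exc)) from exc

    try:
        # ---- finemap ---------------------------------------------------
        stage("finemap")
        vmap, parent, marker_indices, labels = finemap_design(
            config.sim, config.finemap)
        matrix = sim.simulate_f3_family(
            parent, vmap, config.finemap.n_f3, marker_indices,
            marker_labels=labels, rng=rngs["f3"], config=config.sim)
        files["f3_genotypes"] = str(out / "f3_genotypes.tsv")
        write_genotype_table(matrix, files["f3_genotypes"])
        files["f3_phenotypes"] = str(out / "f3_phenotypes.tsv")
        write_phenotypes(matrix.phenotypes, files["f3_phenotypes"])
        files["markers"] = str(out / "markers.tsv")
        write_marker_info(labels, [matrix.chrom] * len(labels),
                          matrix.positions, files["markers"])
        recombinants = find_recombinants(matrix, config.finemap.flank_left,
                                         config.finemap.flank_right)
        fine = delimit_interval(recombinants, matrix)
        summary["finemap"] = {
            "n_f3": matrix.n_individuals,
            "flanking_markers": [config.finemap.flank_left,
                                 config.finemap.flank_right],
            "n_recombinants": len(recombinants),
            "interval": {
                "chrom": fine.interval.chrom,
                "start": fine.interval.start, "end": fine.interval.end,
                "width_bp": fine.width_bp,
                "left_marker": fine.left_marker,
                "right_marker": fine.right_marker,
            },
        }
        files["finemap_bed"] = str(out / "finemap.bed")
        from .variant_io import write_bed
        write_bed([fine.interval], files["finemap_bed"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("finemap", str(exc)) from exc

    try:
        # ---- panel -----------------------------------------------------
        stage("panel")
        panel = sim.simulate_panel(config.panel.n_green, config.panel.n_yellow,
                                   config.panel.discordant, rng=rngs["panel"])
        files["panel"] = str(out / "panel.tsv")
        write_panel(panel, files["panel"])
        n_conc, n_total, perfect, fisher_p = panel_concordance(panel)
        summary["panel"] = {
            "n_concordant": n_conc, "n_total": n_total,
            "perfect": perfect, "fisher_p": fisher_p,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("panel", str(exc)) from exc

    files["summary"] = str(out / "summary.json")
    Path(files["summary"]).write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    root.removeHandler(handler)
    handler.close()
    return summary
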