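"""One-step driver: run any contiguous combination of stages from a config.

The configuration is flat ``key = value`` text (``#`` comments allowed).
Stages run in the fixed order mine -> stats -> plot -> design -> emap ->
export; each stage reads the artifacts of the previous one from the output
prefix, so a later stage can also be run alone against pre-existing files.
A manifest records the package version, the resolved parameters and the
products of the run.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

from . import __version__
from . import epcr as epcr_mod
from . import gff3, markers as markers_mod, mining, plotting, stats as stats_mod
from .sequence_io import PathLike, read_fasta

log = logging.getLogger("ssrforge")

STAGE_ORDER = ["mine", "stats", "plot", "design", "emap", "export"]


class PipelineError(RuntimeError):
    """Missing upstream artifact or bad configuration."""


def parse_config(path: PathLike) -> Dict[str, str]:
    """Parse flat ``key = value`` settings; later keys override earlier."""
    settings: Dict[str, str] = {}
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise PipelineError(f"{path}:{line_no}: expected key = value")
        key, value = line.split("=", 1)
        settings[key.strip()] = value.strip()
    return settings


@dataclass
class PipelineConfig:
    """Resolved settings for a run; every field has a schema key."""

    fasta: str
    out_prefix: str
    stages: List[str] = field(default_factory=lambda: list(STAGE_ORDER))
    min_repeats: Dict[int, int] = field(
        default_factory=lambda: dict(mining.DEFAULT_MIN_REPEATS)
    )
    chunk_size: int = mining.DEFAULT_CHUNK_SIZE
    overlap: int = mining.DEFAULT_OVERLAP
    keep_contained: bool = False
    freq_scale: int = stats_mod.DEFAULT_FREQ_SCALE
    flank: int = 400
    product_min: int = 100
    product_max: int = 400
    tm: float = 60.0
    mismatches: int = 0
    margin: Optional[int] = None
    targets_fasta: Optional[str] = None
    formats: List[str] = field(default_factory=lambda: ["png", "svg"])

    @classmethod
    def from_settings(cls, settings: Mapping[str, str]) -> "PipelineConfig":
        if "fasta" not in settings or "out_prefix" not in settings:
            raise PipelineError("config must set 'fasta' and 'out_prefix'")
        kwargs: Dict[str, object] = {
            "fasta": settings["fasta"],
            "out_prefix": settings["out_prefix"],
        }
        if "stages" in settings:
            stages = [s.strip() for s in settings["stages"].split(",") if s.strip()]
            bad = [s for s in stages if s not in STAGE_ORDER]
            if bad:
                raise PipelineError(f"unknown stages {bad}; choose from {STAGE_ORDER}")
            kwargs["stages"] = sorted(stages, key=STAGE_ORDER.index)
        if "min_repeats" in settings:
            kwargs["min_repeats"] = mining.parse_min_repeats(settings["min_repeats"])
        for key, conv in [
            ("chunk_size", int),
            ("overlap", int),
            ("freq_scale", int),
            ("flank", int),
            ("product_min", int),
            ("product_max", int),
            ("tm", float),
            ("mismatches", int),
            ("margin", int),
        ]:
            if key in settings:
                kwargs[key] = conv(settings[key])
        if "keep_contained" in settings:
            kwargs["keep_contained"] = settings["keep_contained"].lower() in (
                "1",
                "true",
                "yes",
            )
        if "targets_fasta" in settings:
            kwargs["targets_fasta"] = settings["targets_fasta"]
        if "formats" in settings:
            kwargs["formats"] = [
                f.strip() for f in settings["formats"].split(",") if f.strip()
            ]
        return cls(**kwargs)  # type: ignore[arg-type]


def _require(path: Path, stage: str, hint: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{stage}' needs {path.name} ({hint}); run that stage first"
        )
    return path


def run_pipeline(config: PipelineConfig) -> Dict[str, str]:
    """Execute the configured stages; returns a map of artifact -> path."""
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    produced: Dict[str, str] = {}
    records = read_fasta(config.fasta)
    rec_list = list(records)

    ssr_path = prefix.with_suffix(".ssr")
    sat1_path = prefix.with_suffix(".sat1")
    sat2_path = prefix.with_suffix(".sat2")
    mk_path = prefix.with_suffix(".mk")
    sts_path = prefix.with_suffix(".sts")
    amp_path = prefix.with_suffix(".amp")
    frg_path = prefix.with_suffix(".frg")
    emap_path = prefix.with_suffix(".emap")
    sat4_path = prefix.with_suffix(".sat4")
    gff_path = prefix.with_suffix(".gff3")

    if "mine" in config.stages:
        cfg = mining.MiningConfig(
            min_repeats=config.min_repeats,
            chunk_size=config.chunk_size,
            overlap=config.overlap,
            containment_filter=not config.keep_contained,
        )
        loci, summary = mining.mine_genome(rec_list, cfg)
        mining.write_ssr(loci, ssr_path)
        mining.write_sat1(summary, sat1_path)
        produced[".ssr"] = str(ssr_path)
        produced[".sat1"] = str(sat1_path)
        log.info("mine: %d loci over %d sequences", summary.n_loci, summary.n_sequences)

    if "stats" in config.stages:
        loci = mining.read_ssr(_require(ssr_path, "stats", "locus table"))
        report = stats_mod.compute_stats(loci, rec_list, scale=config.freq_scale)
        stats_mod.write_sat2(report, sat2_path)
        produced[".sat2"] = str(sat2_path)
        log.info("stats: report written")

    if "plot" in config.stages:
        report = stats_mod.read_sat2(_require(sat2_path, "plot", "statistics report"))
        plot_cfg = plotting.PlotConfig(
            outdir=str(prefix.parent / (prefix.name + "_plots")),
            formats=config.formats,
        )
        paths = plotting.plot_all(report, plot_cfg)
        produced["plots"] = str(plot_cfg.outdir)
        log.info("plot: %d images", len(paths))

    if "design" in config.stages:
        loci = mining.read_ssr(_require(ssr_path, "design", "locus table"))
        params = markers_mod.PrimerParams(
            flank=config.flank,
            product_min=config.product_min,
            product_max=config.product_max,
            tm_opt=config.tm,
            tm_min=config.tm - 3,
            tm_max=config.tm + 3,
        )
        designed, failures = markers_mod.design_all(loci, rec_list, params)
        marker_set = markers_mod.deduplicate_markers(designed)
        markers_mod.write_sts(marker_set, sts_path)
        markers_mod.write_mk(marker_set, mk_path)
        produced[".sts"] = str(sts_path)
        produced[".mk"] = str(mk_path)
        log.info(
            "design: %d markers from %d loci (%d failures)",
            len(marker_set),
            len(loci),
            len(failures),
        )

    if "emap" in config.stages:
        marker_set = markers_mod.read_sts(_require(sts_path, "emap", "marker table"))
        targets = (
            read_fasta(config.targets_fasta) if config.targets_fasta else rec_list
        )
        eparams = epcr_mod.EpcrParams(
            max_mismatches=config.mismatches, size_margin=config.margin
        )
        amplicons = epcr_mod.epcr(marker_set, targets, eparams)
        matrix, _ = epcr_mod.score_polymorphism(amplicons, marker_set, targets)
        summary4 = epcr_mod.summarize_mapping(amplicons, marker_set, targets)
        epcr_mod.write_amp(amplicons, amp_path)
        epcr_mod.write_frg(matrix, frg_path)
        epcr_mod.write_emap(amplicons, targets, emap_path)
        epcr_mod.write_sat4(summary4, sat4_path)
        produced[".amp"] = str(amp_path)
        produced[".frg"] = str(frg_path)
        produced[".emap"] = str(emap_path)
        produced[".sat4"] = str(sat4_path)
        log.info("emap: %d amplicons", summary4.total_amplicons)

    if "export" in config.stages:
        loci = mining.read_ssr(_require(ssr_path, "export", "locus table"))
        gff3.loci_to_gff3(loci, gff_path)
        produced[".gff3"] = str(gff_path)
        if sts_path.exists() and amp_path.exists():
            marker_set = markers_mod.read_sts(sts_path)
            amplicons = epcr_mod.read_amp(amp_path)
            marker_gff = prefix.parent / (prefix.name + ".markers.gff3")
            gff3.markers_to_gff3(marker_set, amplicons, marker_gff)
            produced[".markers.gff3"] = str(marker_gff)
        log.info("export: browser tracks written")

    manifest = {
        "version": __version__,
        "config": {
            k: (v if not isinstance(v, dict) else {str(a): b for a, b in v.items()})
            for k, v in vars(config).items()
        },
        "produced": produced,
    }
    manifest_path = prefix.parent / (prefix.name + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    produced["manifest"] = str(manifest_path)
    return produced
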