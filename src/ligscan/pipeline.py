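"""End-to-end orchestration: design → simulate → count → activity → kinetics.

A :class:`RunConfig` (a flat YAML-friendly dictionary of per-stage blocks)
drives :func:`run_pipeline`, which executes the enabled stages in order,
writes every intermediate artifact to the output directory, and records a
manifest (package version, seeds, input digests, per-stage counters) so a
run can be reproduced byte-for-byte from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .design import (
    assemble_oligos,
    build_library,
    read_variant_table,
    write_oligo_fasta,
    write_variant_table,
)
from .reads import CountTable, count_variants, read_fastq, write_fastq
from .activity import activity_table
from .simulate import (
    SimulationConfig,
    sample_activity_landscape,
    simulate_reads,
    write_truth_table,
)
from .templates import f1star_template, minf1_template

logger = logging.getLogger("ligscan")

TEMPLATES = {"f1star": f1star_template, "minf1": minf1_template}
STAGES = ("design", "simulate", "count", "activity")


@dataclass
class RunConfig:
    """Flat pipeline configuration; unknown stages are rejected up front."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    template: str = "f1star"
    classes: list[str] = field(default_factory=lambda: ["sub1", "sub2"])
    preset: str = "f1star-like"
    depth: int = 200
    error_rate: float = 0.001
    seed: int = 0
    policy: str = "f1star"
    min_reads: int = 20
    wt_id: str = "WT"
    write_fastq: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        order = [s for s in STAGES if s in self.stages]
        if order != self.stages:
            raise ValueError("stages must be in pipeline order")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest.

    Stage failures abort the run: the manifest written so far is saved as
    ``manifest.partial.json`` with the failing stage named, and the
    exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ligscan_version": __version__,
        "config": {k: getattr(config, k) for k in vars(config)},
        "stages": {},
    }
    state: dict = {}
    stage = None
    try:
        for stage in config.stages:
            logger.info("running stage %s", stage)
            _STAGE_FNS[stage](config, outdir, state, manifest)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.partial.json").write_text(json.dumps(manifest, indent=2))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_design(config: RunConfig, outdir: Path, state: dict, manifest: dict) -> None:
    template = TEMPLATES[config.template]()
    library = build_library(template, config.classes)
    write_variant_table(library, outdir / "variants.tsv")
    write_oligo_fasta(assemble_oligos(library), outdir / "oligos.fasta")
    state["library"] = library
    manifest["stages"]["design"] = {
        "template": template.name,
        "n_variants": len(library),
        "variant_table": _digest(outdir / "variants.tsv"),
    }


def _require_library(config: RunConfig, outdir: Path, state: dict):
    if "library" not in state:
        path = outdir / "variants.tsv"
        if not path.exists():
            raise FileNotFoundError(
                "no design stage in this run and no variants.tsv in the output dir"
            )
        state["library"] = read_variant_table(path, TEMPLATES[config.template]())
    return state["library"]


def _stage_simulate(config: RunConfig, outdir: Path, state: dict, manifest: dict) -> None:
    library = _require_library(config, outdir, state)
    truth = sample_activity_landscape(library, config.preset, seed=config.seed)
    write_truth_table(truth, outdir / "truth.tsv")
    sim = SimulationConfig(
        depth=config.depth, error_rate=config.error_rate, seed=config.seed
    )
    state["sim_config"] = sim
    if config.write_fastq:
        n = write_fastq(simulate_reads(truth, library, sim), outdir / "reads.fastq.gz")
    else:
        n = None  # reads re-generated in-memory by the count stage
    state["truth"] = truth
    manifest["stages"]["simulate"] = {
        "preset": config.preset,
        "seed": config.seed,
        "depth": config.depth,
        "error_rate": config.error_rate,
        "n_reads_written": n,
    }


def _stage_count(config: RunConfig, outdir: Path, state: dict, manifest: dict) -> None:
    library = _require_library(config, outdir, state)
    sim = state.get("sim_config") or SimulationConfig(
        depth=config.depth, error_rate=config.error_rate, seed=config.seed
    )
    fastq = outdir / "reads.fastq.gz"
    if config.write_fastq and fastq.exists():
        reads = read_fastq(fastq)
    elif "truth" in state:
        reads = simulate_reads(state["truth"], library, sim)
    else:
        raise FileNotFoundError("count stage needs simulated reads or a FASTQ file")
    counts = count_variants(reads, library, sim.layout, sim.demux_table, config.policy)
    if not counts.check_partition():
        raise RuntimeError("read-partition invariant violated")
    counts.write(outdir / "counts.tsv")
    state["counts"] = counts
    manifest["stages"]["count"] = counts.summary()


def _stage_activity(config: RunConfig, outdir: Path, state: dict, manifest: dict) -> None:
    counts = state.get("counts")
    if counts is None:
        path = outdir / "counts.tsv"
        if not path.exists():
            raise FileNotFoundError("activity stage needs a counts.tsv")
        counts = CountTable.read(path)
    table = activity_table(counts, wt_id=config.wt_id, min_reads=config.min_reads)
    table.to_csv(outdir / "activity.tsv", sep="\t")
    manifest["stages"]["activity"] = {
        "n_variants": int(table.shape[0]),
        "wt_fl": float(table.loc[config.wt_id, "fl"]),
        "activity_table": _digest(outdir / "activity.tsv"),
    }


_STAGE_FNS = {
    "design": _stage_design,
    "simulate": _stage_simulate,
    "count": _stage_count,
    "activity": _stage_activity,
}
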