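"""Synthetic ground-truth landscapes, barcoded read sets, and time courses.

The real screens' raw reads are not redistributed with this package, so
every analysis stage is exercised against simulated data with known truth:

* :func:`sample_activity_landscape` draws a per-variant true fraction
  ligated (FL_true) from a preset mixture that mimics the observed shape of
  the landscapes — a large near-wild-type class, a near-zero (inactive)
  class, and a uniform middle.
* :func:`simulate_reads` emits single-end amplicon reads for each variant:
  pool barcode + constant 5' flank + variant core (as cDNA) + constant 3'
  flank, with each read's ligated/unligated fate drawn Bernoulli(FL_true),
  iid substitution sequencing errors, and discretized-Gaussian Phred
  qualities. Indel errors are not modeled: exact-sequence counting discards
  any error read regardless of error type, so substitutions alone reproduce
  the loss process that matters.
* :func:`simulate_timecourse` draws noisy observations from the
  exponential-saturation ligation model.

All randomness flows from the single seed in the config; identical inputs
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .design import DesignLibrary
from .kinetics import TimeCourse, exponential_fl
from .reads import DEFAULT_DEMUX_TABLE, LIGATED, ReadLayout, SequencingRead
from .templates import rna_to_dna

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Constant amplicon flanks used by the default synthetic layout. These are
#: arbitrary fixed sequences standing in for the run-specific adapter +
#: constant ribozyme regions of a real amplicon design.
DEFAULT_FLANK_5 = "ACTGGCCGTCGTTTTA"
DEFAULT_FLANK_3 = "CGCTTGGCGTAATCAT"


def default_read_layout() -> ReadLayout:
    """Barcode at the read start, then 5' flank, core, 3' flank."""
    return ReadLayout(
        flank_5=DEFAULT_FLANK_5,
        flank_3=DEFAULT_FLANK_3,
        barcode_start=0,
        barcode_length=8,
    )


@dataclass
class TruthMap:
    """Ground-truth FL per variant, with its generating preset and seed."""

    fl_true: dict[str, float]
    preset: str
    seed: int

    def __post_init__(self) -> None:
        bad = [v for v, f in self.fl_true.items() if not 0 <= f <= 1]
        if bad:
            raise ValueError(f"FL_true outside [0,1] for {bad[:3]}")

    def __getitem__(self, variant_id: str) -> float:
        return self.fl_true[variant_id]

    def __len__(self) -> int:
        return len(self.fl_true)


#: Landscape presets: (wild-type FL, weight of the near-WT high class,
#: weight of the near-zero class; the remainder is uniform mid-activity).
#: `f1star-like` mimics a highly mutation-tolerant parent (wild-type
#: FL 0.826, ~66% of variants within >0.90 relative activity, ~6% inactive);
#: `minf1-like` a minimized, fragile one (wild-type FL 0.76, sparser high
#: class). `all-wt` gives every variant the wild-type FL.
PRESETS: dict[str, tuple[float, float, float]] = {
    "f1star-like": (0.826, 0.66, 0.06),
    "minf1-like": (0.76, 0.25, 0.45),
    "all-wt": (0.826, 1.0, 0.0),
}


def sample_activity_landscape(
    library: DesignLibrary,
    preset: str = "f1star-like",
    seed: int = 0,
    fl_wt: float | None = None,
) -> TruthMap:
    """Draw FL_true for every library variant from a preset mixture.

    High-class variants draw a relative activity 0.90 + 0.31·Beta(2,2)
    (strictly above the 0.90 class boundary), near-zero ones
    0.10·Beta(1,3), and the rest Uniform(0.10, 0.90); FL_true is the
    relative activity times the wild-type FL, clipped to [0, 1]. The WT
    entry is pinned to the preset's wild-type FL exactly.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    preset_wt, w_high, w_zero = PRESETS[preset]
    wt_fl = preset_wt if fl_wt is None else fl_wt
    rng = np.random.default_rng(seed)
    fl_true: dict[str, float] = {}
    for rec in library:
        if rec.variant_id == "WT" or preset == "all-wt":
            fl_true[rec.variant_id] = wt_fl
            continue
        u = rng.random()
        if u < w_high:
            ra = 0.90 + 0.31 * rng.beta(2.0, 2.0)
        elif u < w_high + w_zero:
            ra = 0.10 * rng.beta(1.0, 3.0)
        else:
            ra = rng.uniform(0.10, 0.90)
        fl_true[rec.variant_id] = float(np.clip(ra * wt_fl, 0.0, 1.0))
    return TruthMap(fl_true, preset, seed)


@dataclass
class SimulationConfig:
    """Read-simulation parameters: coverage, error model, quality model."""

    depth: int = 200
    error_rate: float = 0.001
    qs_mean: float = 37.0
    qs_sd: float = 4.0
    layout: ReadLayout = field(default_factory=default_read_layout)
    demux_table: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DEMUX_TABLE))
    seed: int = 0
    depth_distribution: str = "fixed"  # or "poisson"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.depth_distribution not in ("fixed", "poisson"):
            raise ValueError("depth_distribution must be 'fixed' or 'poisson'")


def _mutate_and_qualify(
    template_codes: np.ndarray, n: int, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-read substitution errors and Phred qualities."""
    length = template_codes.size
    bases = np.broadcast_to(template_codes, (n, length)).copy()
    if cfg.error_rate > 0:
        err = rng.random((n, length)) < cfg.error_rate
        k = int(err.sum())
        if k:
            # replace with one of the three other bases, uniformly
            idx = np.searchsorted(_DNA, bases[err])
            shift = rng.integers(1, 4, size=k)
            bases[err] = _DNA[(idx + shift) % 4]
    qs = np.rint(rng.normal(cfg.qs_mean, cfg.qs_sd, (n, length)))
    qs = np.clip(qs, 2, 41).astype(np.int16)  # floor at QS 2, Illumina-style cap
    return bases, qs


def simulate_reads(
    truth: TruthMap, library: DesignLibrary, config: SimulationConfig
) -> Iterator[SequencingRead]:
    """Yield synthetic amplicon reads for every variant in the truth map.

    Per variant, the number of reads is ``depth`` (or Poisson(depth)); each
    read's pool fate is Bernoulli(FL_true) and selects the barcode; bases
    and qualities come from :func:`_mutate_and_qualify`. Reads are emitted
    in library order so a fixed seed reproduces the stream exactly.
    """
    missing = [v for v in truth.fl_true if v not in {r.variant_id for r in library}]
    if missing:
        raise ValueError(f"truth variants absent from library: {missing[:3]}")
    rng = np.random.default_rng(config.seed)
    by_fate: dict[str, str] = {}
    for barcode, fate in config.demux_table.items():
        by_fate.setdefault(fate, barcode)
    layout = config.layout
    for rec in library:
        if rec.variant_id not in truth.fl_true:
            continue
        fl_true = truth.fl_true[rec.variant_id]
        n = (
            config.depth
            if config.depth_distribution == "fixed"
            else int(rng.poisson(config.depth))
        )
        if n == 0:
            continue
        fates = rng.random(n) < fl_true
        core_dna = rna_to_dna(rec.core_sequence)
        templates = {}
        for fate, barcode in by_fate.items():
            amplicon = barcode + layout.flank_5 + core_dna + layout.flank_3
            templates[fate] = np.frombuffer(amplicon.encode(), dtype=np.uint8)
        for fate_name, sel in ((LIGATED, fates), ("unligated", ~fates)):
            m = int(sel.sum())
            if m == 0:
                continue
            bases, qs = _mutate_and_qualify(templates[fate_name], m, config, rng)
            read_nums = np.nonzero(sel)[0]
            for row, q_row, i in zip(bases, qs, read_nums):
                yield SequencingRead(
                    f"{rec.variant_id}|{i}",
                    row.tobytes().decode("ascii"),
                    q_row,
                )


def write_truth_table(truth: TruthMap, path) -> None:
    """Write the ground-truth map as TSV (variant_id, fl_true)."""
    import pandas as pd

    pd.DataFrame(
        {"variant_id": list(truth.fl_true), "fl_true": list(truth.fl_true.values())}
    ).to_csv(path, sep="\t", index=False)


def simulate_timecourse(
    k_obs: float,
    f_max: float,
    times,
    noise_sd: float = 0.02,
    replicates: int = 3,
    seed: int = 0,
    unit: str = "min",
) -> TimeCourse:
    """Noisy draws from FL(t) = F_max(1 - e^{-k t}), clamped to [0, 1]."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    all_t = np.tile(times, replicates)
    rep = np.repeat(np.arange(replicates), times.size)
    clean = exponential_fl(all_t, k_obs, f_max)
    noisy = np.clip(clean + rng.normal(0.0, noise_sd, clean.shape), 0.0, 1.0)
    return TimeCourse(all_t, noisy, unit, rep)
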