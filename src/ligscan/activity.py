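"""Per-variant activity statistics and mutational-landscape analytics.

The assay reads out, for each variant, how many sequencing reads came from
the ligated and unligated gel bands at a single reaction end point. The
fraction ligated

    FL = N_lig / (N_lig + N_unlig)

estimates the per-molecule ligation probability at that end point, and the
relative activity RA = FL / FL_wt normalizes it to the parental ribozyme.
RA is semi-quantitative: at a 30-min end point any variant with a rate
constant above roughly 0.1 min⁻¹ saturates near RA ≈ 1, so RA separates
damaged variants from near-wild-type ones rather than ranking fast ones.

On top of the per-variant table this module builds the landscape views used
to reason about structure: per-position single-mutant effect maps, the
upper-triangular double-mutant matrix, deletion-tolerance tables that expand
deduplicated deletion records back onto positions, compensatory
(rescue) pair detection, and Watson-Crick/wobble base-pair inference from
those rescues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .design import DesignLibrary
from .reads import CountTable

#: Base combinations read as helix-compatible pairs.
WATSON_CRICK_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

DEFAULT_CLASS_THRESHOLDS = (0.90, 0.50, 0.10)
CLASS_LABELS = ("high", "active", "partial", "inactive")


@dataclass
class ActivityRecord:
    """FL/RA and uncertainty for one variant."""

    variant_id: str
    n_lig: int
    n_unlig: int
    fl: float | None
    ci_low: float | None
    ci_high: float | None
    flagged_low_coverage: bool
    ra: float | None = None
    activity_class: str | None = None


def compute_fraction_ligated(
    n_lig: int, n_unlig: int, min_reads: int = 20
) -> tuple[float | None, float | None, float | None, bool]:
    """FL with a Wilson 95% interval and a low-coverage flag.

    Returns ``(fl, ci_low, ci_high, flagged)``. FL is ``None`` (missing)
    when the variant has no reads at all; below ``min_reads`` total reads
    the estimate is flagged but still reported.
    """
    if n_lig < 0 or n_unlig < 0:
        raise ValueError("read counts must be non-negative")
    total = n_lig + n_unlig
    if total == 0:
        return None, None, None, True
    fl = n_lig / total
    lo, hi = proportion_confint(n_lig, total, alpha=0.05, method="wilson")
    # guard against float round-off at the 0/n and n/n boundaries
    lo = min(max(float(lo), 0.0), fl)
    hi = max(min(float(hi), 1.0), fl)
    return fl, lo, hi, total < min_reads


def compute_relative_activity(fl: float, fl_wt: float) -> float:
    """RA = FL / FL_wt; the wild-type maps to exactly 1."""
    if fl_wt <= 0:
        raise ValueError("wild-type FL must be positive to normalize")
    return fl / fl_wt


def classify_activity(
    ra: float, thresholds: Sequence[float] = DEFAULT_CLASS_THRESHOLDS
) -> str:
    """Bin RA into high (>t0), active (t1, t0], partial [t2, t1], inactive (<t2).

    With the default cutoffs (0.90, 0.50, 0.10) the upper comparisons are
    strict — RA = 0.90 is "active", not "high" — and "inactive" is the strict
    RA < 0.10 bin.
    """
    if ra < 0:
        raise ValueError("RA must be non-negative")
    t0, t1, t2 = thresholds
    if not t0 > t1 > t2:
        raise ValueError("thresholds must be strictly decreasing")
    if ra > t0:
        return "high"
    if ra > t1:
        return "active"
    if ra >= t2:
        return "partial"
    return "inactive"


def activity_table(
    counts: CountTable,
    wt_id: str = "WT",
    min_reads: int = 20,
    thresholds: Sequence[float] = DEFAULT_CLASS_THRESHOLDS,
) -> pd.DataFrame:
    """Per-variant FL, Wilson CI, RA and activity class as a DataFrame.

    RA is normalized to the observed wild-type FL, which therefore comes out
    as exactly 1.
    """
    wt_fl, *_ = compute_fraction_ligated(
        counts.n_lig(wt_id), counts.n_unlig(wt_id), min_reads
    )
    if wt_fl is None or wt_fl <= 0:
        raise ValueError(f"wild-type {wt_id!r} has no usable reads; cannot normalize")
    rows = []
    for vid, (n_lig, n_unlig) in counts.counts.items():
        fl, lo, hi, flagged = compute_fraction_ligated(n_lig, n_unlig, min_reads)
        ra = None if fl is None else compute_relative_activity(fl, wt_fl)
        rows.append(
            {
                "variant_id": vid,
                "n_lig": n_lig,
                "n_unlig": n_unlig,
                "fl": fl,
                "ci_low": lo,
                "ci_high": hi,
                "flagged_low_coverage": flagged,
                "ra": ra,
                "activity_class": None if ra is None else classify_activity(ra, thresholds),
            }
        )
    return pd.DataFrame(rows).set_index("variant_id")


def _ra_mapping(records) -> dict[str, float]:
    """Accept an activity DataFrame or a plain variant_id→RA mapping."""
    if isinstance(records, pd.DataFrame):
        return {k: v for k, v in records["ra"].items() if v is not None and not np.isnan(v)}
    return dict(records)


_SUB_RE = re.compile(r"^[ACGU]\d+[ACGU]$")
_DEL_RE = re.compile(r"^[ACGU]\d+del$")


def _parse_sub(edit: str) -> tuple[int, str, str]:
    """'U23G' → (23, 'U', 'G')."""
    return int(edit[1:-1]), edit[0], edit[-1]


def _parse_del(edit: str) -> tuple[int, str]:
    """'A26del' → (26, 'A')."""
    return int(edit[1:-3]), edit[0]


def single_mutant_effect_map(records, library: DesignLibrary) -> pd.DataFrame:
    """Position × alternative grid of single-mutant RA values.

    Rows are template positions, columns the three non-wild-type bases plus
    ``del``; entries missing from the data stay NaN. Deletion records that
    collapsed several equivalent positions are expanded so every collapsed
    position shows the shared RA.
    """
    ra = _ra_mapping(records)
    positions = sorted(library.template.mutable_positions)
    grid = pd.DataFrame(
        np.nan, index=positions, columns=["A", "C", "G", "U", "del"]
    )
    for rec in library.by_class("sub1"):
        if rec.variant_id not in ra:
            continue
        for label in rec.source_labels:
            if not _SUB_RE.match(label):
                continue
            pos, _, alt = _parse_sub(label)
            grid.loc[pos, alt] = ra[rec.variant_id]
    for rec in library.by_class("del1"):
        if rec.variant_id not in ra:
            continue
        for label in rec.source_labels:
            if not _DEL_RE.match(label):
                continue
            pos, _ = _parse_del(label)
            grid.loc[pos, "del"] = ra[rec.variant_id]
    wt = library.template.sequence
    for pos in positions:  # the wild-type base is not an alternative
        grid.loc[pos, wt[pos - 1]] = np.nan
    return grid


def double_mutant_matrix(records, library: DesignLibrary) -> dict:
    """Upper-triangular map (pos_i, base_i, pos_j, base_j) → RA, i < j.

    Each double substitution is stored once with ``pos_i < pos_j``; the
    (j, i) view is implied by symmetry.
    """
    ra = _ra_mapping(records)
    matrix: dict[tuple[int, str, int, str], float] = {}
    for rec in library.by_class("sub2"):
        if rec.variant_id not in ra:
            continue
        a, b = rec.variant_id.split("/")
        pi, _, bi = _parse_sub(a)
        pj, _, bj = _parse_sub(b)
        if pi > pj:
            (pi, bi), (pj, bj) = (pj, bj), (pi, bi)
        matrix[(pi, bi, pj, bj)] = ra[rec.variant_id]
    return matrix


def pair_type(base_a: str, base_b: str) -> str:
    """Classify two bases as Watson-Crick, wobble, or other."""
    if (base_a, base_b) in WATSON_CRICK_PAIRS:
        return "Watson-Crick"
    if (base_a, base_b) in WOBBLE_PAIRS:
        return "wobble"
    return "other"


@dataclass(frozen=True)
class CompensatoryPair:
    """Two individually deleterious substitutions whose combination rescues."""

    mutation_a: str
    mutation_b: str
    ra_a: float
    ra_b: float
    ra_ab: float
    pair_type: str


def detect_compensatory_pairs(
    records,
    library: DesignLibrary,
    single_cutoff: float = 0.10,
    rescue_margin: float = 0.20,
) -> list[CompensatoryPair]:
    """Find rescue pairs: both singles below cutoff, double well above both.

    A pair qualifies when RA(a) < cutoff, RA(b) < cutoff, and
    RA(ab) ≥ max(RA(a), RA(b)) + margin. The two *mutant* bases are
    classified as Watson-Crick / wobble / other, the covariation signal used
    to infer helices. Output is sorted by variant id, hence independent of
    input record order.
    """
    ra = _ra_mapping(records)
    singles: dict[str, float] = {}
    for rec in library.by_class("sub1"):
        if rec.variant_id in ra:
            singles[rec.variant_id] = ra[rec.variant_id]
    pairs = []
    for rec in sorted(library.by_class("sub2"), key=lambda r: r.variant_id):
        if rec.variant_id not in ra:
            continue
        a, b = rec.variant_id.split("/")
        if a not in singles or b not in singles:
            continue
        ra_a, ra_b, ra_ab = singles[a], singles[b], ra[rec.variant_id]
        if ra_a < single_cutoff and ra_b < single_cutoff:
            if ra_ab >= max(ra_a, ra_b) + rescue_margin:
                _, _, base_a = _parse_sub(a)
                _, _, base_b = _parse_sub(b)
                pairs.append(
                    CompensatoryPair(a, b, ra_a, ra_b, ra_ab, pair_type(base_a, base_b))
                )
    return pairs


def infer_paired_positions(
    pairs: Sequence[CompensatoryPair], min_support: int = 1
) -> list[tuple[int, int, int]]:
    """Position pairs supported by ≥ min_support helix-compatible rescues.

    Only rescues whose mutant bases form Watson-Crick or wobble pairs count
    as support; rescues through non-pairing bases may reflect tertiary
    contacts and are excluded. Returns (pos_i, pos_j, support) with i < j,
    sorted by position.
    """
    support: dict[tuple[int, int], int] = {}
    for p in pairs:
        if p.pair_type == "other":
            continue
        pi, _, _ = _parse_sub(p.mutation_a)
        pj, _, _ = _parse_sub(p.mutation_b)
        key = (min(pi, pj), max(pi, pj))
        support[key] = support.get(key, 0) + 1
    return sorted(
        (i, j, n) for (i, j), n in support.items() if n >= min_support
    )


def deletion_tolerance_map(
    records, library: DesignLibrary, max_order: int = 3, threshold: float = 0.90
) -> dict:
    """Deletion-tolerance views per order, expanding deduplicated records.

    Returns ``{1: Series position→RA, 2: DataFrame position×position
    (diagonal = single deletions), 3: {"n", "n_above", "fraction_above"}}``
    up to ``max_order``. A merged record (several equivalent deletion label
    sets) fills every position (combination) it collapsed with the same RA.
    """
    ra = _ra_mapping(records)
    positions = sorted(library.template.mutable_positions)
    out: dict[int, object] = {}
    if max_order >= 1:
        vec = pd.Series(np.nan, index=positions)
        for rec in library.by_class("del1"):
            if rec.variant_id not in ra:
                continue
            for label in rec.source_labels:
                if not _DEL_RE.match(label):
                    continue
                pos, _ = _parse_del(label)
                vec.loc[pos] = ra[rec.variant_id]
        out[1] = vec
    if max_order >= 2:
        mat = pd.DataFrame(np.nan, index=positions, columns=positions)
        for rec in library.by_class("del2"):
            if rec.variant_id not in ra:
                continue
            for label in rec.source_labels:
                edits = label.split("/")
                if not all(_DEL_RE.match(e) for e in edits):
                    continue
                (pa, _), (pb, _) = (_parse_del(e) for e in edits)
                i, j = min(pa, pb), max(pa, pb)
                mat.loc[i, j] = ra[rec.variant_id]
        if 1 in out:  # diagonal carries the single deletions
            for pos, val in out[1].items():
                mat.loc[pos, pos] = val
        out[2] = mat
    if max_order >= 3:
        values = [
            ra[rec.variant_id]
            for rec in library.by_class("del3")
            if rec.variant_id in ra
        ]
        n_above = sum(v > threshold for v in values)
        out[3] = {
            "n": len(values),
            "n_above": n_above,
            "fraction_above": (n_above / len(values)) if values else float("nan"),
        }
    return out
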