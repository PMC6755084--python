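"""Sequencing-read processing: quality filters, demultiplexing, counting.

Converts raw single-end amplicon reads into per-variant ligated/unligated
read counts. Each read carries a pool barcode (introduced by the reverse
transcription primer, marking the ligated or unligated gel band), constant
flanking sequence, and the variable catalytic-core sequence. Processing
applies, in order: an optional read-level quality filter, barcode
demultiplexing, constant-region trimming (core extraction), a core-level
quality filter, and exact sequence lookup against the design library; every
read ends up in exactly one counter, so the totals always partition the
input.

Two named filter policies mirror the two screens this pipeline models:

``f1star``
    read passes if ≥70% of base calls have Phred quality ≥20, and the
    extracted core must have all calls ≥20.
``minf1``
    no read-level filter; the extracted core must have all calls ≥30.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .design import DesignLibrary
from .templates import dna_to_rna

LIGATED = "ligated"
UNLIGATED = "unligated"
UNKNOWN = "unknown"

#: Synthetic default pool barcodes (Hamming distance 8 apart). The real
#: screens used RT-primer barcodes of 8 or 10 nt; any study-specific table
#: can be supplied instead.
DEFAULT_DEMUX_TABLE = {"AACCGGTT": LIGATED, "TTGGCCAA": UNLIGATED}


@dataclass
class SequencingRead:
    """A single read: id, base calls, and per-base Phred quality scores."""

    read_id: str
    bases: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if len(self.qualities) and self.qualities.min() < 0:
            raise ValueError("Phred quality scores must be >= 0")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadLayout:
    """Amplicon architecture: where the barcode and constant flanks sit.

    ``barcode_start`` is a 0-based offset; the barcode occupies
    ``[barcode_start, barcode_start + barcode_length)``. ``flank_5`` and
    ``flank_3`` are the constant DNA sequences immediately surrounding the
    variable core. The architecture is fully configurable because amplicon
    designs differ between runs.
    """

    flank_5: str
    flank_3: str
    barcode_start: int = 0
    barcode_length: int = 8

    def __post_init__(self) -> None:
        if self.barcode_length not in (8, 10):
            raise ValueError("barcode_length must be 8 or 10")
        if not self.flank_5 or not self.flank_3:
            raise ValueError("both flanks must be non-empty")
        if self.barcode_start < 0:
            raise ValueError("barcode_start must be >= 0")

    @property
    def barcode_slice(self) -> slice:
        return slice(self.barcode_start, self.barcode_start + self.barcode_length)


def make_demux_table(table: dict[str, str]) -> dict[str, str]:
    """Validate a barcode→fate mapping (unique barcodes, both fates present)."""
    fates = set(table.values())
    if not fates <= {LIGATED, UNLIGATED}:
        raise ValueError(f"fates must be {LIGATED!r}/{UNLIGATED!r}, got {fates}")
    if fates != {LIGATED, UNLIGATED}:
        raise ValueError("demux table must contain both ligated and unligated barcodes")
    return dict(table)


@dataclass
class FilterPolicy:
    """Quality-filter parameters; see the module docstring for the presets."""

    name: str
    read_min_fraction: float | None  # None disables the read-level filter
    read_qs_threshold: int
    core_qs_threshold: int


POLICIES = {
    "f1star": FilterPolicy("f1star", 0.70, 20, 20),
    "minf1": FilterPolicy("minf1", None, 0, 30),
}


def get_policy(policy: "str | FilterPolicy") -> FilterPolicy:
    if isinstance(policy, FilterPolicy):
        return policy
    try:
        return POLICIES[policy]
    except KeyError:
        raise ValueError(
            f"unknown policy {policy!r}; available: {sorted(POLICIES)}"
        ) from None


def filter_read_quality(
    read: SequencingRead, min_fraction: float = 0.70, qs_threshold: int = 20
) -> bool:
    """True iff at least ``min_fraction`` of base calls have QS ≥ threshold.

    An empty read always fails.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    if len(read) == 0:
        return False
    frac = float(np.count_nonzero(read.qualities >= qs_threshold)) / len(read)
    return frac >= min_fraction


def filter_core_quality(core_qualities: np.ndarray, qs_threshold: int) -> bool:
    """True iff every base call in the core has QS ≥ threshold."""
    q = np.asarray(core_qualities)
    if q.size == 0:
        raise ValueError("empty core quality vector")
    return bool((q >= qs_threshold).all())


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex_read(
    read: SequencingRead,
    layout: ReadLayout,
    table: dict[str, str],
    max_mismatch: int = 0,
) -> str:
    """Assign a read to the ligated or unligated pool via its barcode.

    Returns the fate of the unique table barcode within ``max_mismatch``
    Hamming distance of the read's barcode; ``"unknown"`` when no barcode
    is close enough, when two are equally close (ambiguity is never
    resolved by fate), or when the read is too short to contain the
    barcode interval.
    """
    end = layout.barcode_start + layout.barcode_length
    if len(read) < end:
        return UNKNOWN
    observed = read.bases[layout.barcode_slice]
    fate = table.get(observed)
    if fate is not None:
        return fate
    if max_mismatch == 0:
        return UNKNOWN
    best, best_d, ties = None, max_mismatch + 1, 0
    for barcode, f in table.items():
        d = _hamming(observed, barcode)
        if d < best_d:
            best, best_d, ties = f, d, 1
        elif d == best_d:
            ties += 1
    if best is None or ties > 1:
        return UNKNOWN
    return best


def _find_approx(haystack: str, needle: str, max_mismatch: int, start: int = 0) -> int:
    """Leftmost position of ``needle`` in ``haystack`` within Hamming distance."""
    if max_mismatch == 0:
        return haystack.find(needle, start)
    n, m = len(haystack), len(needle)
    for i in range(start, n - m + 1):
        if _hamming(haystack[i : i + m], needle) <= max_mismatch:
            return i
    return -1


def extract_core(
    read: SequencingRead, layout: ReadLayout, max_flank_mismatch: int = 0
) -> tuple[str, np.ndarray] | None:
    """Trim constant regions: return (core bases, core qualities) or None.

    Locates ``flank_5`` then ``flank_3`` strictly downstream of it (each
    within ``max_flank_mismatch``); the subsequence between them is the
    candidate core. Failure (either flank absent, or only in the wrong
    order) returns ``None``.
    """
    i = _find_approx(read.bases, layout.flank_5, max_flank_mismatch)
    if i < 0:
        return None
    core_start = i + len(layout.flank_5)
    j = _find_approx(read.bases, layout.flank_3, max_flank_mismatch, core_start)
    if j < 0:
        return None
    return read.bases[core_start:j], read.qualities[core_start:j]


@dataclass
class CountTable:
    """Per-variant pool counts plus the read-fate partition counters."""

    counts: dict[str, list[int]] = field(default_factory=dict)
    reads_in: int = 0
    fail_quality: int = 0
    fail_demux: int = 0
    fail_trim: int = 0
    unassigned: int = 0

    def add(self, variant_id: str, fate: str) -> None:
        pair = self.counts.setdefault(variant_id, [0, 0])
        pair[0 if fate == LIGATED else 1] += 1

    def n_lig(self, variant_id: str) -> int:
        return self.counts.get(variant_id, [0, 0])[0]

    def n_unlig(self, variant_id: str) -> int:
        return self.counts.get(variant_id, [0, 0])[1]

    @property
    def assigned(self) -> int:
        return sum(a + b for a, b in self.counts.values())

    def check_partition(self) -> bool:
        """Every input read is in exactly one counter."""
        return self.reads_in == (
            self.assigned
            + self.fail_quality
            + self.fail_demux
            + self.fail_trim
            + self.unassigned
        )

    def summary(self) -> dict[str, int]:
        return {
            "reads_in": self.reads_in,
            "assigned": self.assigned,
            "fail_quality": self.fail_quality,
            "fail_demux": self.fail_demux,
            "fail_trim": self.fail_trim,
            "unassigned": self.unassigned,
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variant_id": list(self.counts),
                "n_lig": [c[0] for c in self.counts.values()],
                "n_unlig": [c[1] for c in self.counts.values()],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "CountTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
        table = cls()
        for row in df.itertuples():
            table.counts[row.variant_id] = [int(row.n_lig), int(row.n_unlig)]
        table.reads_in = table.assigned
        return table


def count_variants(
    reads: Iterable[SequencingRead],
    library: DesignLibrary,
    layout: ReadLayout,
    table: dict[str, str],
    policy: "str | FilterPolicy" = "f1star",
    max_barcode_mismatch: int = 0,
    max_flank_mismatch: int = 0,
) -> CountTable:
    """Stream reads through the full filter → demux → trim → assign chain.

    Cores are matched to library variants by exact sequence identity only
    (reads carrying sequencing errors in the core fall into ``unassigned``),
    after converting the read's DNA core back to the RNA alphabet of the
    design library.
    """
    pol = get_policy(policy)
    demux = make_demux_table(table)
    out = CountTable()
    index = library.index
    for read in reads:
        out.reads_in += 1
        if pol.read_min_fraction is not None and not filter_read_quality(
            read, pol.read_min_fraction, pol.read_qs_threshold
        ):
            out.fail_quality += 1
            continue
        fate = demultiplex_read(read, layout, demux, max_barcode_mismatch)
        if fate == UNKNOWN:
            out.fail_demux += 1
            continue
        extracted = extract_core(read, layout, max_flank_mismatch)
        if extracted is None:
            out.fail_trim += 1
            continue
        core, core_q = extracted
        if len(core) == 0 or not filter_core_quality(core_q, pol.core_qs_threshold):
            out.fail_quality += 1
            continue
        vid = index.get(dna_to_rna(core))
        if vid is None:
            out.unassigned += 1
            continue
        out.add(vid, fate)
    return out


def _open_maybe_gzip(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[SequencingRead]:
    """Iterate a (possibly gzipped) Sanger-encoded FASTQ file as reads."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with _open_maybe_gzip(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            qualities = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int16
            ) - 33
            yield SequencingRead(title.split()[0], seq, qualities)


def write_fastq(reads: Iterable[SequencingRead], path) -> int:
    """Write reads as Sanger-encoded FASTQ; returns the number written."""
    n = 0
    with _open_maybe_gzip(path, "wt") as fh:
        for read in reads:
            qual = (read.qualities.astype(np.uint8) + 33).tobytes().decode("ascii")
            fh.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n
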