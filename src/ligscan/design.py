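"""Combinatorial variant-library design for oligo-pool synthesis.

Enumerates the variant classes of a saturation mutagenesis / minimization
screen of a ligase ribozyme core — all single and double substitutions, all
single/double/triple deletions (with deduplication of deletions that yield
identical sequences), exhaustive bulge replacements of size 0..k, and stem
truncations — then assembles them into a deduplicated :class:`DesignLibrary`
with a sequence→variant index, and emits the oligo pool (T7-promoter-flanked
DNA) for chip synthesis.

Mutation nomenclature: substitutions ``U23G``, deletions ``A26del``, multiple
edits joined by ``/`` (``A2C/U14G``); bulge replacements ``bulge:<seq>`` (with
``bulge:-`` for bulge removal) and stem truncations ``stem:<name>:<len>``.
When several deletion label sets collapse to one sequence, the canonical
``variant_id`` is the label with the leftmost deletion positions and all
equivalent labels are kept in ``source_labels``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .templates import RNA_ALPHABET, CoreTemplate, rna_to_dna

BASES = "ACGU"
T7_PROMOTER_FLANK = "CCTAATACGACTCACTATA"

VARIANT_CLASSES = (
    "wt",
    "sub1",
    "sub2",
    "del1",
    "del2",
    "del3",
    "bulge",
    "stem_trunc",
    "custom",
)


@dataclass
class VariantRecord:
    """One designed variant: canonical label, class, and core sequence."""

    variant_id: str
    variant_class: str
    core_sequence: str
    source_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")
        if not self.source_labels:
            self.source_labels = [self.variant_id]


def _sub_label(template: CoreTemplate, pos: int, alt: str) -> str:
    return f"{template.base(pos)}{pos + template.numbering_offset}{alt}"


def _del_label(template: CoreTemplate, positions: Sequence[int]) -> str:
    off = template.numbering_offset
    return "/".join(f"{template.base(p)}{p + off}del" for p in positions)


def _apply_substitutions(template: CoreTemplate, edits: dict[int, str]) -> str:
    seq = list(template.sequence)
    for pos, alt in edits.items():
        seq[pos - 1] = alt
    return "".join(seq)


def _apply_deletions(template: CoreTemplate, positions: Iterable[int]) -> str:
    drop = set(positions)
    return "".join(b for i, b in enumerate(template.sequence, 1) if i not in drop)


def enumerate_substitutions(template: CoreTemplate, order: int) -> list[VariantRecord]:
    """All base-substitution variants of the given order over the mutable span.

    Returns ``3L`` records for ``order=1`` and ``9*C(L,2)`` for ``order=2``
    (L = number of mutable positions); the wild-type sequence is never among
    them since every position is changed to a non-wild-type base.
    """
    if order not in (1, 2):
        raise ValueError(f"unsupported substitution order {order}; only 1 and 2")
    positions = sorted(template.mutable_positions)
    records: list[VariantRecord] = []
    cls = f"sub{order}"
    for combo in itertools.combinations(positions, order):
        alt_sets = [[b for b in BASES if b != template.base(p)] for p in combo]
        for alts in itertools.product(*alt_sets):
            label = "/".join(
                _sub_label(template, p, a) for p, a in zip(combo, alts)
            )
            seq = _apply_substitutions(template, dict(zip(combo, alts)))
            records.append(VariantRecord(label, cls, seq))
    return records


def enumerate_deletions(
    template: CoreTemplate, order: int, deduplicate: bool = True
) -> list[VariantRecord]:
    """All ``order``-base deletions over the mutable span.

    Deleting different positions inside a homopolymer run yields the same
    sequence; with ``deduplicate`` (the default) one record is returned per
    distinct sequence, its ``variant_id`` taken from the leftmost position
    combination and all equivalent labels collected in ``source_labels``.
    """
    if order < 1:
        raise ValueError(f"invalid deletion order {order}")
    positions = sorted(template.mutable_positions)
    if order > len(positions):
        raise ValueError(
            f"deletion order {order} exceeds {len(positions)} mutable positions"
        )
    cls = f"del{order}" if order <= 3 else "custom"
    records: list[VariantRecord] = []
    by_seq: dict[str, VariantRecord] = {}
    for combo in itertools.combinations(positions, order):
        label = _del_label(template, combo)
        seq = _apply_deletions(template, combo)
        if not deduplicate:
            records.append(VariantRecord(label, cls, seq))
            continue
        rec = by_seq.get(seq)
        if rec is None:
            rec = VariantRecord(label, cls, seq)
            by_seq[seq] = rec
            records.append(rec)
        else:
            rec.source_labels.append(label)
    return records


def enumerate_bulge_variants(
    template: CoreTemplate, max_size: int = 3
) -> list[VariantRecord]:
    """Replace the annotated bulge with every sequence of length 0..max_size.

    Emits ``sum(4**s for s in 0..max_size)`` records (85 for ``max_size=3``),
    including the record that restores the wild-type bulge. Labels follow the
    lowercase-for-mutated-base convention for full-length replacements (e.g.
    ``ucA`` for a GAA→UCA bulge), the plain replacement for shorter bulges,
    and ``-`` for complete bulge removal; these go to ``source_labels`` while
    ``variant_id`` uses the unambiguous ``bulge:<seq>`` form.
    """
    if template.bulge_span is None:
        raise ValueError(f"template {template.name!r} has no bulge_span configured")
    if max_size < 0:
        raise ValueError("max_size must be >= 0")
    s, e = template.bulge_span
    wt_bulge = template.bulge_sequence
    records = []
    for size in range(max_size + 1):
        for repl in itertools.product(BASES, repeat=size):
            bulge = "".join(repl)
            seq = template.sequence[: s - 1] + bulge + template.sequence[e:]
            if not bulge:
                display = "-"
            elif len(bulge) == len(wt_bulge):
                display = "".join(
                    b if b == w else b.lower() for b, w in zip(bulge, wt_bulge)
                )
            else:
                display = bulge
            vid = f"bulge:{bulge or '-'}"
            records.append(VariantRecord(vid, "bulge", seq, [display]))
    return records


def enumerate_stem_truncations(
    template: CoreTemplate,
    stem_name: str,
    lengths: Sequence[int],
    side: str = "bulge-proximal",
) -> list[VariantRecord]:
    """Shorten a named stem (on the ribozyme strand) to each requested length.

    ``side`` selects which end of the stem span loses bases:
    ``"bulge-proximal"`` (default) trims from the 3' end of the span,
    ``"bulge-distal"`` from the 5' end. The choice is exposed because the
    screen's construct drawings, not the core annotations, fix it.
    """
    if stem_name not in template.stem_spans:
        raise ValueError(f"unknown stem {stem_name!r}")
    if side not in ("bulge-proximal", "bulge-distal"):
        raise ValueError(f"unknown truncation side {side!r}")
    s, e = template.stem_spans[stem_name]
    current = e - s + 1
    records = []
    for length in lengths:
        if not (0 <= length < current):
            raise ValueError(
                f"invalid truncation of {stem_name} ({current} nt) to {length} nt"
            )
        ndrop = current - length
        if side == "bulge-proximal":
            keep = range(s, e - ndrop + 1)
        else:
            keep = range(s + ndrop, e + 1)
        drop = set(range(s, e + 1)) - set(keep)
        seq = _apply_deletions(template, drop)
        records.append(
            VariantRecord(f"stem:{stem_name}:{length}", "stem_trunc", seq)
        )
    return records


@dataclass
class DesignLibrary:
    """A deduplicated variant library with a sequence→variant_id index."""

    template: CoreTemplate | None
    variants: list[VariantRecord]
    index: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {v.core_sequence: v.variant_id for v in self.variants}
        if len(self.index) != len(self.variants):
            raise ValueError("library contains duplicate core sequences")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def get(self, variant_id: str) -> VariantRecord:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)

    def lookup(self, core_sequence: str) -> str | None:
        """Variant id whose core equals ``core_sequence`` exactly, else None."""
        return self.index.get(core_sequence)

    def by_class(self, variant_class: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.variant_class == variant_class]


def build_library(
    template: CoreTemplate,
    class_specs: Sequence[str] = ("sub1", "sub2", "del1", "del2", "del3"),
    custom_variants: Sequence[VariantRecord] = (),
    bulge_max_size: int = 3,
    stem_truncations: dict[str, Sequence[int]] | None = None,
) -> DesignLibrary:
    """Assemble the requested variant classes into one deduplicated library.

    The wild-type record (id ``WT``) is always first. Records from different
    classes that share a core sequence — e.g. a bulge single deletion equal to
    a core deletion — are merged into the first-seen record, concatenating
    ``source_labels``; sequencing cannot distinguish identical sequences, so
    the library must not either. Custom records whose sequence collides with
    an existing record are merged with a warning rather than rejected.
    """
    known = {"sub1", "sub2", "del1", "del2", "del3", "bulge", "stem_trunc"}
    unknown = set(class_specs) - known
    if unknown:
        raise ValueError(f"unknown class specs: {sorted(unknown)}")

    pending: list[VariantRecord] = [
        VariantRecord("WT", "wt", template.sequence)
    ]
    for spec in class_specs:
        if spec.startswith("sub"):
            pending.extend(enumerate_substitutions(template, int(spec[3:])))
        elif spec.startswith("del"):
            pending.extend(enumerate_deletions(template, int(spec[3:])))
        elif spec == "bulge":
            pending.extend(enumerate_bulge_variants(template, bulge_max_size))
        elif spec == "stem_trunc":
            for stem, lengths in (stem_truncations or {}).items():
                pending.extend(enumerate_stem_truncations(template, stem, lengths))
    pending.extend(custom_variants)

    merged: dict[str, VariantRecord] = {}
    order: list[VariantRecord] = []
    for rec in pending:
        existing = merged.get(rec.core_sequence)
        if existing is None:
            rec = VariantRecord(
                rec.variant_id, rec.variant_class, rec.core_sequence,
                list(rec.source_labels),
            )
            merged[rec.core_sequence] = rec
            order.append(rec)
        else:
            if rec.variant_class == "custom" and existing.variant_id != rec.variant_id:
                warnings.warn(
                    f"custom variant {rec.variant_id!r} duplicates "
                    f"{existing.variant_id!r}; merged",
                    stacklevel=2,
                )
            for lab in rec.source_labels:
                if lab not in existing.source_labels:
                    existing.source_labels.append(lab)
    return DesignLibrary(template, order)


def apply_variant_label(template: CoreTemplate, variant_id: str) -> str:
    """Reconstruct a variant's core sequence from its canonical label.

    Supports ``WT``, substitution/deletion edit strings (``U23G``,
    ``A26del/U27del``, mixed), ``bulge:<seq>`` and ``stem:<name>:<len>``.
    Used for round-trip validation of emitted records.
    """
    if variant_id == "WT":
        return template.sequence
    if variant_id.startswith("bulge:"):
        bulge = variant_id[len("bulge:"):]
        bulge = "" if bulge == "-" else bulge
        s, e = template.bulge_span  # type: ignore[misc]
        return template.sequence[: s - 1] + bulge + template.sequence[e:]
    if variant_id.startswith("stem:"):
        _, stem, length = variant_id.split(":")
        (rec,) = enumerate_stem_truncations(template, stem, [int(length)])
        return rec.core_sequence
    subs: dict[int, str] = {}
    dels: list[int] = []
    for edit in variant_id.split("/"):
        if edit.endswith("del"):
            wt, pos = edit[0], int(edit[1:-3]) - template.numbering_offset
            tail = "del"
        else:
            wt, pos, tail = edit[0], int(edit[1:-1]) - template.numbering_offset, edit[-1]
        if template.base(pos) != wt:
            raise ValueError(
                f"label {edit!r} inconsistent with template base {template.base(pos)}"
            )
        if tail == "del":
            dels.append(pos)
        else:
            subs[pos] = tail
    seq = list(template.sequence)
    for pos, alt in subs.items():
        seq[pos - 1] = alt
    return "".join(b for i, b in enumerate(seq, 1) if i not in dels)


def write_variant_table(library: DesignLibrary, path) -> None:
    """Write the library as TSV (variant_id, class, source_labels, core_sequence)."""
    import pandas as pd

    pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in library],
            "variant_class": [v.variant_class for v in library],
            "source_labels": [",".join(v.source_labels) for v in library],
            "core_sequence": [v.core_sequence for v in library],
        }
    ).to_csv(path, sep="\t", index=False)


def read_variant_table(path, template: CoreTemplate | None = None) -> DesignLibrary:
    """Read a variant table written by :func:`write_variant_table`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    variants = [
        VariantRecord(
            row.variant_id,
            row.variant_class,
            row.core_sequence,
            row.source_labels.split(","),
        )
        for row in df.itertuples()
    ]
    return DesignLibrary(template, variants)


def write_oligo_fasta(oligos: Sequence[tuple[str, str]], path) -> None:
    """Write (variant_id, oligo) pairs as a FASTA oligo-pool file."""
    with open(path, "w") as fh:
        for vid, oligo in oligos:
            fh.write(f">{vid}\n{oligo}\n")


def assemble_oligos(
    library: DesignLibrary,
    flank_5: str = T7_PROMOTER_FLANK,
    flank_3: str = "",
) -> list[tuple[str, str]]:
    """DNA oligo for each variant: ``flank_5 + DNA(core) + flank_3``.

    The default 5' flank is the T7 promoter used to transcribe the pool.
    """
    for name, flank in (("flank_5", flank_5), ("flank_3", flank_3)):
        if set(flank) - set("ACGT"):
            raise ValueError(f"{name} must be a DNA string")
    oligos = []
    for v in library:
        if set(v.core_sequence) - RNA_ALPHABET:
            raise ValueError(f"non-RNA characters in variant {v.variant_id}")
        oligos.append((v.variant_id, flank_5 + rna_to_dna(v.core_sequence) + flank_3))
    return oligos
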