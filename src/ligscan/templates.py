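"""Annotated catalytic-core templates for ligase ribozymes.

A :class:`CoreTemplate` describes the parental (wild-type) catalytic core that a
variant library mutagenizes: the RNA sequence, which positions are open to
substitution/deletion, where the bulge opposite the ligation site sits, and any
named stems (e.g. the P2 spacer stem).

The bundled defaults (:func:`f1star_template`, :func:`minf1_template`) are
*synthetic* stand-in sequences: they reproduce the documented architecture of
the F1*-family ligase cores (28-nt main core + 4-bp P2 stem + GAA bulge for
F1*; 22-nt main core + substrate-pairing U + 4-bp P2 + GAA bulge for minF1)
and every individually documented base identity, but the full wild-type
sequences are not redistributed here. Any real analysis should load its own
template from configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class CoreTemplate:
    """Parental catalytic-core sequence with mutagenesis annotations.

    Parameters
    ----------
    name:
        Identifier of the construct (e.g. ``"F1*"``).
    sequence:
        Uppercase RNA core sequence, 5'→3'.
    mutable_positions:
        1-based positions open to substitution and deletion. Need not be
        contiguous (the F1*-style design mutagenizes the main core and the
        bulge but leaves the P2 spacer stem fixed).
    bulge_span:
        1-based inclusive ``(start, end)`` of the bulge opposite the ligation
        site, or ``None`` when the construct has none annotated.
    stem_spans:
        Named 1-based inclusive intervals for stems on the ribozyme strand,
        e.g. ``{"P2": (29, 32)}``.
    numbering_offset:
        Added to internal 1-based positions when rendering labels; 0 keeps
        core-local numbering.
    """

    name: str
    sequence: str
    mutable_positions: frozenset[int]
    bulge_span: tuple[int, int] | None = None
    stem_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("template sequence must be non-empty")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(f"non-RNA characters in template sequence: {sorted(bad)}")
        object.__setattr__(self, "mutable_positions", frozenset(self.mutable_positions))
        n = len(self.sequence)
        if not self.mutable_positions:
            raise ValueError("mutable_positions must be non-empty")
        if any(p < 1 or p > n for p in self.mutable_positions):
            raise ValueError("mutable_positions outside template")
        for label, span in self._spans():
            s, e = span
            if not (1 <= s <= e <= n):
                raise ValueError(f"{label} span {span} outside template of length {n}")

    def _spans(self):
        if self.bulge_span is not None:
            yield "bulge", self.bulge_span
        for name, span in self.stem_spans.items():
            yield name, span

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self.sequence[pos - 1]

    @property
    def bulge_sequence(self) -> str:
        if self.bulge_span is None:
            raise ValueError(f"template {self.name!r} has no bulge_span annotated")
        s, e = self.bulge_span
        return self.sequence[s - 1 : e]


def f1star_template() -> CoreTemplate:
    """Synthetic F1*-like core: 35 nt, mutable 1-28 and 33-35, P2 = 29-32.

    The 31 mutable positions give 93 single and 4185 double substitution
    variants, matching the published design counts for the F1* core.
    """
    return CoreTemplate(
        name="F1*",
        sequence="UAUCAACUAAGAUGGAUUAGAUUAGAUGGUCUGAA",
        mutable_positions=frozenset(range(1, 29)) | frozenset(range(33, 36)),
        bulge_span=(33, 35),
        stem_spans={"P2": (29, 32)},
    )


def minf1_template() -> CoreTemplate:
    """Synthetic minF1-like core: 30 nt, mutable 1-22 and 28-30, P2 = 24-27.

    Position 23 (U, pairing the substrate 3' end) and the P2 stem are held
    constant; the 22-nt main core carries the 2-14 / 3-13 / 4-12 base pairs
    and the A5-A9 adenosine run of the minimized ligase.
    """
    return CoreTemplate(
        name="minF1",
        sequence="UAUCAAAAAUGGAUGAUUAGAAUGUGUGAA",
        mutable_positions=frozenset(range(1, 23)) | frozenset(range(28, 31)),
        bulge_span=(28, 30),
        stem_spans={"P2": (24, 27)},
    )


def rna_to_dna(seq: str) -> str:
    """Transcribe an RNA string to its coding DNA form (U→T)."""
    return seq.replace("U", "T")


def dna_to_rna(seq: str) -> str:
    """DNA coding strand to RNA (T→U)."""
    return seq.replace("T", "U")
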