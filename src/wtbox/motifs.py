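"""IUPAC degenerate pattern compilation and occurrence scanning.

The matcher reports every window (overlaps included) whose bases all fall in
the pattern's per-position allowed sets.  A subject N never matches any
pattern position, including pattern N: an unknown base cannot be claimed as a
hit.  Minus-strand occurrences are found by scanning the reverse-complement
pattern over the forward string and are reported with forward coordinates of
the leftmost matched base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .io import SequenceRecord, SequenceSet

#: IUPAC one-letter nucleotide ambiguity codes
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items()}
_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

StrandPolicy = Literal["forward", "both"]


class PatternError(ValueError):
    """Invalid IUPAC pattern string."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled IUPAC degenerate pattern with per-position allowed bases."""

    label: str
    iupac: str
    allowed: tuple[frozenset[str], ...] = field(repr=False)

    @property
    def length(self) -> int:
        return len(self.allowed)

    def matches_window(self, window: str) -> bool:
        return len(window) == self.length and all(
            base in pos for base, pos in zip(window, self.allowed)
        )

    def _regex(self) -> re.Pattern[str]:
        # subject alphabet is ACGTN; character classes omit N so unknown
        # bases never match, even under pattern N
        body = "".join("[" + "".join(sorted(pos)) + "]" for pos in self.allowed)
        return re.compile(f"(?=({body}))")


def compile_pattern(label: str, iupac: str) -> MotifPattern:
    """Compile an IUPAC string (e.g. ``NGACTTTN``) into a MotifPattern."""
    if not iupac:
        raise PatternError("empty pattern string")
    up = iupac.upper()
    allowed = []
    for i, ch in enumerate(up, start=1):
        if ch not in IUPAC_SETS:
            raise PatternError(
                f"pattern {label!r}: invalid IUPAC code {ch!r} at position {i}"
            )
        allowed.append(IUPAC_SETS[ch])
    return MotifPattern(label=label, iupac=up, allowed=tuple(allowed))


def reverse_complement_pattern(p: MotifPattern) -> MotifPattern:
    """Complement each position's allowed set and reverse the order."""
    allowed = tuple(
        frozenset(_BASE_COMPLEMENT[b] for b in pos) for pos in reversed(p.allowed)
    )
    iupac = "".join(_SET_TO_CODE[pos] for pos in allowed)
    return MotifPattern(label=f"revcomp({p.label})", iupac=iupac, allowed=allowed)


@dataclass(frozen=True)
class Occurrence:
    """One match: 1-based forward-coordinate start of the leftmost base."""

    sequence_id: str
    start: int
    strand: str
    matched_text: str


@dataclass
class OccurrenceTable:
    """Per-sequence occurrence counts for one pattern and strand policy."""

    pattern: MotifPattern
    strand_policy: StrandPolicy
    per_sequence_counts: dict[str, int]
    occurrences: list[Occurrence] | None = None

    @property
    def total(self) -> int:
        return sum(self.per_sequence_counts.values())


def _scan_starts(p: MotifPattern, residues: str) -> Iterable[int]:
    """0-based start offsets of all (overlapping) matches."""
    for m in p._regex().finditer(residues):
        yield m.start()


def find_occurrences(
    p: MotifPattern,
    s: SequenceRecord,
    strand_policy: StrandPolicy = "both",
) -> list[Occurrence]:
    """All occurrences of ``p`` in ``s``, sorted by start then strand (+ first)."""
    hits: list[Occurrence] = []
    for off in _scan_starts(p, s.residues):
        hits.append(
            Occurrence(
                sequence_id=s.id,
                start=off + 1,
                strand="+",
                matched_text=s.residues[off : off + p.length],
            )
        )
    if strand_policy == "both":
        rc = reverse_complement_pattern(p)
        for off in _scan_starts(rc, s.residues):
            hits.append(
                Occurrence(
                    sequence_id=s.id,
                    start=off + 1,
                    strand="-",
                    matched_text=s.residues[off : off + p.length],
                )
            )
    hits.sort(key=lambda o: (o.start, o.strand))
    return hits


def count_occurrences(
    p: MotifPattern,
    seqs: SequenceSet,
    strand_policy: StrandPolicy = "both",
    keep_positions: bool = False,
) -> OccurrenceTable:
    """Count occurrences per sequence; positions retained only on request."""
    counts: dict[str, int] = {}
    occurrences: list[Occurrence] | None = [] if keep_positions else None
    rc = reverse_complement_pattern(p) if strand_policy == "both" else None
    for rec in seqs:
        if keep_positions:
            hits = find_occurrences(p, rec, strand_policy)
            counts[rec.id] = len(hits)
            occurrences.extend(hits)  # type: ignore[union-attr]
        else:
            n = sum(1 for _ in _scan_starts(p, rec.residues))
            if rc is not None:
                n += sum(1 for _ in _scan_starts(rc, rec.residues))
            counts[rec.id] = n
    return OccurrenceTable(
        pattern=p,
        strand_policy=strand_policy,
        per_sequence_counts=counts,
        occurrences=occurrences,
    )
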