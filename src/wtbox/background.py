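"""Nucleotide-composition null model for degenerate-motif frequencies.

The null model treats every position of a sequence as an independent draw
from per-base frequencies derived from the regional GC content.  Under the
symmetric parameterisation used for strand-agnostic DNA,

    P(G) = P(C) = gc/2,      P(A) = P(T) = (1 - gc)/2,

and the expected per-nucleotide frequency of a degenerate motif is the
product over its positions of the summed frequencies of that position's
allowed bases (an N position contributes a factor of exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Literal

from .io import SequenceSet
from .motifs import MotifPattern

Parameterization = Literal["symmetric", "empirical"]


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts and the per-base null frequencies they induce."""

    counts: dict[str, int]
    total_counted: int
    gc_fraction: float
    null_base_frequencies: dict[str, float]
    parameterization: str = "symmetric"

    @classmethod
    def from_gc_fraction(
        cls, gc: float, round_digits: int | None = None
    ) -> "CompositionProfile":
        """Symmetric profile from a GC fraction alone (no counts).

        ``round_digits`` rounds the per-base frequencies to that many decimal
        places before use, reproducing analyses carried out with frequencies
        quoted at fixed printed precision (e.g. GC 0.3262 -> 0.3369/0.1631
        at four digits).
        """
        if not 0.0 <= gc <= 1.0:
            raise ValueError(f"gc fraction must be in [0,1], got {gc}")
        at = (1.0 - gc) / 2.0
        gc2 = gc / 2.0
        if round_digits is not None:
            at = round(at, round_digits)
            gc2 = round(gc2, round_digits)
        freqs = {"A": at, "C": gc2, "G": gc2, "T": at}
        return cls(
            counts={b: 0 for b in "ACGT"},
            total_counted=0,
            gc_fraction=gc,
            null_base_frequencies=freqs,
        )


def composition_profile(
    seqs: SequenceSet, parameterization: Parameterization = "symmetric"
) -> CompositionProfile:
    """Tally A/C/G/T over all records (N excluded) and derive null frequencies."""
    counts = {b: 0 for b in "ACGT"}
    for rec in seqs:
        for b in "ACGT":
            counts[b] += rec.residues.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("composition_profile: no countable (non-N) residues")
    gc = (counts["G"] + counts["C"]) / total
    if parameterization == "symmetric":
        freqs = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    elif parameterization == "empirical":
        freqs = {b: counts[b] / total for b in "ACGT"}
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    return CompositionProfile(
        counts=counts,
        total_counted=total,
        gc_fraction=gc,
        null_base_frequencies=freqs,
        parameterization=parameterization,
    )


def expected_frequency(p: MotifPattern, profile: CompositionProfile) -> float:
    """Expected per-nucleotide motif frequency under the independent-base null."""
    f = profile.null_base_frequencies
    return prod(sum(f[b] for b in pos) for pos in p.allowed)


def expected_count(
    p: MotifPattern, profile: CompositionProfile, region_nt: int
) -> float:
    """Null-expected occurrence count in a region of ``region_nt`` nucleotides."""
    if region_nt < 0:
        raise ValueError(f"region_nt must be >= 0, got {region_nt}")
    return region_nt * expected_frequency(p, profile)


def valid_start_positions(seqs: SequenceSet, pattern_length: int) -> int:
    """Number of window start positions, sum over records of max(L-k+1, 0).

    Alternative denominator convention to total nucleotides; which one a
    report used is always recorded alongside the frequencies.
    """
    return sum(max(rec.length - pattern_length + 1, 0) for rec in seqs)
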