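"""Per-gene motif content and gene-set algebra.

Counts motif occurrences per upstream window, ranks motif-rich promoters,
builds include/exclude pattern sets (e.g. WT-box present AND W-box absent),
and intersects the resulting gene sets with external target-gene lists
(Venn-style region counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from .io import SequenceSet
from .motifs import MotifPattern, StrandPolicy, count_occurrences


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of (upper-cased) gene identifiers."""

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("GeneSet label must be non-empty")
        object.__setattr__(
            self, "members", frozenset(m.upper() for m in self.members)
        )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id.upper() in self.members

    def intersection(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(
            label=f"{self.label}&{other.label}",
            members=self.members & other.members,
        )


@dataclass
class GeneMotifCounts:
    """Occurrence count of one pattern per gene's window (zeros retained)."""

    pattern_label: str
    window_length: int | None
    strand_policy: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def per_gene_motif_counts(
    p: MotifPattern,
    upstream: SequenceSet,
    strand_policy: StrandPolicy = "both",
) -> GeneMotifCounts:
    """Count occurrences of ``p`` in every gene's upstream window."""
    table = count_occurrences(p, upstream, strand_policy)
    return GeneMotifCounts(
        pattern_label=p.label,
        window_length=upstream.window_length,
        strand_policy=strand_policy,
        counts=dict(table.per_sequence_counts),
    )


def top_motif_rich_genes(
    counts: GeneMotifCounts,
    k: int | None = None,
    threshold: int | None = None,
) -> list[tuple[str, int]]:
    """Genes ranked by motif count, descending; ties broken by gene id.

    Exactly one of ``k`` (top-k mode) or ``threshold`` (all genes with count
    >= threshold) must be given.
    """
    if (k is None) == (threshold is None):
        raise ValueError("give exactly one of k or threshold")
    ranked = sorted(counts.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if k is not None:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        return ranked[:k]
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return [(g, c) for g, c in ranked if c >= threshold]


def motif_presence_set(
    include: Sequence[MotifPattern],
    exclude: Sequence[MotifPattern],
    upstream: SequenceSet,
    strand_policy: StrandPolicy = "both",
    label: str | None = None,
) -> GeneSet:
    """Genes with >=1 hit of every include pattern and 0 hits of every exclude.

    The canonical use is include = the WT-box NGACTTTN, exclude = the W-box
    TTGACY, yielding promoters that could respond through a WT-box that is
    not part of a classic WRKY W-box.
    """
    if not include:
        raise ValueError("at least one include pattern is required")
    keep = set(upstream.ids)
    for pat in include:
        counts = count_occurrences(pat, upstream, strand_policy).per_sequence_counts
        keep &= {g for g, c in counts.items() if c >= 1}
    for pat in exclude:
        counts = count_occurrences(pat, upstream, strand_policy).per_sequence_counts
        keep -= {g for g, c in counts.items() if c >= 1}
    if label is None:
        inc = "+".join(p.label for p in include)
        exc = "+".join(p.label for p in exclude)
        label = f"with[{inc}]without[{exc}]" if exc else f"with[{inc}]"
    return GeneSet(label=label, members=frozenset(keep))


def venn_counts(sets: Sequence[GeneSet]) -> dict[tuple[bool, ...], int]:
    """Membership-signature counts for 2-4 gene sets.

    The key is a tuple of booleans aligned with ``sets`` (True = member);
    the all-False signature is omitted, so the counts partition the union.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError(f"venn_counts needs 2-4 sets, got {len(sets)}")
    regions = {
        sig: 0
        for sig in product([False, True], repeat=len(sets))
        if any(sig)
    }
    for gene in frozenset().union(*(s.members for s in sets)):
        sig = tuple(gene in s.members for s in sets)
        regions[sig] += 1
    return regions


def venn_members(
    sets: Sequence[GeneSet],
) -> dict[tuple[bool, ...], frozenset[str]]:
    """Per-region member lists matching :func:`venn_counts` signatures."""
    if not 2 <= len(sets) <= 4:
        raise ValueError(f"venn_members needs 2-4 sets, got {len(sets)}")
    out: dict[tuple[bool, ...], set[str]] = {
        sig: set()
        for sig in product([False, True], repeat=len(sets))
        if any(sig)
    }
    for gene in frozenset().union(*(s.members for s in sets)):
        sig = tuple(gene in s.members for s in sets)
        out[sig].add(gene)
    return {sig: frozenset(m) for sig, m in out.items()}


def split_by_universe(
    genes: Iterable[str], universe: GeneSet
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition identifiers into (inside, outside) a gene universe.

    External target lists are intersected as given, but identifiers absent
    from the analysed promoter universe are reported separately.
    """
    inside, outside = set(), set()
    for g in genes:
        (inside if g.upper() in universe.members else outside).add(g.upper())
    return frozenset(inside), frozenset(outside)
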