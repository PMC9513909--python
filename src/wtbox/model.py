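"""Model/results interface for motif enrichment analysis.

`MotifEnrichment` bundles the inputs of a distribution analysis — the motif
patterns, the upstream-window sequence set, the genome (reference) sequence
set, and the null-model conventions — and `fit()` runs the census and the
binomial tests, returning a `MotifEnrichmentResults` carrying the per-motif
estimates, p-values and significance flags, with a `summary()` table.

Two construction routes are supported:

* ``MotifEnrichment(patterns, upstream, genome)`` — scan the sequences.
* ``MotifEnrichment.from_counts(...)`` — start from pre-tabulated occurrence
  counts (e.g. a published census) and run only the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .background import CompositionProfile, composition_profile
from .enrichment import (
    DEFAULT_ALPHAS,
    EnrichmentResult,
    distribution_table,
    enrichment_vs_reference,
)
from .io import SequenceSet
from .motifs import MotifPattern, StrandPolicy, compile_pattern


def _as_patterns(patterns: Sequence[MotifPattern | str]) -> list[MotifPattern]:
    return [
        p if isinstance(p, MotifPattern) else compile_pattern(p, p)
        for p in patterns
    ]


class MotifEnrichment:
    """Binomial enrichment model for degenerate motifs in genomic regions.

    Parameters
    ----------
    patterns
        IUPAC strings or compiled :class:`~wtbox.motifs.MotifPattern` objects.
    upstream
        The region of interest (typically fixed-length upstream windows).
    genome
        Optional reference region; when present, upstream counts are also
        tested against the genome-wide observed frequency.
    strand_policy
        ``"both"`` (default) or ``"forward"``.
    profile_source
        Which sequences parameterise the composition null: ``"upstream"``
        (default), ``"genome"``, or ``"explicit"`` with ``profile=``.
    alphas
        Significance levels for the flag columns.
    """

    def __init__(
        self,
        patterns: Sequence[MotifPattern | str],
        upstream: SequenceSet,
        genome: SequenceSet | None = None,
        *,
        strand_policy: StrandPolicy = "both",
        profile_source: Literal["upstream", "genome", "explicit"] = "upstream",
        profile: CompositionProfile | None = None,
        alphas: Sequence[float] = DEFAULT_ALPHAS,
    ) -> None:
        self.patterns = _as_patterns(patterns)
        if not self.patterns:
            raise ValueError("at least one pattern is required")
        self.upstream = upstream
        self.genome = genome
        self.strand_policy: StrandPolicy = strand_policy
        self.profile_source = profile_source
        self.profile = profile
        self.alphas = tuple(alphas)
        self._count_rows: list[EnrichmentResult] | None = None

    @classmethod
    def from_counts(
        cls,
        observed: Mapping[str, int],
        region_nt: int,
        expected_frequencies: Mapping[str, float],
        reference_frequencies: Mapping[str, float] | None = None,
        *,
        region_label: str = "region",
        reference_label: str = "reference",
        alphas: Sequence[float] = DEFAULT_ALPHAS,
    ) -> "MotifEnrichment":
        """Build the model from pre-tabulated counts and frequencies.

        ``observed`` maps motif label -> occurrence count in the region of
        ``region_nt`` nucleotides; ``expected_frequencies`` gives the
        composition-expected per-nucleotide frequency per motif, and
        ``reference_frequencies`` optionally a second (e.g. genome-wide)
        frequency to test against.
        """
        rows: list[EnrichmentResult] = []
        for label, k in observed.items():
            exp_f = expected_frequencies[label]
            if reference_frequencies is not None:
                res = enrichment_vs_reference(
                    observed_k=k,
                    region_nt=region_nt,
                    reference_frequency=reference_frequencies[label],
                    expected_freq=exp_f,
                    pattern_label=label,
                    region_label=region_label,
                    reference_label=reference_label,
                    alphas=alphas,
                )
            else:
                res = enrichment_vs_reference(
                    observed_k=k,
                    region_nt=region_nt,
                    reference_frequency=exp_f,
                    expected_freq=exp_f,
                    pattern_label=label,
                    region_label=region_label,
                    reference_label="expected",
                    alphas=alphas,
                )
                res.reference_label = None
                res.reference_frequency = None
                res.p_vs_reference = None
                res.log_p_vs_reference = None
            rows.append(res)
        model = cls.__new__(cls)
        model.patterns = [compile_pattern(lbl, lbl) for lbl in observed]
        model.upstream = None  # type: ignore[assignment]
        model.genome = None
        model.strand_policy = "both"
        model.profile_source = "explicit"
        model.profile = None
        model.alphas = tuple(alphas)
        model._count_rows = rows
        return model

    def fit(self) -> "MotifEnrichmentResults":
        """Run the census and binomial tests; return the results object."""
        if self._count_rows is not None:
            return MotifEnrichmentResults(self, self._count_rows)
        if self.genome is None:
            # no reference region: test against the composition null only
            profile = (
                self.profile
                if self.profile_source == "explicit"
                else composition_profile(self.upstream)
            )
            from .enrichment import enrichment_vs_expected
            from .motifs import count_occurrences

            rows = [
                enrichment_vs_expected(
                    count_occurrences(p, self.upstream, self.strand_policy),
                    self.upstream.total_nt,
                    profile,
                    region_label=self.upstream.region_label,
                    alphas=self.alphas,
                )
                for p in self.patterns
            ]
        else:
            rows = distribution_table(
                self.patterns,
                self.upstream,
                self.genome,
                strand_policy=self.strand_policy,
                profile_source=self.profile_source,
                profile=self.profile,
                alphas=self.alphas,
            )
        return MotifEnrichmentResults(self, rows)


@dataclass
class MotifEnrichmentResults:
    """Fitted enrichment results: per-motif rows, flags, and a summary table."""

    model: MotifEnrichment
    rows: list[EnrichmentResult]

    @property
    def table(self) -> pd.DataFrame:
        """One row per motif x region with all estimates and p-values."""
        recs = []
        for r in self.rows:
            rec = {
                "pattern": r.pattern_label,
                "region": r.region_label,
                "region_nt": r.region_nt,
                "observed": r.observed,
                "observed_frequency": r.observed_frequency,
                "expected_frequency": r.expected_frequency,
                "expected_count": r.expected_count,
                "p_vs_expected": r.p_vs_expected,
                "log_p_vs_expected": r.log_p_vs_expected,
                "reference_frequency": r.reference_frequency,
                "p_vs_reference": r.p_vs_reference,
            }
            for a in r.alphas:
                rec[f"sig_vs_expected_{a:g}"] = r.p_vs_expected < a
                if r.p_vs_reference is not None:
                    rec[f"sig_vs_reference_{a:g}"] = r.p_vs_reference < a
            recs.append(rec)
        return pd.DataFrame.from_records(recs)

    def significant_vs_expected(self, alpha: float = 0.01) -> list[str]:
        """Motifs whose region count beats the composition null at ``alpha``."""
        return [
            r.pattern_label
            for r in self._primary_rows()
            if r.p_vs_expected < alpha
        ]

    def not_significant_vs_expected(self, alpha: float = 0.01) -> list[str]:
        return [
            r.pattern_label
            for r in self._primary_rows()
            if not r.p_vs_expected < alpha
        ]

    def significant_vs_reference(self, alpha: float = 0.05) -> list[str]:
        """Motifs enriched in the region relative to the reference frequency."""
        return [
            r.pattern_label
            for r in self._primary_rows()
            if r.p_vs_reference is not None and r.p_vs_reference < alpha
        ]

    def _primary_rows(self) -> list[EnrichmentResult]:
        # the rows carrying the region-of-interest tests (first row per pattern)
        seen: set[str] = set()
        out = []
        for r in self.rows:
            if r.pattern_label not in seen:
                seen.add(r.pattern_label)
                out.append(r)
        return out

    def summary(self) -> str:
        """Human-readable summary table, statsmodels-style."""
        df = self.table
        lines = [
            "Motif enrichment (one-sided binomial, composition null)",
            f"regions: {', '.join(df['region'].unique())}; "
            f"strand policy: {self.model.strand_policy}; "
            f"alphas: {', '.join(f'{a:g}' for a in self.model.alphas)}",
            "",
        ]
        cols = [
            "pattern",
            "region",
            "observed",
            "expected_count",
            "observed_frequency",
            "expected_frequency",
            "p_vs_expected",
            "p_vs_reference",
        ]
        with pd.option_context("display.float_format", "{:.6G}".format):
            lines.append(df[cols].to_string(index=False))
        return "\n".join(lines)
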