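"""Exact one-sided binomial enrichment tests and the distribution report.

Enrichment of a motif in a region is assessed as the upper-tail probability
P(X >= k) for X ~ Binomial(n, p), where n is the region size in nucleotides,
k the observed occurrence count, and p either the composition-expected
per-nucleotide frequency or a reference (e.g. genome-wide) frequency.  The
tail is computed through the regularised incomplete beta identity, which is
stable for n up to 1e8 and beyond; for p-values that underflow double
precision, a log-space summed-PMF routine supplies the natural-log value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, inf, lgamma, log, log1p
from typing import Literal, Sequence

from scipy.stats import binom as _binom

from .background import (
    CompositionProfile,
    composition_profile,
    expected_frequency,
)
from .io import SequenceSet
from .motifs import MotifPattern, OccurrenceTable, StrandPolicy, count_occurrences

DEFAULT_ALPHAS = (0.05, 0.01)

#: below this the double-precision tail is untrustworthy; log value takes over
_UNDERFLOW = 1e-300


def binomial_upper_pvalue(k: int, n: int, p: float) -> float:
    """Exact one-sided upper tail P(X >= k), X ~ Binomial(n, p).

    Returns 1.0 exactly for k <= 0 and 0.0 only on true underflow (use
    :func:`binomial_upper_logpvalue` for those cases).
    """
    _check_binomial_args(k, n, p)
    if k <= 0:
        return 1.0
    # sf(k-1) = P(X >= k) via the incomplete-beta route inside scipy
    return float(_binom.sf(k - 1, n, p))


def binomial_lower_pvalue(k: int, n: int, p: float) -> float:
    """Lower tail P(X <= k); complementary to the strictly-above tail."""
    if k < 0:
        return 0.0
    _check_binomial_args(k, n, p)
    return float(_binom.cdf(k, n, p))


def binomial_upper_logpvalue(k: int, n: int, p: float) -> float:
    """Natural log of P(X >= k), stable when the tail underflows doubles.

    In the double-representable regime this is the log of the
    incomplete-beta tail; below ~1e-300 it switches to summing the PMF in
    log space from k upward, where for k above the mean the terms decay
    geometrically and the sum is truncated once the tail ratio bound makes
    further terms negligible.
    """
    _check_binomial_args(k, n, p)
    if k <= 0:
        return 0.0
    sf = float(_binom.sf(k - 1, n, p))
    if sf > _UNDERFLOW:
        return log(sf)
    logq = log1p(-p)
    logp = log(p)

    def logpmf(j: int) -> float:
        return (
            lgamma(n + 1)
            - lgamma(j + 1)
            - lgamma(n - j + 1)
            + j * logp
            + (n - j) * logq
        )

    # accumulate terms relative to the first (largest, since k > mean use
    # cases dominate; for k <= mean the double-precision tail is ~O(1))
    first = logpmf(k)
    total = 1.0  # sum of exp(logpmf(j) - first)
    prev = first
    j = k + 1
    while j <= n:
        cur = logpmf(j)
        term = exp(cur - first)
        total += term
        ratio = exp(cur - prev)
        prev = cur
        # remaining tail bounded by geometric series term*ratio/(1-ratio)
        if ratio < 1.0 and term * ratio / (1.0 - ratio) < 1e-16 * total:
            break
        j += 1
    return first + log(total)


def _check_binomial_args(k: int, n: int, p: float) -> None:
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0,1), got {p}")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")


@dataclass
class EnrichmentResult:
    """Observed vs expected motif content of one region, with binomial tests."""

    pattern_label: str
    region_label: str
    region_nt: int
    observed: int
    expected_frequency: float
    p_vs_expected: float
    log_p_vs_expected: float
    reference_label: str | None = None
    reference_frequency: float | None = None
    p_vs_reference: float | None = None
    log_p_vs_reference: float | None = None
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    strand_policy: str | None = None

    @property
    def observed_frequency(self) -> float:
        return self.observed / self.region_nt

    @property
    def expected_count(self) -> float:
        return self.region_nt * self.expected_frequency

    def significant_vs_expected(self, alpha: float) -> bool:
        return self.p_vs_expected < alpha

    def significant_vs_reference(self, alpha: float) -> bool:
        if self.p_vs_reference is None:
            raise ValueError("no reference comparison in this result")
        return self.p_vs_reference < alpha

    @property
    def flags(self) -> dict[str, dict[float, bool]]:
        out = {"vs_expected": {a: self.p_vs_expected < a for a in self.alphas}}
        if self.p_vs_reference is not None:
            out["vs_reference"] = {
                a: self.p_vs_reference < a for a in self.alphas
            }
        return out


def _tail(k: int, n: int, p: float) -> tuple[float, float]:
    pv = binomial_upper_pvalue(k, n, p)
    logpv = binomial_upper_logpvalue(k, n, p) if pv < _UNDERFLOW else (
        log(pv) if pv > 0 else -inf
    )
    if pv < _UNDERFLOW:
        pv = exp(logpv) if logpv > -745 else 0.0
    return pv, logpv


def enrichment_vs_expected(
    observed: OccurrenceTable,
    region_nt: int,
    profile: CompositionProfile,
    region_label: str = "region",
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> EnrichmentResult:
    """Test an observed count against its composition-expected frequency."""
    if region_nt <= 0:
        raise ValueError(f"region_nt must be > 0, got {region_nt}")
    k = observed.total
    p = expected_frequency(observed.pattern, profile)
    pv, logpv = _tail(k, region_nt, p)
    return EnrichmentResult(
        pattern_label=observed.pattern.label,
        region_label=region_label,
        region_nt=region_nt,
        observed=k,
        expected_frequency=p,
        p_vs_expected=pv,
        log_p_vs_expected=logpv,
        alphas=tuple(alphas),
        strand_policy=observed.strand_policy,
    )


def enrichment_vs_reference(
    observed_k: int,
    region_nt: int,
    reference_frequency: float,
    expected_freq: float | None = None,
    pattern_label: str = "pattern",
    region_label: str = "region",
    reference_label: str = "reference",
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> EnrichmentResult:
    """Test an observed count against an externally measured frequency."""
    if region_nt <= 0:
        raise ValueError(f"region_nt must be > 0, got {region_nt}")
    pv_ref, logpv_ref = _tail(observed_k, region_nt, reference_frequency)
    if expected_freq is not None:
        pv_exp, logpv_exp = _tail(observed_k, region_nt, expected_freq)
    else:
        expected_freq, pv_exp, logpv_exp = reference_frequency, pv_ref, logpv_ref
    return EnrichmentResult(
        pattern_label=pattern_label,
        region_label=region_label,
        region_nt=region_nt,
        observed=observed_k,
        expected_frequency=expected_freq,
        p_vs_expected=pv_exp,
        log_p_vs_expected=logpv_exp,
        reference_label=reference_label,
        reference_frequency=reference_frequency,
        p_vs_reference=pv_ref,
        log_p_vs_reference=logpv_ref,
        alphas=tuple(alphas),
    )


def distribution_table(
    patterns: Sequence[MotifPattern],
    upstream: SequenceSet,
    genome: SequenceSet,
    strand_policy: StrandPolicy = "both",
    profile_source: Literal["upstream", "genome", "explicit"] = "upstream",
    profile: CompositionProfile | None = None,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> list[EnrichmentResult]:
    """Full distribution report: one row per pattern per region.

    For each pattern, the upstream region is tested both against the
    composition-expected frequency (from ``profile_source``) and against the
    genome-wide observed frequency; the genome row carries the vs-expected
    test only.  Row order is pattern order, upstream before genome.
    """
    if not patterns:
        raise ValueError("distribution_table: empty pattern list")
    if profile_source == "explicit":
        if profile is None:
            raise ValueError("profile_source='explicit' requires a profile")
    elif profile_source == "upstream":
        profile = composition_profile(upstream)
    elif profile_source == "genome":
        profile = composition_profile(genome)
    else:
        raise ValueError(f"unknown profile_source {profile_source!r}")

    n_up = upstream.total_nt
    n_gen = genome.total_nt
    rows: list[EnrichmentResult] = []
    for pat in patterns:
        k_up = count_occurrences(pat, upstream, strand_policy).total
        k_gen = count_occurrences(pat, genome, strand_policy).total
        exp_f = expected_frequency(pat, profile)
        genome_freq = k_gen / n_gen
        pv_exp, logpv_exp = _tail(k_up, n_up, exp_f)
        if 0 < genome_freq < 1:
            pv_ref, logpv_ref = _tail(k_up, n_up, genome_freq)
        else:  # motif absent from (or saturating) the reference: no test
            pv_ref = logpv_ref = None
        rows.append(
            EnrichmentResult(
                pattern_label=pat.label,
                region_label=upstream.region_label,
                region_nt=n_up,
                observed=k_up,
                expected_frequency=exp_f,
                p_vs_expected=pv_exp,
                log_p_vs_expected=logpv_exp,
                reference_label=genome.region_label,
                reference_frequency=genome_freq,
                p_vs_reference=pv_ref,
                log_p_vs_reference=logpv_ref,
                alphas=tuple(alphas),
                strand_policy=strand_policy,
            )
        )
        pv_g, logpv_g = _tail(k_gen, n_gen, exp_f)
        rows.append(
            EnrichmentResult(
                pattern_label=pat.label,
                region_label=genome.region_label,
                region_nt=n_gen,
                observed=k_gen,
                expected_frequency=exp_f,
                p_vs_expected=pv_g,
                log_p_vs_expected=logpv_g,
                alphas=tuple(alphas),
                strand_policy=strand_policy,
            )
        )
    return rows
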