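"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's scanning/statistics code
paths: the window matcher enumerates windows directly against its own IUPAC
table, and the binomial tail is summed term-by-term with ``math.lgamma``.
"""

from __future__ import annotations

import random

import pytest

from wtbox.io import SequenceSet

# --- independent IUPAC window-matching oracle -------------------------------

ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(s: str) -> str:
    return "".join(_RC[b] for b in reversed(s))


def oracle_matches(iupac: str, window: str) -> bool:
    return len(window) == len(iupac) and all(
        b in ORACLE_IUPAC[c] for b, c in zip(window, iupac)
    )


def brute_force_hits(iupac: str, seq: str, strand_policy: str):
    """All (start, strand) matches by direct window enumeration.

    A minus-strand hit at forward start i means the reverse complement of the
    window matches the pattern read 5'->3' on the minus strand.
    """
    k = len(iupac)
    hits = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        if oracle_matches(iupac, window):
            hits.append((i + 1, "+"))
        if strand_policy == "both" and oracle_matches(iupac, oracle_revcomp(window)):
            hits.append((i + 1, "-"))
    return sorted(hits)


# --- independent binomial upper-tail oracle ---------------------------------


def oracle_binomial_sf(k: int, n: int, p: float) -> float:
    """P(X >= k) by high-precision PMF summation (50-digit arithmetic)."""
    return float(_mp_binomial_sf(k, n, p))


def oracle_binomial_log_sf(k: int, n: int, p: float) -> float:
    """Natural log of P(X >= k) at 50-digit precision (deep-tail safe)."""
    import mpmath as mp

    with mp.workdps(50):
        return float(mp.log(_mp_binomial_sf(k, n, p)))


def _mp_binomial_sf(k: int, n: int, p: float):
    """High-precision upper tail.

    The first term comes from loggamma; successive terms use the exact
    recurrence pmf(j+1) = pmf(j) * (n-j)/(j+1) * p/(1-p), so no catastrophic
    cancellation enters the sum.  Independent of the package's
    incomplete-beta and double-precision log-summation routes.
    """
    import mpmath as mp

    if k <= 0:
        return mp.mpf(1)
    with mp.workdps(50):
        mpp = mp.mpf(repr(p))
        q = 1 - mpp
        logt = (
            mp.loggamma(n + 1) - mp.loggamma(k + 1) - mp.loggamma(n - k + 1)
            + k * mp.log(mpp) + (n - k) * mp.log(q)
        )
        t = mp.e ** logt
        total = t
        j = k
        while j < n:
            t = t * (n - j) / (j + 1) * mpp / q
            total += t
            j += 1
            if j > n * mpp and t < total * mp.mpf("1e-45"):
                break
        return total


# --- fixtures ----------------------------------------------------------------


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text: str, name: str = "seqs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def random_sequence():
    """Seeded random ACGT(N) sequence factory."""
    rng = random.Random(20260921)

    def _make(length: int, alphabet: str = "ACGT") -> str:
        return "".join(rng.choice(alphabet) for _ in range(length))

    return _make


def make_set(label: str = "test", **seqs: str) -> SequenceSet:
    from wtbox.io import SequenceRecord

    return SequenceSet(
        records=[SequenceRecord(id=k, residues=v) for k, v in seqs.items()],
        region_label=label,
    )
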