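"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the alignment oracle
enumerates every position on both strands with a vectorized window compare,
the trimming oracles evaluate every cut point explicitly, the binomial
oracle sums probability-mass terms, and the ping-pong oracles loop over all
read pairs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from visrna.align import AlignmentRecord
from visrna.simulate import SimRead, revcomp


def brute_force_alignments(sequence: str, reference: str, max_mismatches: int = 1):
    """All (strand, start, mismatches) placements by full enumeration.

    'N' on either side always counts as a mismatch.
    """
    out = []
    ref_arr = np.frombuffer(reference.upper().encode(), dtype="S1")
    for strand, query in (("+", sequence.upper()), ("-", revcomp(sequence.upper()))):
        L = len(query)
        if L > len(reference) or L == 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
        q_arr = np.frombuffer(query.encode(), dtype="S1")
        mismatch = (windows != q_arr) | (windows == b"N") | (q_arr == b"N")
        mm = mismatch.sum(axis=1)
        for start in np.flatnonzero(mm <= max_mismatches):
            out.append((strand, int(start), int(mm[start])))
    return sorted(out)


def adapter_trim_oracle(sequence: str, adapter: str, min_overlap: int, max_error_rate: float) -> int:
    """Leftmost cut position for 3'-adapter removal; len(sequence) if none.

    A suffix starting at i matches when its overlap with the adapter prefix
    is >= min_overlap and the mismatch fraction is <= max_error_rate.
    """
    n = len(sequence)
    for i in range(n):
        overlap = min(n - i, len(adapter))
        if overlap < min_overlap:
            continue
        mm = sum(1 for a, b in zip(sequence[i : i + overlap], adapter[:overlap]) if a != b)
        if overlap > 0 and mm / overlap <= max_error_rate:
            return i
    return n


def quality_trim_oracle(qualities, threshold: int) -> int:
    """Cut position maximizing the removed-suffix penalty sum.

    Evaluates every cut explicitly; ties resolved toward the rightmost cut
    (least trimming); no cut when no suffix has positive penalty.
    """
    n = len(qualities)
    best_score, best_cut = 0, n
    for cut in range(n, -1, -1):
        score = sum(threshold - q for q in qualities[cut:])
        if score > best_score or (score == best_score and cut > best_cut):
            best_score, best_cut = score, cut
    return best_cut


def binomial_two_sided_oracle(count: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value by direct summation of the pmf."""
    pmf_obs = stats.binom.pmf(count, n, p)
    total = 0.0
    for k in range(n + 1):
        pk = stats.binom.pmf(k, n, p)
        if pk <= pmf_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


def pingpong_allpairs_oracle(records, max_overlap: int = 20) -> np.ndarray:
    """Quadratic all-pairs 5'-5' overlap histogram."""
    counts = np.zeros(max_overlap, dtype=np.int64)
    plus = [r for r in records if r.strand == "+"]
    minus = [r for r in records if r.strand == "-"]
    for a in plus:
        for b in minus:
            overlap = b.five_prime - a.five_prime + 1
            if 1 <= overlap <= max_overlap:
                counts[overlap - 1] += 1
    return counts


def pingpong_dedup_oracle(records, max_overlap: int = 20) -> np.ndarray:
    """Distinct (5'+, 5'-) pairs weighted by the smaller multiplicity."""
    counts = np.zeros(max_overlap, dtype=np.int64)
    plus: dict[int, int] = {}
    minus: dict[int, int] = {}
    for r in records:
        d = plus if r.strand == "+" else minus
        d[r.five_prime] = d.get(r.five_prime, 0) + 1
    for p, mp in plus.items():
        for q, mq in minus.items():
            overlap = q - p + 1
            if 1 <= overlap <= max_overlap:
                counts[overlap - 1] += min(mp, mq)
    return counts


def record_from_simread(read: SimRead, reference: str = "") -> AlignmentRecord:
    """Truth-based alignment record for an error-free simulated read."""
    forward = read.sequence if read.strand == "+" else revcomp(read.sequence)
    return AlignmentRecord(
        read_id="",
        reference=reference or read.source,
        strand=read.strand,
        start=read.start,
        read_length=len(read.sequence),
        mismatches=0,
        sequence=forward,
    )
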