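"""piRNA signature analytics: positional nucleotide frequencies, 1U/10A
bias tests and the ping-pong 5'-overlap statistic.

Primary piRNAs carry a uridine bias at position 1 (1U); secondary piRNAs,
produced by ping-pong amplification, carry an adenine at position 10 (10A)
because their 5' ends overlap the 5' ends of complementary primary piRNAs by
exactly 10 nt.  For virus-derived 26-30 nt reads the canonical arrangement
is 1U on the strand feeding primary biogenesis and 10A on the opposite
strand; degradation products show neither bias and no 10 nt overlap
enrichment.

Positions are 1-based from the read's biological 5' end.  For '-' strand
placements, read-space sequences (reverse complement of the reference
window) are used, so position 1 is always the sequenced 5' nucleotide.
T is reported as U, matching the RNA identity of the molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentRecord
from .simulate import revcomp

RNA_BASES = ("A", "C", "G", "U")
_DNA_TO_COL = {"A": 0, "C": 1, "G": 2, "T": 3}  # T counted in the U column


@dataclass
class FrequencyMatrix:
    """Per-position nucleotide composition of a 5'-anchored read class.

    ``counts[p, b]`` is the number of reads whose position ``p+1`` (1-based
    from the 5' end) is base ``RNA_BASES[b]``; ``coverage[p]`` is the number
    of reads long enough to cover the position, which is non-increasing for
    variable-length classes.
    """

    strand: str
    class_label: str
    counts: np.ndarray  # (max_len, 4) ints
    coverage: np.ndarray  # (max_len,) ints

    @property
    def max_len(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        """Row-normalized counts; rows with zero coverage are NaN."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / self.coverage[:, None]

    def frequency(self, position: int, base: str) -> float:
        """Frequency of ``base`` (A/C/G/U) at a 1-based position."""
        return float(self.frequencies[position - 1, RNA_BASES.index(base)])

    def to_frame(self) -> pd.DataFrame:
        freq = self.frequencies
        df = pd.DataFrame(freq, columns=list(RNA_BASES))
        df.insert(0, "position", np.arange(1, self.max_len + 1))
        df["coverage"] = self.coverage
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def nucleotide_frequency_matrix(
    records: Iterable[AlignmentRecord],
    strand: str,
    max_len: int = 30,
    class_label: str = "",
) -> FrequencyMatrix:
    """Positional base composition of reads on one strand.

    Reads are anchored at their 5' ends; '-' strand reads contribute their
    read-space sequence, so the matrix reflects the sequenced molecules.
    An empty class yields an all-zero matrix.
    """
    counts = np.zeros((max_len, 4), dtype=np.int64)
    coverage = np.zeros(max_len, dtype=np.int64)
    for rec in records:
        if rec.strand != strand:
            continue
        seq = rec.read_sequence  # 5'->3' as sequenced
        upto = min(len(seq), max_len)
        coverage[:upto] += 1
        for pos in range(upto):
            col = _DNA_TO_COL.get(seq[pos])
            # N contributes to coverage but to no base column
            if col is not None:
                counts[pos, col] += 1
    return FrequencyMatrix(strand=strand, class_label=class_label, counts=counts, coverage=coverage)


def strand_composition(genome: str, strand: str) -> dict[str, float]:
    """Base composition (A/C/G/U) of one strand of a reference.

    The '-' strand composition is the complement of the deposited sequence's
    composition; used as the background for bias tests because viral genomes
    are compositionally skewed.
    """
    seq = genome if strand == "+" else revcomp(genome)
    n = len(seq)
    return {
        "A": seq.count("A") / n,
        "C": seq.count("C") / n,
        "G": seq.count("G") / n,
        "U": seq.count("T") / n,
    }


@dataclass(frozen=True)
class BiasResult:
    """Exact binomial test of a positional nucleotide enrichment."""

    position: int
    nucleotide: str
    strand: str
    observed_frequency: float
    coverage: int
    background: float
    p_value: float
    biased: bool


def bias_test(
    matrix: FrequencyMatrix,
    position: int,
    nucleotide: str,
    background: float,
    alpha: float = 0.01,
) -> BiasResult:
    """Two-sided exact binomial test of the base count at one position.

    ``biased`` requires both significance at ``alpha`` and enrichment above
    the background frequency (a depletion is significant but not a bias).
    """
    coverage = int(matrix.coverage[position - 1])
    if coverage == 0:
        raise ValueError(f"no reads cover position {position}")
    count = int(matrix.counts[position - 1, RNA_BASES.index(nucleotide)])
    result = stats.binomtest(count, coverage, background, alternative="two-sided")
    freq = count / coverage
    return BiasResult(
        position=position,
        nucleotide=nucleotide,
        strand=matrix.strand,
        observed_frequency=freq,
        coverage=coverage,
        background=background,
        p_value=float(result.pvalue),
        biased=bool(result.pvalue < alpha and freq > background),
    )


@dataclass
class OverlapHistogram:
    """Counts of opposite-strand read pairs by 5'-5' overlap length.

    ``counts[o - 1]`` holds the weight of pairs whose 5' ends overlap by
    exactly ``o`` nt (o = 1..max_overlap).  ``z10`` standardizes the 10 nt
    bin against the empirical distribution of the other bins; it is None
    when fewer than two of those bins are nonzero or their spread is zero,
    since no null scale can then be estimated.
    """

    counts: np.ndarray
    mode: str = "dedup"

    @property
    def max_overlap(self) -> int:
        return len(self.counts)

    @property
    def argmax_bin(self) -> int | None:
        """1-based overlap length with the largest count; None if empty."""
        if self.counts.sum() == 0:
            return None
        return int(np.argmax(self.counts)) + 1

    @property
    def z10(self) -> float | None:
        others = np.delete(self.counts.astype(float), 9)
        if np.count_nonzero(others) < 2:
            return None
        sd = float(others.std(ddof=1))
        if sd == 0:
            return None
        return (float(self.counts[9]) - float(others.mean())) / sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"overlap": np.arange(1, self.max_overlap + 1), "pairs": self.counts}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def pingpong_overlap(
    records: Iterable[AlignmentRecord],
    reference_length: int,
    max_overlap: int = 20,
    mode: str = "dedup",
) -> OverlapHistogram:
    """5'-5' overlap histogram between '+' and '-' strand reads.

    A '+' read with 5' end at p and a '-' read with 5' end at q >= p overlap
    by ``q - p + 1`` nt in reference space.  ``mode="dedup"`` counts each
    distinct (p, q) position pair once, weighted by the smaller of the two
    positional read multiplicities, damping the quadratic blow-up of ping-pong
    towers; ``mode="allpairs"`` counts every read pair (the brute-force
    definition used by the oracle comparison).
    """
    if mode not in ("dedup", "allpairs"):
        raise ValueError(f"unknown mode {mode!r}")
    plus = np.zeros(reference_length, dtype=np.int64)
    minus = np.zeros(reference_length, dtype=np.int64)
    for rec in records:
        (plus if rec.strand == "+" else minus)[rec.five_prime] += 1
    counts = np.zeros(max_overlap, dtype=np.int64)
    for overlap in range(1, max_overlap + 1):
        shift = overlap - 1
        p = plus[: reference_length - shift]
        q = minus[shift:]
        if mode == "dedup":
            counts[overlap - 1] = int(np.minimum(p, q)[(p > 0) & (q > 0)].sum())
        else:
            counts[overlap - 1] = int((p * q).sum())
    return OverlapHistogram(counts=counts, mode=mode)


def bias_results_frame(results: Sequence[BiasResult], virus: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "virus": virus,
                "strand": r.strand,
                "position": r.position,
                "nucleotide": r.nucleotide,
                "observed_frequency": r.observed_frequency,
                "coverage": r.coverage,
                "background": r.background,
                "p_value": r.p_value,
                "biased": r.biased,
            }
            for r in results
        ],
        columns=[
            "virus",
            "strand",
            "position",
            "nucleotide",
            "observed_frequency",
            "coverage",
            "background",
            "p_value",
            "biased",
        ],
    )
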