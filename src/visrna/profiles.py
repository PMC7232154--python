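"""Size distributions, RPM normalization, strand-resolved coverage profiles,
hotspot detection and the vpiRNA:vsiRNA proportion statistic.

Conventions
-----------
* Profiles count 5' ends, one count per read: for a '+' strand placement the
  5' end is the leftmost reference position, for a '-' strand placement the
  rightmost (the biological 5' terminus).  This makes conservation exact:
  a profile sums to its class read count.  A per-base coverage mode is
  available for plotting.
* The vpiRNA:vsiRNA proportion is the number of virus-derived 26-30 nt reads
  per 100 virus-derived 21 nt reads; it is flagged undefined (not zero) when
  there are no 21 nt reads.
* RPM = 1e6 * count / library_total, with the library total taken as reads
  kept after trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord, LibraryAlignment
from .preprocess import TrimmedRead

SIRNA_LENGTH = 21
PIRNA_WINDOW = (26, 30)
LENGTH_RANGE = (19, 33)


def size_distribution(
    items: Iterable,
    scope: str = "mapped",
    min_len: int = LENGTH_RANGE[0],
    max_len: int = LENGTH_RANGE[1],
) -> pd.DataFrame:
    """Per-length read counts, strand-resolved for mapped reads.

    ``scope="mapped"`` takes :class:`AlignmentRecord` items and returns
    columns ``plus``/``minus``; ``scope="library"`` takes trimmed reads (or
    plain lengths) and returns a single ``count`` column, since strand is
    undefined before mapping.  Indexed by length over the full window, so an
    empty input yields an all-zero table.
    """
    lengths = range(min_len, max_len + 1)
    if scope == "mapped":
        df = pd.DataFrame(0, index=lengths, columns=["plus", "minus"])
        for rec in items:
            col = "plus" if rec.strand == "+" else "minus"
            df.loc[rec.read_length, col] += 1
    elif scope == "library":
        df = pd.DataFrame(0, index=lengths, columns=["count"])
        for item in items:
            length = item if isinstance(item, int) else len(item)
            df.loc[length, "count"] += 1
    else:
        raise ValueError(f"unknown scope {scope!r}")
    df.index.name = "length"
    return df


@dataclass(frozen=True)
class RpmValue:
    """A count normalized to reads per million library reads."""

    raw: int
    library_total: int
    value: float

    def __float__(self) -> float:
        return self.value


def rpm_normalize(raw: int, library_total: int) -> RpmValue:
    """Reads-per-million normalization: 1e6 * raw / library_total."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    if raw < 0:
        raise ValueError("raw count must be >= 0")
    return RpmValue(raw, library_total, 1e6 * raw / library_total)


@dataclass
class CoverageProfile:
    """Per-position, strand-resolved 5'-end counts for one length class."""

    virus: str
    length_class: tuple[int, int]
    plus: np.ndarray
    minus: np.ndarray
    mode: str = "5prime"
    annotations: tuple[tuple[str, int, int], ...] = ()

    @property
    def n_reads(self) -> int:
        """Total counts; equals the class read count in 5'-end mode."""
        return int(self.plus.sum() + self.minus.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"position": np.arange(len(self.plus)), "plus": self.plus, "minus": self.minus}
        )
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def coverage_profile(
    alignment: LibraryAlignment,
    length_class: tuple[int, int] = PIRNA_WINDOW,
    mode: str = "5prime",
    annotations: Sequence[tuple[str, int, int]] = (),
) -> CoverageProfile:
    """Strand-resolved positional profile of one read-length class.

    ``mode="5prime"`` increments the single 5'-end position per read;
    ``mode="perbase"`` increments every covered position (for plots that show
    full read footprints).
    """
    if mode not in ("5prime", "perbase"):
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = length_class
    G = alignment.reference_length
    plus = np.zeros(G, dtype=np.int64)
    minus = np.zeros(G, dtype=np.int64)
    for rec in alignment.records:
        if not (lo <= rec.read_length <= hi):
            continue
        track = plus if rec.strand == "+" else minus
        if mode == "5prime":
            track[rec.five_prime] += 1
        else:
            track[rec.start : rec.end] += 1
    return CoverageProfile(
        virus=alignment.reference,
        length_class=(lo, hi),
        plus=plus,
        minus=minus,
        mode=mode,
        annotations=tuple(annotations),
    )


@dataclass(frozen=True)
class RatioStatistic:
    """vpiRNA-candidate reads per 100 vsiRNA reads for one virus."""

    virus: str
    tissue: str
    n_26_30: int
    n_21: int
    value: float | None
    undefined: bool

    def __post_init__(self) -> None:
        if self.n_26_30 < 0 or self.n_21 < 0:
            raise ValueError("read counts must be non-negative")


def vpirna_vsirna_ratio(
    n_26_30: int, n_21: int, virus: str = "", tissue: str = ""
) -> RatioStatistic:
    """26-30 nt reads per 100 21 nt reads; undefined when n_21 == 0."""
    if n_26_30 < 0 or n_21 < 0:
        raise ValueError("read counts must be non-negative")
    if n_21 == 0:
        return RatioStatistic(virus, tissue, n_26_30, n_21, None, True)
    return RatioStatistic(virus, tissue, n_26_30, n_21, 100.0 * n_26_30 / n_21, False)


def class_counts(
    alignment: LibraryAlignment,
    sirna_length: int = SIRNA_LENGTH,
    pirna_window: tuple[int, int] = PIRNA_WINDOW,
) -> tuple[int, int]:
    """(n_21, n_26_30) mapped-read counts for one virus."""
    n21 = sum(1 for r in alignment.records if r.read_length == sirna_length)
    lo, hi = pirna_window
    n2630 = sum(1 for r in alignment.records if lo <= r.read_length <= hi)
    return n21, n2630


@dataclass(frozen=True)
class Hotspot:
    """A run of unusually dense 5'-end positions on one strand."""

    start: int
    end: int  # exclusive
    strand: str
    fold_over_median: float


def _runs_above(counts: np.ndarray, threshold: float, gap: int) -> list[tuple[int, int]]:
    above = np.flatnonzero(counts >= threshold)
    if above.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(above[0])
    for pos in above[1:]:
        pos = int(pos)
        if pos - prev > gap + 1:
            runs.append((start, prev + 1))
            start = pos
        prev = pos
    runs.append((start, prev + 1))
    return runs


def hotspot_flags(
    profile: CoverageProfile,
    fold: float = 5.0,
    min_count: int = 10,
    gap: int = 5,
) -> list[Hotspot]:
    """Flag maximal position runs whose counts exceed the background.

    A position qualifies when its count >= max(``min_count``, ``fold`` x the
    nonzero median of its strand); qualifying positions closer than ``gap``
    are merged.  Thresholds are heuristic defaults for screening, not a
    calibrated test.
    """
    hotspots: list[Hotspot] = []
    for strand, counts in (("+", profile.plus), ("-", profile.minus)):
        nonzero = counts[counts > 0]
        if nonzero.size == 0:
            continue
        median = float(np.median(nonzero))
        threshold = max(float(min_count), fold * median)
        for start, end in _runs_above(counts, threshold, gap):
            mean_count = float(counts[start:end].mean())
            hotspots.append(
                Hotspot(start, end, strand, mean_count / median if median else np.inf)
            )
    return hotspots


def hotspots_to_frame(hotspots: Sequence[Hotspot], virus: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "virus": virus,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "fold_over_median": h.fold_over_median,
            }
            for h in hotspots
        ],
        columns=["virus", "start", "end", "strand", "fold_over_median"],
    )
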