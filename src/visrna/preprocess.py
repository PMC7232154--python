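"""Adapter and quality trimming with length filtering for small-RNA reads.

The cleaning contract is the standard one for gel-purified small-RNA
libraries: strip the 3' sequencing adapter, trim low-quality 3' tails at a
Phred threshold (default 20), then keep only reads inside the gel size
window (default 19-33 nt).  The trimmer is a self-contained re-implementation
of the usual cutadapt-style 3'-adapter semantics (leftmost read suffix vs
adapter prefix, mismatch fraction bounded by an error rate) so the pipeline
has no external tool dependency and its behavior is exactly testable.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_QUALITY_THRESHOLD = 20
DEFAULT_MIN_LEN = 19
DEFAULT_MAX_LEN = 33
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MAX_ERROR_RATE = 0.1


@dataclass(frozen=True)
class RawRead:
    """A read as sequenced: id, bases (ACGTN) and per-base Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrimmedRead:
    """Outcome of the trimming pipeline for one read."""

    id: str
    sequence: str
    original_length: int
    kept: bool
    discard_reason: str  # none | too_short | too_long | low_quality

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QCReport:
    """Per-library trimming accounting; conserves read counts exactly."""

    reads_in: int = 0
    reads_kept: int = 0
    discards: dict[str, int] = field(
        default_factory=lambda: {"too_short": 0, "too_long": 0, "low_quality": 0}
    )
    length_histogram: dict[int, int] = field(default_factory=dict)

    def add(self, read: TrimmedRead) -> None:
        self.reads_in += 1
        if read.kept:
            self.reads_kept += 1
            length = len(read.sequence)
            self.length_histogram[length] = self.length_histogram.get(length, 0) + 1
        else:
            self.discards[read.discard_reason] += 1

    @property
    def conserved(self) -> bool:
        return self.reads_in == self.reads_kept + sum(self.discards.values())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("metric\tvalue\n")
            handle.write(f"reads_in\t{self.reads_in}\n")
            handle.write(f"reads_kept\t{self.reads_kept}\n")
            for reason in sorted(self.discards):
                handle.write(f"discard_{reason}\t{self.discards[reason]}\n")
            for length in sorted(self.length_histogram):
                handle.write(f"length_{length}\t{self.length_histogram[length]}\n")


def trim_adapter(
    read: RawRead,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> RawRead:
    """Remove a 3' adapter occurrence from a read.

    Scans read positions left to right; at position ``i`` the read suffix is
    compared with the adapter prefix of the same length.  The leftmost
    position with overlap >= ``min_overlap`` and at most
    ``floor(max_error_rate * overlap)`` mismatches wins; the suffix from
    there is removed, qualities in lockstep.  No occurrence leaves the read
    unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq, n = read.sequence, len(read.sequence)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        if overlap < min_overlap:
            break
        allowed = int(max_error_rate * overlap)
        mismatches = 0
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        if mismatches <= allowed:
            return RawRead(read.id, seq[:i], read.qualities[:i])
    return read


def quality_trim(read: RawRead, threshold: int = DEFAULT_QUALITY_THRESHOLD) -> RawRead:
    """3'-end quality trimming by the BWA-style running-sum rule.

    The read is cut at the position maximizing the summed penalty
    ``threshold - q`` over the removed suffix; among ties the rightmost cut
    (least trimming) is chosen, and nothing is removed when no suffix has a
    positive penalty sum (e.g. an all-high-quality read).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    best, best_cut, running = 0, len(read), 0
    for i in range(len(read) - 1, -1, -1):
        running += threshold - read.qualities[i]
        if running > best:
            best, best_cut = running, i
    if best_cut == len(read):
        return read
    return RawRead(read.id, read.sequence[:best_cut], read.qualities[:best_cut])


def length_filter(
    read: RawRead,
    original_length: int | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    quality_emptied: bool = False,
) -> TrimmedRead:
    """Classify a trimmed read against the gel size window."""
    length = len(read)
    original = original_length if original_length is not None else length
    if length == 0 and quality_emptied:
        return TrimmedRead(read.id, read.sequence, original, False, "low_quality")
    if length < min_len:
        return TrimmedRead(read.id, read.sequence, original, False, "too_short")
    if length > max_len:
        return TrimmedRead(read.id, read.sequence, original, False, "too_long")
    return TrimmedRead(read.id, read.sequence, original, True, "none")


def process_read(
    read: RawRead,
    adapter: str = "",
    quality_threshold: int = DEFAULT_QUALITY_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> TrimmedRead:
    """Full cleaning of one read: adapter -> quality -> length window.

    Adapter trimming runs first because adapter bases carry synthetic
    quality values that would distort the quality cut.
    """
    original_length = len(read)
    trimmed = trim_adapter(read, adapter, min_overlap, max_error_rate) if adapter else read
    after_adapter = len(trimmed)
    trimmed = quality_trim(trimmed, quality_threshold)
    quality_emptied = after_adapter > 0 and len(trimmed) == 0
    return length_filter(
        trimmed,
        original_length=original_length,
        min_len=min_len,
        max_len=max_len,
        quality_emptied=quality_emptied,
    )


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Iterate a FASTQ file (Phred+33, plain or gzip) as :class:`RawRead`."""
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield RawRead(
                record.id,
                str(record.seq).upper(),
                tuple(record.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[TrimmedRead], path: str | Path, quality: int = 37) -> int:
    """Write kept reads as FASTQ with a constant quality; returns count."""
    count = 0
    with _open_maybe_gzip(path, "wt") as handle:
        for read in reads:
            record = SeqRecord(Seq(read.sequence), id=read.id, description="")
            record.letter_annotations["phred_quality"] = [quality] * len(read.sequence)
            SeqIO.write([record], handle, "fastq")
            count += 1
    return count


def process_fastq(
    in_path: str | Path,
    out_path: str | Path | None = None,
    adapter: str = "",
    quality_threshold: int = DEFAULT_QUALITY_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> tuple[list[TrimmedRead], QCReport]:
    """Clean a whole FASTQ file; returns kept reads and the QC report.

    ``reads_kept`` in the report is the library total used downstream as the
    RPM denominator.
    """
    report = QCReport()
    kept: list[TrimmedRead] = []
    for raw in read_fastq(in_path):
        trimmed = process_read(
            raw,
            adapter=adapter,
            quality_threshold=quality_threshold,
            min_len=min_len,
            max_len=max_len,
            min_overlap=min_overlap,
            max_error_rate=max_error_rate,
        )
        report.add(trimmed)
        if trimmed.kept:
            kept.append(trimmed)
    if out_path is not None:
        write_fastq(kept, out_path)
    return kept, report
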