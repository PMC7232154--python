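"""Short-read alignment to viral genomes allowing at most one mismatch.

This is a deliberately small, exact aligner for 19-33 nt reads mapped to
kilobase-scale viral references, emulating bowtie's ``-v 1`` end-to-end
mode: candidate placements on both strands with <= 1 mismatch, best-stratum
(0-mismatch beats 1-mismatch) single-placement reporting, uniform random
tie-breaking under a run seed, and SAM output.

Candidate generation uses pigeonhole seeding: the index stores every
``seed_len``-mer of the reference; a read is looked up at offsets 0 and
``seed_len``.  With one allowed mismatch and two disjoint seed windows, at
least one window is mismatch-free, so no valid placement is ever missed
(reads shorter than two seeds fall back to a full scan).  'N' in read or
reference always counts as a mismatch, which also preserves the guarantee:
an exact seed hit implies a mismatch-free, N-free window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .preprocess import TrimmedRead
from .simulate import revcomp

DEFAULT_SEED_LEN = 9  # floor(min read length 19 / 2)


def count_mismatches(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance where 'N' on either side is always a mismatch."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if limit is not None and mm > limit:
                return mm
    return mm


class ReferenceIndex:
    """Exact-match seed table over one reference sequence."""

    def __init__(self, name: str, sequence: str, seed_len: int = DEFAULT_SEED_LEN):
        if not sequence:
            raise ValueError("reference sequence is empty")
        if seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        self.name = name
        self.sequence = sequence.upper()
        self.seed_len = seed_len
        table: dict[str, list[int]] = {}
        for pos in range(len(self.sequence) - seed_len + 1):
            kmer = self.sequence[pos : pos + seed_len]
            table.setdefault(kmer, []).append(pos)
        self._table = {k: tuple(v) for k, v in table.items()}

    def __len__(self) -> int:
        return len(self.sequence)

    def lookup(self, kmer: str) -> tuple[int, ...]:
        """All reference positions where ``kmer`` occurs exactly."""
        return self._table.get(kmer, ())


def build_index(
    name: str, sequence: str, seed_len: int = DEFAULT_SEED_LEN
) -> ReferenceIndex:
    return ReferenceIndex(name, sequence, seed_len)


@dataclass(frozen=True)
class AlignmentRecord:
    """One counted placement of a read on a reference.

    ``sequence`` is stored in reference-forward orientation (for '-' strand
    placements it is the reverse complement of the read as sequenced), the
    SAM convention.
    """

    read_id: str
    reference: str
    strand: str
    start: int  # 0-based leftmost reference position
    read_length: int
    mismatches: int
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        if self.start < 0:
            raise ValueError("start must be >= 0")

    @property
    def end(self) -> int:
        """Exclusive rightmost reference position."""
        return self.start + self.read_length

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the read's biological 5' end."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def read_sequence(self) -> str:
        """The read as sequenced (5'->3' in read space)."""
        return self.sequence if self.strand == "+" else revcomp(self.sequence)


@dataclass
class LibraryAlignment:
    """All counted placements of one library on one reference."""

    reference: str
    reference_length: int
    records: list[AlignmentRecord]
    library_total: int  # RPM denominator: reads kept after preprocessing
    n_unmapped: int = 0

    @property
    def n_mapped(self) -> int:
        return len(self.records)


def _seed_candidates(query: str, index: ReferenceIndex) -> set[int]:
    """Candidate start positions for one orientation of a read."""
    L, k, G = len(query), index.seed_len, len(index)
    starts: set[int] = set()
    if L >= 2 * k:
        offsets = (0, k)
        for off in offsets:
            for pos in index.lookup(query[off : off + k]):
                start = pos - off
                if 0 <= start <= G - L:
                    starts.add(start)
    else:  # too short for two disjoint seeds: exhaustive scan
        starts.update(range(0, G - L + 1))
    return starts


def enumerate_alignments(
    sequence: str, index: ReferenceIndex, max_mismatches: int = 1
) -> list[tuple[str, int, int]]:
    """All placements of a read with <= ``max_mismatches``, both strands.

    Returns sorted ``(strand, start, mismatches)`` tuples; the full candidate
    set, before best-stratum selection.  The pigeonhole guarantee (see module
    docstring) holds for ``max_mismatches <= 1``.
    """
    if max_mismatches > 1:
        raise ValueError("only 0 or 1 mismatches are supported")
    sequence = sequence.upper()
    out: list[tuple[str, int, int]] = []
    for strand, query in (("+", sequence), ("-", revcomp(sequence))):
        for start in _seed_candidates(query, index):
            mm = count_mismatches(
                query, index.sequence[start : start + len(query)], limit=max_mismatches
            )
            if mm <= max_mismatches:
                out.append((strand, start, mm))
    return sorted(out)


def align_read(
    read: TrimmedRead | str,
    index: ReferenceIndex,
    rng: np.random.Generator,
    max_mismatches: int = 1,
    read_id: str | None = None,
) -> AlignmentRecord | None:
    """Best-stratum, single-placement alignment of one read.

    Placements with the fewest mismatches form the reported stratum; ties
    within it are broken uniformly at random under ``rng``.  Returns ``None``
    when the read has no placement with <= ``max_mismatches``.
    """
    if isinstance(read, str):
        sequence, rid = read, read_id or ""
    else:
        sequence, rid = read.sequence, read_id or read.id
    candidates = enumerate_alignments(sequence, index, max_mismatches)
    if not candidates:
        return None
    best = min(mm for _, _, mm in candidates)
    stratum = [c for c in candidates if c[2] == best]
    strand, start, mm = stratum[int(rng.integers(len(stratum)))]
    forward = sequence.upper() if strand == "+" else revcomp(sequence.upper())
    return AlignmentRecord(
        read_id=rid,
        reference=index.name,
        strand=strand,
        start=start,
        read_length=len(sequence),
        mismatches=mm,
        sequence=forward,
    )


def align_library(
    reads: Sequence[TrimmedRead],
    indexes: Mapping[str, ReferenceIndex] | Sequence[ReferenceIndex],
    library_total: int,
    seed: int = 0,
    max_mismatches: int = 1,
) -> dict[str, LibraryAlignment]:
    """Align every kept read to every reference independently.

    A read may be counted on more than one reference (per-genome mapping, as
    when each virus is mapped separately), but contributes at most one
    placement per reference.  ``library_total`` is carried through as the
    RPM denominator and must be positive.
    """
    if library_total <= 0:
        raise ValueError("library_total must be > 0 (RPM undefined otherwise)")
    if not isinstance(indexes, Mapping):
        indexes = {ix.name: ix for ix in indexes}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(indexes))
    out: dict[str, LibraryAlignment] = {}
    for child, (name, index) in zip(children, indexes.items()):
        rng = np.random.default_rng(child)
        records = []
        for read in reads:
            rec = align_read(read, index, rng, max_mismatches)
            if rec is not None:
                records.append(rec)
        out[name] = LibraryAlignment(
            reference=name,
            reference_length=len(index),
            records=records,
            library_total=library_total,
            n_unmapped=len(reads) - len(records),
        )
    return out


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------


def write_sam(alignment: LibraryAlignment, path: str | Path) -> None:
    """Write one reference's alignments as uncompressed SAM.

    POS is 1-based (pysam handles the conversion from 0-based starts), FLAG
    16 marks '-' strand placements, SEQ is reference-forward, and the NM tag
    carries the mismatch count.  The library total is preserved in a @CO
    header line so the file round-trips through :func:`read_sam`.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": alignment.reference, "LN": alignment.reference_length}],
            "PG": [{"ID": "visrna", "PN": "visrna"}],
            "CO": [
                f"library_total:{alignment.library_total}",
                f"n_unmapped:{alignment.n_unmapped}",
            ],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as handle:
        for rec in alignment.records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            seg.flag = 16 if rec.strand == "-" else 0
            seg.reference_id = 0
            seg.reference_start = rec.start
            seg.mapping_quality = 255
            seg.cigartuples = [(0, rec.read_length)]
            seg.query_sequence = rec.sequence
            seg.set_tag("NM", rec.mismatches)
            handle.write(seg)


def read_sam(path: str | Path) -> LibraryAlignment:
    """Parse a SAM written by :func:`write_sam` back into records."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        sq = handle.header.to_dict()["SQ"][0]
        comments = handle.header.to_dict().get("CO", [])
        meta = dict(c.split(":", 1) for c in comments if ":" in c)
        records = []
        for seg in handle:
            if seg.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    reference=sq["SN"],
                    strand="-" if seg.is_reverse else "+",
                    start=seg.reference_start,
                    read_length=seg.query_length,
                    mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                    sequence=seg.query_sequence,
                )
            )
    return LibraryAlignment(
        reference=sq["SN"],
        reference_length=int(sq["LN"]),
        records=records,
        library_total=int(meta.get("library_total", 0)),
        n_unmapped=int(meta.get("n_unmapped", 0)),
    )
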