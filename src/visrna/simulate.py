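"""Synthetic small-RNA library simulator.

Generates viral reference genomes and small-RNA FASTQ libraries with the
statistical structure expected in a multi-virus co-infection experiment:
host background reads (21-22 nt miRNA/siRNA-like and 27-30 nt piRNA-like
classes), 21 nt virus-derived siRNAs from both strands with localized
hotspots, 26-30 nt virus-derived piRNAs with configurable 1U/10A biases and
ping-pong pairing, and strand-biased 26-30 nt degradation reads carrying no
nucleotide bias.

Every read is an exact substring (or reverse complement of a substring) of
its source sequence before sequencing errors are applied, so nucleotide
biases are realized by 5'-end *position selection* on the genome, never by
editing read sequences.  A truth table records, per (source, class), the
emitted counts and the realized 1U/10A frequencies and strand split, which
parameter-recovery tests compare against pipeline estimates.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so a recipe is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default Illumina-style 3' adapter (NEB small RNA kit prefix).
DEFAULT_ADAPTER = "AGATCGGAAGAGC"

#: Name used by read classes drawn from the host decoy sequence.
HOST = "host"

CLASS_LABELS = (
    "vsiRNA",
    "vpiRNA_primary",
    "vpiRNA_secondary",
    "degradation",
    "background",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Recipe data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """A viral reference to synthesize.

    Parameters
    ----------
    name
        Unique identifier within a recipe.
    length
        Genome length in nt (> 0).
    sense
        Polarity label of the deposited sequence, ``"positive"`` or
        ``"negative"``.  Annotation only: read strand is always expressed
        relative to the deposited orientation.
    genes
        ``(label, start, end)`` intervals, 0-based half-open.
    base_composition
        Sampling probabilities over A/C/G/T; must sum to 1.
    """

    name: str
    length: int
    sense: str = "positive"
    genes: tuple[tuple[str, int, int], ...] = ()
    base_composition: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in BASES}
    )

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome length must be positive, got {self.length}")
        if self.sense not in ("positive", "negative"):
            raise ValueError(f"sense must be positive/negative, got {self.sense!r}")
        comp = self.base_composition
        if set(comp) - set(BASES):
            raise ValueError(f"base_composition keys must be in {BASES}")
        total = sum(comp.get(b, 0.0) for b in BASES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base_composition sums to {total}, expected 1")
        if any(p < 0 for p in comp.values()):
            raise ValueError("base_composition probabilities must be non-negative")
        for label, start, end in self.genes:
            if not (0 <= start < end <= self.length):
                raise ValueError(
                    f"gene {label!r} interval [{start}, {end}) outside "
                    f"[0, {self.length})"
                )

    @property
    def composition_vector(self) -> np.ndarray:
        return np.array([self.base_composition.get(b, 0.0) for b in BASES])


@dataclass(frozen=True)
class ReadClassParams:
    """Sampling parameters for one read class.

    ``positional_weights`` weight candidate 5'-end positions on the genome
    (uniform if ``None``); hotspots are expressed as elevated weights over an
    interval.  ``p_1U`` (``vpiRNA_primary`` only) is the probability that the
    read's 5' nucleotide is U (T on the reference).  ``pingpong_fraction``
    (``vpiRNA_secondary`` only) is the fraction of reads generated as exact
    10 nt 5'-overlap partners of primary reads on the opposite strand, which
    by construction forces position 10 to be the complement of the template's
    position 1 (A whenever the template starts with U).
    """

    class_label: str
    count: int
    length_dist: Mapping[int, float]
    strand_fraction_positive: float = 1.0
    positional_weights: np.ndarray | None = None
    p_1U: float | None = None
    pingpong_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if not self.length_dist:
            raise ValueError("length_dist is empty")
        for length in self.length_dist:
            if not (19 <= int(length) <= 33):
                raise ValueError(f"read length {length} outside 19-33 nt")
        total = sum(self.length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length_dist sums to {total}, expected 1")
        if not (0.0 <= self.strand_fraction_positive <= 1.0):
            raise ValueError("strand_fraction_positive outside [0, 1]")
        if self.p_1U is not None and not (0.0 <= self.p_1U <= 1.0):
            raise ValueError("p_1U outside [0, 1]")
        if not (0.0 <= self.pingpong_fraction <= 1.0):
            raise ValueError("pingpong_fraction outside [0, 1]")

    @property
    def lengths(self) -> np.ndarray:
        return np.array(sorted(int(k) for k in self.length_dist))

    @property
    def length_probs(self) -> np.ndarray:
        return np.array([self.length_dist[k] for k in sorted(self.length_dist)])


@dataclass(frozen=True)
class LibraryRecipe:
    """Full description of one simulated library."""

    genomes: tuple[GenomeSpec, ...]
    classes: tuple[tuple[str, ReadClassParams], ...]
    sequencing_error_rate: float = 0.0
    adapter: str = DEFAULT_ADAPTER
    constant_quality: int = 37
    seed: int = 0
    host_length: int = 20000

    def __post_init__(self) -> None:
        names = [g.name for g in self.genomes]
        if len(set(names)) != len(names):
            raise ValueError("genome names must be unique within a recipe")
        if not (0.0 <= self.sequencing_error_rate <= 1.0):
            raise ValueError("sequencing_error_rate outside [0, 1]")
        for source, _ in self.classes:
            if source != HOST and source not in names:
                raise ValueError(f"class references undeclared genome {source!r}")

    def genome_spec(self, name: str) -> GenomeSpec:
        for g in self.genomes:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass(frozen=True)
class SimRead:
    """One simulated read (insert only; adapter is added at FASTQ emission).

    ``sequence`` is in read space (5'->3' as sequenced); for ``strand == '-'``
    it is the reverse complement of the genomic window
    ``[start, start + len)``.  ``n_errors`` counts substituted bases.
    """

    sequence: str
    source: str
    class_label: str
    strand: str
    start: int
    n_errors: int = 0

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the biological 5' end."""
        if self.strand == "+":
            return self.start
        return self.start + len(self.sequence) - 1


# ---------------------------------------------------------------------------
# Length-distribution helpers
# ---------------------------------------------------------------------------


def delta_length(length: int) -> dict[int, float]:
    """Point mass on a single read length (e.g. 21 nt vsiRNAs)."""
    return {int(length): 1.0}


def uniform_length(lo: int, hi: int) -> dict[int, float]:
    """Uniform distribution over ``lo..hi`` inclusive (e.g. 26-30 nt vpiRNAs)."""
    n = hi - lo + 1
    return {length: 1.0 / n for length in range(lo, hi + 1)}


#: Host background: a 21-22 nt siRNA/miRNA-like component plus a 27-30 nt
#: piRNA-like component, mimicking whole-body small-RNA size profiles.
BACKGROUND_LENGTH_DIST: dict[int, float] = {
    21: 0.30,
    22: 0.25,
    27: 0.10,
    28: 0.15,
    29: 0.12,
    30: 0.08,
}


def interval_weights(
    length: int, intervals: Iterable[tuple[int, int, float]]
) -> np.ndarray:
    """Per-position weights: 1 everywhere, ``weight`` over each interval."""
    w = np.ones(length)
    for start, end, weight in intervals:
        if not (0 <= start < end <= length):
            raise ValueError(f"interval [{start}, {end}) outside [0, {length})")
        w[start:end] = weight
    return w


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------


def generate_genome(spec: GenomeSpec, seed: int | np.random.Generator) -> str:
    """Draw a random reference sequence from the spec's base composition."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(4, size=spec.length, p=spec.composition_vector)
    return "".join(BASES[i] for i in draws)


def _position_sampler(
    genome: str, weights: np.ndarray | None, strand: str, length: int, bias: str
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate 5'-end positions and normalized sampling probabilities.

    ``bias`` is ``""`` (no constraint), ``"T"`` (the strand-aware 5' base must
    be T, i.e. a 1U read) or ``"V"`` (must not be T).  Falls back to the
    unconstrained set when the constrained one is empty.
    """
    G = len(genome)
    if length > G:
        raise ValueError(f"read length {length} exceeds genome length {G}")
    if strand == "+":
        lo, hi = 0, G - length + 1
    else:
        lo, hi = length - 1, G
    idx = np.arange(lo, hi)
    w = (np.ones(G) if weights is None else np.asarray(weights, dtype=float))[idx]
    if bias:
        # 5' base on + strand is genome[i]; on - strand it is the complement
        # of genome[i], which is T exactly when genome[i] is A.
        target = "T" if strand == "+" else "A"
        arr = np.frombuffer(genome.encode(), dtype="S1")[idx]
        is_t = arr == target.encode()
        mask = is_t if bias == "T" else ~is_t
        if w[mask].sum() > 0:
            idx, w = idx[mask], w[mask]
    total = w.sum()
    if total <= 0:
        raise ValueError("positional weights sum to zero over valid positions")
    return idx, w / total


def _extract(genome: str, strand: str, five_prime: int, length: int) -> tuple[str, int]:
    """Read-space sequence and leftmost reference start for a placement."""
    if strand == "+":
        start = five_prime
        return genome[start : start + length], start
    start = five_prime - length + 1
    return revcomp(genome[start : start + length]), start


def simulate_class(
    genome: str,
    params: ReadClassParams,
    seed: int | np.random.Generator,
    primaries: Sequence[SimRead] | None = None,
    source: str = "",
) -> list[SimRead]:
    """Sample one read class from a reference sequence.

    For ``vpiRNA_secondary`` with ``pingpong_fraction > 0``, ``primaries``
    supplies the template reads whose 5' ends anchor the 10 nt overlaps.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.count
    if n == 0:
        return []
    if len(genome) < int(params.lengths.min()):
        raise ValueError("genome shorter than the minimum read length")

    n_pp = 0
    if params.class_label == "vpiRNA_secondary" and params.pingpong_fraction > 0:
        if not primaries:
            raise ValueError(
                "pingpong_fraction > 0 requires primary reads to pair against"
            )
        n_pp = int(round(params.pingpong_fraction * n))
    n_ind = n - n_pp

    reads: list[SimRead | None] = [None] * n

    # Independent reads: draw lengths/strands/bias states, then sample 5' ends
    # per (length, strand, bias) group so weight vectors are built once.
    lengths = rng.choice(params.lengths, size=n_ind, p=params.length_probs)
    strands = np.where(
        rng.random(n_ind) < params.strand_fraction_positive, "+", "-"
    )
    if params.p_1U is not None:
        bias = np.where(rng.random(n_ind) < params.p_1U, "T", "V")
    else:
        bias = np.full(n_ind, "")
    groups: dict[tuple[int, str, str], list[int]] = {}
    for i in range(n_ind):
        groups.setdefault((int(lengths[i]), str(strands[i]), str(bias[i])), []).append(i)
    for key in sorted(groups):
        length, strand, b = key
        members = groups[key]
        idx, probs = _position_sampler(genome, params.positional_weights, strand, length, b)
        fives = rng.choice(idx, size=len(members), p=probs)
        for i, fp in zip(members, fives):
            seq, start = _extract(genome, strand, int(fp), length)
            reads[i] = SimRead(seq, source, params.class_label, strand, start)

    # Ping-pong partners: opposite strand, 5' ends overlapping by exactly 10 nt.
    for j in range(n_pp):
        placed = False
        for _ in range(50):
            template = primaries[int(rng.integers(len(primaries)))]
            length = int(rng.choice(params.lengths, p=params.length_probs))
            if template.strand == "+":
                strand, fp = "-", template.five_prime + 9
                ok = fp - length + 1 >= 0 and fp < len(genome)
            else:
                strand, fp = "+", template.five_prime - 9
                ok = fp >= 0 and fp + length <= len(genome)
            if ok:
                seq, start = _extract(genome, strand, fp, length)
                reads[n_ind + j] = SimRead(seq, source, params.class_label, strand, start)
                placed = True
                break
        if not placed:  # pathological genome/template geometry; sample freely
            length = int(rng.choice(params.lengths, p=params.length_probs))
            strand = "-" if rng.random() >= params.strand_fraction_positive else "+"
            idx, probs = _position_sampler(
                genome, params.positional_weights, strand, length, ""
            )
            fp = int(rng.choice(idx, p=probs))
            seq, start = _extract(genome, strand, fp, length)
            reads[n_ind + j] = SimRead(seq, source, params.class_label, strand, start)

    return [r for r in reads if r is not None]


def _apply_errors(
    reads: list[SimRead], rate: float, rng: np.random.Generator
) -> list[SimRead]:
    """Uniform per-base substitutions; no indels."""
    if rate <= 0:
        return reads
    out = []
    for read in reads:
        length = len(read.sequence)
        k = int(rng.binomial(length, rate))
        if k == 0:
            out.append(read)
            continue
        positions = rng.choice(length, size=k, replace=False)
        seq = list(read.sequence)
        for pos in positions:
            alternatives = [b for b in BASES if b != seq[pos]]
            seq[pos] = alternatives[int(rng.integers(3))]
        out.append(dataclasses.replace(read, sequence="".join(seq), n_errors=k))
    return out


# ---------------------------------------------------------------------------
# Library-level simulation and emission
# ---------------------------------------------------------------------------


@dataclass
class SimulatedLibrary:
    """All artifacts of one recipe run: sequences, reads and the truth table."""

    recipe: LibraryRecipe
    genomes: dict[str, str]
    host_sequence: str
    reads: list[SimRead]
    truth: pd.DataFrame


def truth_table(reads: Sequence[SimRead], recipe: LibraryRecipe | None = None) -> pd.DataFrame:
    """Realized per-(source, class) statistics of a simulated read set.

    Columns: emitted count, realized 1U frequency (5' base is T in read
    space), realized 10A frequency (read-space position 10 is A) and the
    realized positive-strand fraction.
    """
    rows = []
    keys = sorted({(r.source, r.class_label) for r in reads})
    for source, label in keys:
        members = [r for r in reads if r.source == source and r.class_label == label]
        n = len(members)
        long_enough = [r for r in members if len(r.sequence) >= 10]
        rows.append(
            {
                "source": source,
                "class_label": label,
                "n_reads": n,
                "frac_1U": sum(r.sequence[0] == "T" for r in members) / n,
                "frac_10A": (
                    sum(r.sequence[9] == "A" for r in long_enough) / len(long_enough)
                    if long_enough
                    else float("nan")
                ),
                "frac_plus_strand": sum(r.strand == "+" for r in members) / n,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["source", "class_label", "n_reads", "frac_1U", "frac_10A", "frac_plus_strand"],
    )
    return df


def simulate_library(recipe: LibraryRecipe) -> SimulatedLibrary:
    """Run a full recipe: genomes, host decoy, all read classes, errors.

    Classes are simulated in recipe order; a ``vpiRNA_secondary`` class pairs
    against all ``vpiRNA_primary`` reads already simulated for the same
    genome, so primaries must be listed first.
    """
    ss = np.random.SeedSequence(recipe.seed)
    children = ss.spawn(len(recipe.genomes) + 1 + len(recipe.classes) + 1)
    it = iter(children)

    genomes = {
        g.name: generate_genome(g, np.random.default_rng(next(it)))
        for g in recipe.genomes
    }
    host_spec = GenomeSpec(name=HOST, length=recipe.host_length)
    host_sequence = generate_genome(host_spec, np.random.default_rng(next(it)))

    reads: list[SimRead] = []
    primaries: dict[str, list[SimRead]] = {}
    for source, params in recipe.classes:
        rng = np.random.default_rng(next(it))
        sequence = host_sequence if source == HOST else genomes[source]
        new = simulate_class(
            sequence,
            params,
            rng,
            primaries=primaries.get(source),
            source=source,
        )
        if params.class_label == "vpiRNA_primary":
            primaries.setdefault(source, []).extend(new)
        reads.extend(new)

    reads = _apply_errors(reads, recipe.sequencing_error_rate, np.random.default_rng(next(it)))
    return SimulatedLibrary(
        recipe=recipe,
        genomes=genomes,
        host_sequence=host_sequence,
        reads=reads,
        truth=truth_table(reads),
    )


def emit_fastq(
    reads: Sequence[SimRead],
    recipe: LibraryRecipe,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write simulated reads as FASTQ (Phred+33) and return the truth table.

    Each record is insert + 3' adapter with a constant quality string; read
    order is shuffled deterministically by the recipe seed.  Read ids encode
    the simulation provenance
    (``sim_<i>:<source>:<class>:<strand>:<start>:<insert_len>:<n_err>``)
    so downstream parameter-recovery tests can stratify by truth without a
    join.  The truth table is written as TSV when ``truth_path`` is given.
    """
    rng = np.random.default_rng(np.random.SeedSequence([recipe.seed, 0x5E]))
    order = rng.permutation(len(reads)) if reads else np.array([], dtype=int)
    records = []
    for rank, i in enumerate(order):
        read = reads[int(i)]
        full = read.sequence + recipe.adapter
        rec = SeqRecord(
            Seq(full),
            id=(
                f"sim_{rank:07d}:{read.source}:{read.class_label}:"
                f"{read.strand}:{read.start}:{len(read.sequence)}:{read.n_errors}"
            ),
            description="",
        )
        rec.letter_annotations["phred_quality"] = [recipe.constant_quality] * len(full)
        records.append(rec)
    with open(fastq_path, "w") as handle:
        SeqIO.write(records, handle, "fastq")
    truth = truth_table(reads, recipe)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return truth


def write_genomes_fasta(library: SimulatedLibrary, path: str | Path) -> None:
    """Write the recipe's viral references as a multi-record FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description=f"synthetic {name}")
        for name, seq in library.genomes.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def write_genes_bed(recipe: LibraryRecipe, path: str | Path) -> None:
    """Write gene/UTR annotations as BED (0-based, half-open)."""
    with open(path, "w") as handle:
        for spec in recipe.genomes:
            for label, start, end in spec.genes:
                handle.write(f"{spec.name}\t{start}\t{end}\t{label}\n")


# ---------------------------------------------------------------------------
# YAML recipes
# ---------------------------------------------------------------------------


def _parse_length_dist(value) -> dict[int, float]:
    if isinstance(value, str):
        kind, _, rest = value.partition(":")
        if kind == "delta":
            return delta_length(int(rest))
        if kind == "uniform":
            lo, hi = rest.split("-")
            return uniform_length(int(lo), int(hi))
        if kind == "background":
            return dict(BACKGROUND_LENGTH_DIST)
        raise ValueError(f"unknown length_dist shorthand {value!r}")
    return {int(k): float(v) for k, v in value.items()}


def _parse_class(entry: Mapping, genome_lengths: Mapping[str, int], host_length: int):
    source = entry["source"]
    weights = None
    if "positional_weights" in entry and entry["positional_weights"]:
        length = host_length if source == HOST else genome_lengths[source]
        intervals = [
            (int(a), int(b), float(w))
            for a, b, w in entry["positional_weights"]["intervals"]
        ]
        weights = interval_weights(length, intervals)
    params = ReadClassParams(
        class_label=entry["class_label"],
        count=int(entry["count"]),
        length_dist=_parse_length_dist(entry["length_dist"]),
        strand_fraction_positive=float(entry.get("strand_fraction_positive", 1.0)),
        positional_weights=weights,
        p_1U=(float(entry["p_1U"]) if entry.get("p_1U") is not None else None),
        pingpong_fraction=float(entry.get("pingpong_fraction", 0.0)),
    )
    return source, params


def recipe_from_dict(data: Mapping) -> LibraryRecipe:
    """Build a :class:`LibraryRecipe` from a parsed YAML mapping."""
    genomes = tuple(
        GenomeSpec(
            name=g["name"],
            length=int(g["length"]),
            sense=g.get("sense", "positive"),
            genes=tuple(
                (label, int(start), int(end)) for label, start, end in g.get("genes", [])
            ),
            base_composition=(
                {k: float(v) for k, v in g["base_composition"].items()}
                if "base_composition" in g
                else {b: 0.25 for b in BASES}
            ),
        )
        for g in data["genomes"]
    )
    lengths = {g.name: g.length for g in genomes}
    host_length = int(data.get("host", {}).get("length", 20000))
    classes = tuple(
        _parse_class(entry, lengths, host_length) for entry in data["classes"]
    )
    return LibraryRecipe(
        genomes=genomes,
        classes=classes,
        sequencing_error_rate=float(data.get("sequencing_error_rate", 0.0)),
        adapter=data.get("adapter", DEFAULT_ADAPTER),
        constant_quality=int(data.get("constant_quality", 37)),
        seed=int(data.get("seed", 0)),
        host_length=host_length,
    )


def load_recipe(path: str | Path) -> LibraryRecipe:
    """Load a library recipe from a YAML file (schema in docs/methods.md)."""
    with open(path) as handle:
        return recipe_from_dict(yaml.safe_load(handle))


# ---------------------------------------------------------------------------
# Reference three-virus co-infection recipe
# ---------------------------------------------------------------------------


def coinfection_recipe(
    seed: int = 0,
    depth: float = 1.0,
    sequencing_error_rate: float = 0.0,
) -> LibraryRecipe:
    """Three-virus co-infection library emulating the study system.

    One positive-sense flavivirus-like genome (AEFV-like, 11064 nt) with a
    3' UTR vsiRNA hotspot and unbiased positive-strand 26-30 nt degradation
    reads; one negative-sense rhabdovirus-like genome (MERV-like, 11200 nt)
    with a negative-strand 5'-terminal vsiRNA hotspot and true vpiRNAs
    (1U-biased primaries from the positive strand over the structural-gene
    region, ping-pong secondaries from the negative strand) planted at 60
    26-30 nt reads per 100 21 nt reads; one positive-sense virus (SHTV-like,
    5500 nt) with uniform vsiRNAs and almost no 26-30 nt production; plus
    host background.  ``depth`` scales all class counts.
    """

    def n(count: int) -> int:
        return max(1, int(round(count * depth)))

    aefv = GenomeSpec(
        name="AEFV",
        length=11064,
        sense="positive",
        genes=(("5UTR", 0, 95), ("polyprotein", 95, 10379), ("3UTR", 10379, 11064)),
        base_composition={"A": 0.28, "C": 0.21, "G": 0.27, "T": 0.24},
    )
    merv = GenomeSpec(
        name="MERV",
        length=11200,
        sense="negative",
        genes=(
            ("leader", 0, 130),
            ("N", 130, 1450),
            ("P", 1450, 2350),
            ("M", 2350, 3150),
            ("G", 3150, 4162),
            ("L", 4250, 11050),
            ("trailer", 11050, 11200),
        ),
        base_composition={"A": 0.30, "C": 0.20, "G": 0.23, "T": 0.27},
    )
    shtv = GenomeSpec(
        name="SHTV",
        length=5500,
        sense="positive",
        genes=(("5UTR", 0, 60), ("CDS", 60, 5300), ("3UTR", 5300, 5500)),
        base_composition={"A": 0.27, "C": 0.24, "G": 0.24, "T": 0.25},
    )

    classes: list[tuple[str, ReadClassParams]] = [
        (
            HOST,
            ReadClassParams(
                class_label="background",
                count=n(30000),
                length_dist=dict(BACKGROUND_LENGTH_DIST),
                strand_fraction_positive=0.5,
            ),
        ),
        # AEFV: genome-wide 21 nt vsiRNAs, dense over the 3' UTR; 26-30 nt
        # reads are mostly positive-strand degradation with no 1U/10A bias.
        (
            "AEFV",
            ReadClassParams(
                class_label="vsiRNA",
                count=n(4000),
                length_dist=delta_length(21),
                strand_fraction_positive=0.55,
                positional_weights=interval_weights(
                    aefv.length, [(10379, 11064, 10.0)]
                ),
            ),
        ),
        (
            "AEFV",
            ReadClassParams(
                class_label="degradation",
                count=n(600),
                length_dist=uniform_length(26, 30),
                strand_fraction_positive=0.9,
            ),
        ),
        # MERV: vsiRNAs across the genome plus a negative-strand hotspot over
        # the genomic 5'-terminal leader region; canonical vpiRNAs at a
        # planted ratio of 60 per 100 vsiRNAs.
        (
            "MERV",
            ReadClassParams(
                class_label="vsiRNA",
                count=n(4000),
                length_dist=delta_length(21),
                strand_fraction_positive=0.5,
            ),
        ),
        (
            "MERV",
            ReadClassParams(
                class_label="vsiRNA",
                count=n(1000),
                length_dist=delta_length(21),
                strand_fraction_positive=0.0,
                positional_weights=interval_weights(merv.length, [(0, 130, 10.0)]),
            ),
        ),
        (
            "MERV",
            ReadClassParams(
                class_label="vpiRNA_primary",
                count=n(1800),
                length_dist=uniform_length(26, 30),
                strand_fraction_positive=1.0,
                positional_weights=interval_weights(merv.length, [(130, 4162, 10.0)]),
                p_1U=0.9,
            ),
        ),
        (
            "MERV",
            ReadClassParams(
                class_label="vpiRNA_secondary",
                count=n(1200),
                length_dist=uniform_length(26, 30),
                strand_fraction_positive=0.0,
                pingpong_fraction=0.5,
            ),
        ),
        # SHTV: vsiRNAs only, no hotspot, trace 26-30 nt degradation.
        (
            "SHTV",
            ReadClassParams(
                class_label="vsiRNA",
                count=n(2000),
                length_dist=delta_length(21),
                strand_fraction_positive=0.5,
            ),
        ),
        (
            "SHTV",
            ReadClassParams(
                class_label="degradation",
                count=n(40),
                length_dist=uniform_length(26, 30),
                strand_fraction_positive=0.85,
            ),
        ),
    ]

    return LibraryRecipe(
        genomes=(aefv, merv, shtv),
        classes=tuple(classes),
        sequencing_error_rate=sequencing_error_rate,
        seed=seed,
    )
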