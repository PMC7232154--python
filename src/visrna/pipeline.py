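"""End-to-end orchestration: trim -> align -> profile -> signature, with a
consolidated per-library report and cross-library comparison.

A run is described by a :class:`RunConfig` (YAML on disk), is deterministic
given its seed, and writes every intermediate table as TSV before any
downstream stage consumes it, so every number in the report can be
recomputed from the files in the run directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .align import ReferenceIndex, align_library, build_index, write_sam
from .preprocess import process_fastq
from .profiles import (
    PIRNA_WINDOW,
    SIRNA_LENGTH,
    class_counts,
    coverage_profile,
    hotspot_flags,
    hotspots_to_frame,
    rpm_normalize,
    size_distribution,
    vpirna_vsirna_ratio,
)
from .signature import (
    bias_results_frame,
    bias_test,
    nucleotide_frequency_matrix,
    pingpong_overlap,
    strand_composition,
)
from .simulate import DEFAULT_ADAPTER

logger = logging.getLogger("visrna")

BED_COLUMNS = ["chrom", "start", "end", "name"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    ``libraries`` maps a tissue/sex label to a FASTQ path.  All module
    parameters are carried here so the run directory's config echo fully
    determines the outputs.
    """

    libraries: tuple[tuple[str, str], ...]  # (label, fastq path)
    reference_fasta: str
    outdir: str
    annotation_bed: str | None = None
    adapter: str = DEFAULT_ADAPTER
    quality_cutoff: int = 20
    min_len: int = 19
    max_len: int = 33
    sirna_length: int = SIRNA_LENGTH
    pirna_window: tuple[int, int] = PIRNA_WINDOW
    max_mismatches: int = 1
    seed: int = 0
    write_sam_files: bool = True
    bias_alpha: float = 0.01
    hotspot_fold: float = 5.0
    hotspot_min_count: int = 10

    def validate_paths(self) -> None:
        missing = [p for _, p in self.libraries if not Path(p).exists()]
        if not Path(self.reference_fasta).exists():
            missing.append(self.reference_fasta)
        if self.annotation_bed and not Path(self.annotation_bed).exists():
            missing.append(self.annotation_bed)
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")

    def to_dict(self) -> dict:
        return {
            "libraries": [
                {"label": label, "fastq": path} for label, path in self.libraries
            ],
            "reference_fasta": self.reference_fasta,
            "outdir": self.outdir,
            "annotation_bed": self.annotation_bed,
            "adapter": self.adapter,
            "quality_cutoff": self.quality_cutoff,
            "min_len": self.min_len,
            "max_len": self.max_len,
            "sirna_length": self.sirna_length,
            "pirna_window": list(self.pirna_window),
            "max_mismatches": self.max_mismatches,
            "seed": self.seed,
            "write_sam_files": self.write_sam_files,
            "bias_alpha": self.bias_alpha,
            "hotspot_fold": self.hotspot_fold,
            "hotspot_min_count": self.hotspot_min_count,
        }


def load_config(path: str | Path) -> RunConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    return RunConfig(
        libraries=tuple((str(e["label"]), str(e["fastq"])) for e in data["libraries"]),
        reference_fasta=str(data["reference_fasta"]),
        outdir=str(data["outdir"]),
        annotation_bed=data.get("annotation_bed"),
        adapter=data.get("adapter", DEFAULT_ADAPTER),
        quality_cutoff=int(data.get("quality_cutoff", 20)),
        min_len=int(data.get("min_len", 19)),
        max_len=int(data.get("max_len", 33)),
        sirna_length=int(data.get("sirna_length", SIRNA_LENGTH)),
        pirna_window=tuple(data.get("pirna_window", list(PIRNA_WINDOW))),
        max_mismatches=int(data.get("max_mismatches", 1)),
        seed=int(data.get("seed", 0)),
        write_sam_files=bool(data.get("write_sam_files", True)),
        bias_alpha=float(data.get("bias_alpha", 0.01)),
        hotspot_fold=float(data.get("hotspot_fold", 5.0)),
        hotspot_min_count=int(data.get("hotspot_min_count", 10)),
    )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a BED file (3+ columns, 0-based half-open) into a table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


@dataclass
class RunReport:
    """Consolidated per-(library, virus) statistics of one run."""

    table: pd.DataFrame
    config: RunConfig
    version: str = __version__

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _analyze_virus(
    label: str,
    alignment,
    genome: str,
    config: RunConfig,
    annotations: pd.DataFrame | None,
    outdir: Path,
) -> dict:
    """Profile + signature analysis of one (library, virus) pair."""
    virus = alignment.reference
    prefix = outdir / f"{label}_{virus}"
    virus_annotations = ()
    if annotations is not None:
        sub = annotations[annotations["chrom"] == virus]
        virus_annotations = tuple(
            (str(r.get("name", "")), int(r["start"]), int(r["end"]))
            for _, r in sub.iterrows()
        )

    n21, n2630 = class_counts(alignment, config.sirna_length, config.pirna_window)
    ratio = vpirna_vsirna_ratio(n2630, n21, virus=virus, tissue=label)
    rpm21 = (
        rpm_normalize(n21, alignment.library_total).value
        if alignment.library_total > 0
        else float("nan")
    )

    size_distribution(alignment.records, scope="mapped").to_csv(
        prefix.with_name(prefix.name + "_size_distribution.tsv"), sep="\t"
    )
    sirna_profile = coverage_profile(
        alignment, (config.sirna_length, config.sirna_length), annotations=virus_annotations
    )
    pirna_profile = coverage_profile(
        alignment, config.pirna_window, annotations=virus_annotations
    )
    sirna_profile.to_tsv(prefix.with_name(prefix.name + "_profile_21nt.tsv"))
    pirna_profile.to_tsv(
        prefix.with_name(
            prefix.name
            + f"_profile_{config.pirna_window[0]}-{config.pirna_window[1]}nt.tsv"
        )
    )
    hotspots = hotspot_flags(
        sirna_profile, fold=config.hotspot_fold, min_count=config.hotspot_min_count
    )
    hotspots_to_frame(hotspots, virus).to_csv(
        prefix.with_name(prefix.name + "_hotspots.tsv"), sep="\t", index=False
    )

    lo, hi = config.pirna_window
    pirna_records = [r for r in alignment.records if lo <= r.read_length <= hi]
    row = {
        "library": label,
        "virus": virus,
        "library_total": alignment.library_total,
        "mapped": alignment.n_mapped,
        "n_21": n21,
        "n_26_30": n2630,
        "rpm_21": rpm21,
        "ratio_per_100": ratio.value if not ratio.undefined else float("nan"),
        "ratio_undefined": ratio.undefined,
        "n_hotspots_21nt": len(hotspots),
    }

    bias_rows = []
    for strand in ("+", "-"):
        matrix = nucleotide_frequency_matrix(
            pirna_records, strand, max_len=hi, class_label=f"{lo}-{hi}nt"
        )
        strand_tag = "plus" if strand == "+" else "minus"
        matrix.to_tsv(prefix.with_name(prefix.name + f"_freq_matrix_{strand_tag}.tsv"))
        background = strand_composition(genome, strand)
        for position, base in ((1, "U"), (10, "A")):
            if matrix.coverage[position - 1] == 0:
                continue
            result = bias_test(
                matrix, position, base, background[base], alpha=config.bias_alpha
            )
            bias_rows.append(result)
            key = f"{'1U' if position == 1 else '10A'}_{strand_tag}"
            row[f"{key}_freq"] = result.observed_frequency
            row[f"{key}_biased"] = result.biased
    bias_results_frame(bias_rows, virus).to_csv(
        prefix.with_name(prefix.name + "_bias.tsv"), sep="\t", index=False, float_format="%.6g"
    )

    histogram = pingpong_overlap(pirna_records, alignment.reference_length)
    histogram.to_tsv(prefix.with_name(prefix.name + "_pingpong.tsv"))
    row["pingpong_argmax"] = histogram.argmax_bin
    row["pingpong_z10"] = histogram.z10 if histogram.z10 is not None else float("nan")
    return row


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis for every library in the config.

    Stages per library: trimming (QC TSV), per-virus alignment (optional
    SAM), profiles (size distribution, strand-resolved coverage, hotspots,
    vpiRNA:vsiRNA ratio) and piRNA signatures (frequency matrices, 1U/10A
    bias tests, ping-pong overlap histogram).  Empty libraries produce
    all-zero rows rather than failing.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=False)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    references = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(config.reference_fasta, "fasta")
    }
    if not references:
        raise ValueError(f"no references in {config.reference_fasta}")
    indexes = {name: build_index(name, seq) for name, seq in references.items()}
    annotations = (
        read_annotations(config.annotation_bed) if config.annotation_bed else None
    )

    seed_children = np.random.SeedSequence(config.seed).spawn(len(config.libraries))
    rows: list[dict] = []
    try:
        for child, (label, fastq) in zip(seed_children, config.libraries):
            stage = f"trim[{label}]"
            try:
                kept, qc = process_fastq(
                    fastq,
                    out_path=outdir / f"{label}_trimmed.fastq",
                    adapter=config.adapter,
                    quality_threshold=config.quality_cutoff,
                    min_len=config.min_len,
                    max_len=config.max_len,
                )
                qc.to_tsv(outdir / f"{label}_qc.tsv")
                logger.info(
                    "%s: %d reads in, %d kept", stage, qc.reads_in, qc.reads_kept
                )
                size_distribution(kept, scope="library").to_csv(
                    outdir / f"{label}_library_size_distribution.tsv", sep="\t"
                )
                if qc.reads_kept == 0:
                    logger.info("%s: empty library, reporting zeros", stage)
                    for virus in references:
                        rows.append(
                            {
                                "library": label,
                                "virus": virus,
                                "library_total": 0,
                                "mapped": 0,
                                "n_21": 0,
                                "n_26_30": 0,
                                "rpm_21": float("nan"),
                                "ratio_per_100": float("nan"),
                                "ratio_undefined": True,
                                "n_hotspots_21nt": 0,
                                "pingpong_argmax": None,
                                "pingpong_z10": float("nan"),
                            }
                        )
                    continue
                stage = f"align[{label}]"
                run_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
                alignments = align_library(
                    kept,
                    indexes,
                    library_total=qc.reads_kept,
                    seed=run_seed,
                    max_mismatches=config.max_mismatches,
                )
                for virus, alignment in alignments.items():
                    stage = f"analyze[{label}:{virus}]"
                    if config.write_sam_files:
                        write_sam(alignment, outdir / f"{label}_{virus}.sam")
                    logger.info("%s: %d mapped", stage, alignment.n_mapped)
                    rows.append(
                        _analyze_virus(
                            label,
                            alignment,
                            references[virus],
                            config,
                            annotations,
                            outdir,
                        )
                    )
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed for input {fastq!r}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    table = pd.DataFrame(rows)
    report = RunReport(table=table, config=config)
    report.write(outdir / "report.tsv")
    return report


def compare_libraries(
    reports: Sequence[RunReport] | Sequence[pd.DataFrame],
    on: str = "rpm_21",
) -> pd.DataFrame:
    """Per-virus share (%) of each library's 21 nt signal across libraries.

    Mirrors tissue-share comparisons (e.g. the fraction of all vsiRNAs
    detected in testes): for every virus, each library's value of ``on``
    (RPM by default, so depths are comparable; use ``n_21`` for raw counts)
    divided by the sum across libraries, as a percentage.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    tables = [r.table if isinstance(r, RunReport) else r for r in reports]
    merged = pd.concat(tables, ignore_index=True)
    virus_sets = [set(t["virus"]) for t in tables]
    shared = set.intersection(*virus_sets)
    if not shared:
        raise ValueError("reports share no viruses")
    merged = merged[merged["virus"].isin(shared)]
    grouped = merged.groupby("virus")[on].transform("sum")
    out = merged[["library", "virus", on]].copy()
    out["share_percent"] = 100.0 * merged[on] / grouped
    return out.reset_index(drop=True)
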