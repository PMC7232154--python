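"""Simulator: genome generation, class sampling, FASTQ emission, truth table."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from visrna.simulate import (
    BACKGROUND_LENGTH_DIST,
    GenomeSpec,
    LibraryRecipe,
    ReadClassParams,
    coinfection_recipe,
    delta_length,
    emit_fastq,
    generate_genome,
    interval_weights,
    load_recipe,
    recipe_from_dict,
    revcomp,
    simulate_class,
    simulate_library,
    truth_table,
    uniform_length,
)


class TestGenerateGenome:
    def test_degenerate_composition(self):
        spec = GenomeSpec("x", 10, base_composition={"A": 1.0})
        assert generate_genome(spec, 0) == "AAAAAAAAAA"

    def test_uniform_composition_frequencies(self):
        spec = GenomeSpec("x", 11064)
        genome = generate_genome(spec, seed=1)
        tol = 3 * math.sqrt(0.25 * 0.75 / 11064)
        for base in "ACGT":
            assert abs(genome.count(base) / 11064 - 0.25) <= tol

    def test_deterministic(self):
        spec = GenomeSpec("x", 500)
        assert generate_genome(spec, 3) == generate_genome(spec, 3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"length": 0},
            {"base_composition": {"A": 0.5, "C": 0.6}},
            {"base_composition": {"A": 1.2, "C": -0.2}},
            {"genes": (("g", 5, 3),)},
            {"genes": (("g", 0, 99999),)},
            {"sense": "antisense"},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = {"name": "x", "length": 100}
        base.update(kwargs)
        with pytest.raises(ValueError):
            GenomeSpec(**base)


class TestSimulateClass:
    def test_forced_1u(self, random_genome):
        params = ReadClassParams(
            "vpiRNA_primary", 100, uniform_length(26, 30), p_1U=1.0
        )
        reads = simulate_class(random_genome, params, 0)
        assert len(reads) == 100
        assert all(r.sequence[0] == "T" for r in reads)

    def test_pingpong_partner_forces_10a(self, random_genome):
        primaries = simulate_class(
            random_genome,
            ReadClassParams("vpiRNA_primary", 200, uniform_length(26, 30), p_1U=1.0),
            1,
        )
        secondaries = simulate_class(
            random_genome,
            ReadClassParams(
                "vpiRNA_secondary",
                100,
                uniform_length(26, 30),
                strand_fraction_positive=0.0,
                pingpong_fraction=1.0,
            ),
            2,
            primaries=primaries,
        )
        assert len(secondaries) == 100
        assert all(r.sequence[9] == "A" for r in secondaries)
        # every partner's 5' end overlaps some primary 5' end by exactly 10 nt
        primary_fives = {p.five_prime for p in primaries}
        for r in secondaries:
            assert (r.five_prime - 9 in primary_fives) or (r.five_prime + 9 in primary_fives)

    def test_realized_1u_frequency_binomial_ci(self, random_genome):
        params = ReadClassParams(
            "vpiRNA_primary", 10000, uniform_length(26, 30), p_1U=0.9
        )
        reads = simulate_class(random_genome, params, 7)
        freq = sum(r.sequence[0] == "T" for r in reads) / len(reads)
        tol = 3 * math.sqrt(0.9 * 0.1 / 10000)
        assert abs(freq - 0.9) <= tol

    def test_reads_fit_in_genome_and_match_it(self, random_genome):
        params = ReadClassParams(
            "vsiRNA", 500, delta_length(21), strand_fraction_positive=0.5
        )
        for r in simulate_class(random_genome, params, 5):
            window = random_genome[r.start : r.start + 21]
            expected = window if r.strand == "+" else revcomp(window)
            assert r.sequence == expected

    def test_genome_shorter_than_reads_rejected(self):
        params = ReadClassParams("vsiRNA", 10, delta_length(21))
        with pytest.raises(ValueError):
            simulate_class("ACGT", params, 0)

    def test_secondary_without_primaries_rejected(self, random_genome):
        params = ReadClassParams(
            "vpiRNA_secondary", 10, uniform_length(26, 30), pingpong_fraction=0.5
        )
        with pytest.raises(ValueError):
            simulate_class(random_genome, params, 0)

    def test_hotspot_weights_concentrate_reads(self, random_genome):
        weights = interval_weights(len(random_genome), [(1500, 1700, 50.0)])
        params = ReadClassParams(
            "vsiRNA", 2000, delta_length(21), positional_weights=weights
        )
        reads = simulate_class(random_genome, params, 3)
        inside = sum(1 for r in reads if 1500 <= r.five_prime < 1700)
        # weighted interval mass: 50*200 / (50*200 + 1780) ~ 0.85
        assert inside / len(reads) > 0.7


class TestLibraryAndFastq:
    def test_truth_counts_match_recipe(self):
        recipe = coinfection_recipe(seed=0, depth=0.05)
        library = simulate_library(recipe)
        requested: dict[tuple[str, str], int] = {}
        for source, params in recipe.classes:
            key = (source, params.class_label)
            requested[key] = requested.get(key, 0) + params.count
        observed = {
            (row.source, row.class_label): row.n_reads
            for row in library.truth.itertuples()
        }
        assert observed == requested

    def test_error_free_reads_are_exact_substrings(self):
        recipe = coinfection_recipe(seed=2, depth=0.02)
        library = simulate_library(recipe)
        for read in library.reads:
            source = (
                library.host_sequence
                if read.source == "host"
                else library.genomes[read.source]
            )
            window = source[read.start : read.start + len(read.sequence)]
            expected = window if read.strand == "+" else revcomp(window)
            assert read.sequence == expected

    def test_error_rate_recorded_per_read(self):
        recipe = coinfection_recipe(seed=2, depth=0.02, sequencing_error_rate=0.05)
        library = simulate_library(recipe)
        n_with_errors = sum(1 for r in library.reads if r.n_errors > 0)
        # ~ 1 - (1 - 0.05)^24 of reads carry at least one substitution
        assert 0.4 < n_with_errors / len(library.reads) < 0.9
        for read in library.reads[:500]:
            source = (
                library.host_sequence
                if read.source == "host"
                else library.genomes[read.source]
            )
            window = source[read.start : read.start + len(read.sequence)]
            expected = window if read.strand == "+" else revcomp(window)
            observed_mm = sum(1 for a, b in zip(read.sequence, expected) if a != b)
            assert observed_mm == read.n_errors

    def test_emit_empty_fastq(self, tmp_path):
        recipe = coinfection_recipe(seed=0, depth=0.01)
        truth = emit_fastq([], recipe, tmp_path / "empty.fastq", tmp_path / "t.tsv")
        assert (tmp_path / "empty.fastq").read_text() == ""
        assert truth.empty
        assert (tmp_path / "t.tsv").exists()

    def test_adapter_appended(self, tmp_path):
        recipe = coinfection_recipe(seed=0, depth=0.01)
        from visrna.simulate import SimRead

        read = SimRead("A" * 21, "host", "background", "+", 0)
        emit_fastq([read], recipe, tmp_path / "one.fastq")
        lines = (tmp_path / "one.fastq").read_text().splitlines()
        assert len(lines[1]) == 21 + len(recipe.adapter)
        assert lines[1].endswith(recipe.adapter)
        assert len(lines[3]) == len(lines[1])

    def test_emission_is_bit_reproducible(self, tmp_path):
        recipe = coinfection_recipe(seed=3, depth=0.02)
        library = simulate_library(recipe)
        emit_fastq(library.reads, recipe, tmp_path / "a.fastq")
        emit_fastq(library.reads, recipe, tmp_path / "b.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_whole_simulation_reproducible(self):
        a = simulate_library(coinfection_recipe(seed=11, depth=0.02))
        b = simulate_library(coinfection_recipe(seed=11, depth=0.02))
        assert a.genomes == b.genomes
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]


def test_degradation_composition_matches_genome():
    """Unbiased degradation reads are compositionally indistinguishable from
    the genome (chi-square at alpha=0.01), pooled over read positions."""
    spec = GenomeSpec("v", 5000)
    genome = generate_genome(spec, 42)
    params = ReadClassParams("degradation", 10000, uniform_length(26, 30))
    reads = simulate_class(genome, params, 43)
    observed = np.zeros(4)
    for read in reads:
        for base in read.sequence:
            observed["ACGT".index(base)] += 1
    genome_freq = np.array([genome.count(b) / len(genome) for b in "ACGT"])
    result = stats.chisquare(observed, observed.sum() * genome_freq)
    assert result.pvalue > 0.01
    # and specifically at the two bias-diagnostic positions
    for pos in (0, 9):
        counts = np.zeros(4)
        for read in reads:
            counts["ACGT".index(read.sequence[pos])] += 1
        assert stats.chisquare(counts, counts.sum() * genome_freq).pvalue > 0.01


def test_recipe_yaml_loading(tmp_path):
    text = """
seed: 9
sequencing_error_rate: 0.0
adapter: AGATCGGAAGAGC
host: {length: 4000}
genomes:
  - name: VIR
    length: 3000
    sense: negative
    genes: [[N, 0, 1000], [L, 1000, 3000]]
    base_composition: {A: 0.3, C: 0.2, G: 0.2, T: 0.3}
classes:
  - source: host
    class_label: background
    count: 100
    length_dist: background
  - source: VIR
    class_label: vsiRNA
    count: 50
    length_dist: delta:21
    strand_fraction_positive: 0.5
  - source: VIR
    class_label: vpiRNA_primary
    count: 30
    length_dist: uniform:26-30
    p_1U: 0.9
    positional_weights: {intervals: [[0, 1000, 10.0]]}
"""
    path = tmp_path / "recipe.yaml"
    path.write_text(text)
    recipe = load_recipe(path)
    assert recipe.seed == 9
    assert recipe.genomes[0].sense == "negative"
    assert recipe.classes[1][1].length_dist == delta_length(21)
    assert recipe.classes[2][1].p_1U == 0.9
    library = simulate_library(recipe)
    assert len(library.reads) == 180


def test_class_param_validation():
    with pytest.raises(ValueError):
        ReadClassParams("mystery", 1, delta_length(21))
    with pytest.raises(ValueError):
        ReadClassParams("vsiRNA", -1, delta_length(21))
    with pytest.raises(ValueError):
        ReadClassParams("vsiRNA", 1, {21: 0.5})
    with pytest.raises(ValueError):
        ReadClassParams("vsiRNA", 1, {40: 1.0})
    with pytest.raises(ValueError):
        LibraryRecipe(
            genomes=(GenomeSpec("a", 100),),
            classes=(("missing", ReadClassParams("vsiRNA", 1, delta_length(21))),),
        )
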