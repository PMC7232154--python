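# Methods

`visrna` profiles virus-derived small RNAs in deep-sequenced 19–33 nt
libraries from virus-infected insects. The scientific question it serves is
whether a given virus elicits only the siRNA response (21 nt virus-derived
siRNAs, vsiRNAs, made by Dicer-2 from viral dsRNA) or also the piRNA
response (25–30 nt virus-derived piRNAs, vpiRNAs, made by PIWI-family
proteins), and whether the longer read population is genuine piRNA output or
merely viral RNA degradation. The diagnostic criteria are the canonical
piRNA sequence signatures: a uridine bias at read position 1 (1U) on the
strand feeding primary biogenesis, an adenine bias at position 10 (10A) on
the opposite strand, and an excess of sense/antisense read pairs whose 5'
ends overlap by exactly 10 nt (the ping-pong signature).

## Pipeline model

1. **Trimming** (`visrna.preprocess`). 3' adapters are removed by scanning
   read positions left to right and cutting at the leftmost suffix that
   matches an adapter prefix with overlap ≥ `min_overlap` (default 3) and a
   mismatch fraction ≤ `max_error_rate` (default 0.1). Low-quality 3' tails
   are then clipped by the BWA-style running-sum rule at Phred threshold 20:
   the cut maximizes Σ(threshold − q) over the removed suffix, ties resolved
   toward minimal trimming. Finally reads outside the gel window
   [19, 33] nt are discarded with a recorded reason. The number of reads
   kept is the library total used as the RPM denominator (a documented
   choice; pre-trim totals differ only by a scale factor within a library).
   Trimming is single-pass. It is therefore not strictly idempotent for the
   ~(1/4)^k fraction of inserts whose 3' end coincides with a k ≥ 3 nt
   adapter prefix: such an insert is indistinguishable from a partial
   adapter read-through on re-application. Single-pass semantics are kept
   because they guarantee exact insert recovery for error-free reads.
2. **Alignment** (`visrna.align`). Reads are mapped end-to-end to each viral
   genome independently, on both strands, allowing at most one mismatch
   ('N' always counts as a mismatch). Candidates come from pigeonhole
   seeding: the index stores every 9-mer of the reference (9 =
   ⌊19/2⌋), and a read is looked up at offsets 0 and 9; with two disjoint
   seed windows and ≤ 1 mismatch, one window is necessarily mismatch-free,
   so the candidate set provably contains every valid placement. Reporting
   is best-stratum (0 mismatches beat 1) with exactly one placement per
   (read, reference), ties broken uniformly under the run seed. A read may
   count on several viruses (each genome is mapped separately), but at most
   once per genome. Alignments can be written as SAM (FLAG 16 for the minus
   strand, reference-forward SEQ, NM tag).
3. **Profiles** (`visrna.profiles`). Size distributions, RPM normalization
   (10⁶ × count / library total), and strand-resolved per-position
   profiles. Profiles count 5' ends — the leftmost reference position for
   plus-strand reads, the rightmost for minus-strand reads — one count per
   read, so a profile sums exactly to its class read count; a per-base
   footprint mode exists for plotting. The vpiRNA:vsiRNA proportion is the
   number of virus-derived 26–30 nt reads per 100 virus-derived 21 nt
   reads, flagged undefined (never reported as 0) when no 21 nt reads
   mapped. The 26–30 nt window is the default vpiRNA candidate class; a
   26–32 nt window can be configured. Hotspots are flagged as maximal runs
   of positions whose count reaches max(`min_count` = 10, `fold` = 5 × the
   strand's nonzero median), merged across gaps ≤ 5 nt; these thresholds
   are screening heuristics, labelled as such, not a calibrated test.
4. **Signatures** (`visrna.signature`). Positional nucleotide-frequency
   matrices are built over read-space sequences anchored at the 5' end (for
   minus-strand placements the reverse complement of the reference window),
   with per-position coverage, T reported as U. The 1U and 10A biases are
   assessed by a two-sided exact binomial test of the observed base count
   against a background frequency equal to the base composition of the
   corresponding genome strand — not 0.25, because viral genomes are
   compositionally skewed and an A-rich genome would otherwise fake a 10A
   bias. A position is called biased when p < α (default 0.01) **and** the
   observed frequency exceeds the background; significant depletions are
   not biases. The canonical assignment tested by the pipeline is 1U on the
   plus strand and 10A on the minus strand, but both strands are computed
   and reported. The ping-pong statistic bins opposite-strand read pairs by
   their 5'–5' overlap (1–20 nt). The default weighting counts each
   distinct (5'+ position, 5'− position) pair once, weighted by the smaller
   positional multiplicity, which damps the quadratic blow-up of deep
   ping-pong towers; an all-pairs mode implements the raw quadratic
   definition and is what the brute-force oracle checks. z10 standardizes
   the 10 nt bin against the empirical mean and SD of bins 1–9 and 11–20;
   no parametric null is claimed, and z10 is undefined when fewer than two
   of those bins are nonzero.
5. **Orchestration** (`visrna.pipeline`, `visrna.cli`). A YAML config drives
   trim → align → profile → signature per library; every statistic in the
   consolidated report is recomputable from the intermediate TSVs written
   alongside it, runs are byte-reproducible given their seeds, and the full
   config (seeds included) is echoed into the run directory. Cross-library
   comparison reports each library's percentage share of the per-virus
   21 nt signal, on RPM by default so libraries of different depths are
   comparable (raw-count mode available).

## Synthetic libraries

`visrna.simulate` generates the inputs the analysis assumes, from a YAML
recipe: reference genomes drawn from a specified base composition with gene
annotations, plus read classes
(`background`, `vsiRNA`, `degradation`, `vpiRNA_primary`,
`vpiRNA_secondary`) with per-class counts, length distributions, strand
fractions and positional weights. Key mechanisms:

- **Biases are position selection, not sequence editing.** A 1U read is
  produced by sampling its 5' end among strand-appropriate T positions with
  probability `p_1U` (and among non-T positions otherwise), so every
  error-free read remains an exact (reverse-complemented) substring of its
  genome and the realized 1U frequency converges to `p_1U`.
- **Ping-pong pairs are geometric.** A fraction `pingpong_fraction` of
  secondary reads is placed on the strand opposite a randomly chosen
  primary read with 5' ends overlapping by exactly 10 nt, which forces
  position 10 of the partner to complement position 1 of its template —
  10A whenever the template starts with U. Remaining secondaries are
  sampled independently.
- **Hotspots** are positional weights (e.g. 10× over an annotated UTR), not
  a separate mechanism. Minus-strand reads are emitted as reverse
  complements of the genomic window; "strand" always refers to the
  deposited reference orientation.
- **Host background** comes from an independent decoy sequence (default
  20 kb, uniform composition) so background reads map to a virus only by
  chance; such collisions are rare and quantified in tests.
- **Errors** are uniform per-base substitutions (no indels — the aligner is
  substitution-only by design); per-read substitution counts are recorded.
- A **truth table** records, per (source, class), emitted counts and the
  realized 1U/10A frequencies and strand split; FASTQ read ids carry the
  per-read provenance. Emission appends the 3' adapter, uses a constant
  quality (default Phred 37), and shuffles read order deterministically.

The bundled `coinfection_recipe()` encodes a three-virus co-infection
library: an 11,064 nt positive-sense flavivirus-like genome with a 3'
UTR-weighted vsiRNA hotspot and positive-strand-biased unbiased 26–30 nt
degradation reads (planted at 15 per 100 vsiRNAs); an 11,200 nt
negative-sense rhabdovirus-like genome with a minus-strand 5'-terminal
vsiRNA hotspot and true vpiRNAs — 1U = 0.9 primaries from the plus strand
over the structural-gene region (positions 130–4162), ping-pong secondaries
(fraction 0.5) from the minus strand — planted at 60 vpiRNA-window reads
per 100 vsiRNAs; a 5,500 nt positive-sense genome with uniform vsiRNAs and
trace degradation (2 per 100); and 30,000 host background reads mixing
21–22 nt and 27–30 nt classes. Counts scale with a `depth` factor; tests
and the acceptance script run at depths 0.1–0.5 (≈4,500–23,000 reads),
sizes at which every planted parameter is recovered within 3 binomial
standard errors. The genome lengths of the rhabdovirus- and
tetravirus-like references are realistic round values; viral base
compositions are mildly skewed plausible values.

What the simulator does **not** emulate — and hence what green tests do not
establish about real libraries: ligation and PCR biases, UMI structure,
realistic quality-score error profiles (qualities are constant), indels,
host-genome mapping ambiguity, piRNA cluster context, and the deep,
heavy-tailed positional multiplicity of real ping-pong towers. Parameter
recovery on these libraries demonstrates correctness of the computations,
not robustness to every artifact of real sequencing data.

## Numerical and design choices

- All randomness flows from integer seeds through `numpy` `SeedSequence`
  spawning; simulation, alignment tie-breaks and the pipeline are
  bit-reproducible, and seeds are echoed into outputs.
- Internal coordinates are 0-based half-open; SAM output is 1-based; BED is
  0-based half-open. Strand is defined relative to the deposited reference;
  biological sense (genome vs antigenome of a negative-sense virus) is
  annotation, not alignment.
- Degenerate inputs: empty FASTQ yields an all-zero report rather than an
  error; a zero library total makes RPM (and `align_library`) raise; a zero
  21 nt count flags the ratio undefined; zero coverage makes `bias_test`
  raise; an all-one-strand class yields an all-zero overlap histogram with
  undefined argmax and z10.
- Frequency-matrix rows normalize over A/C/G/U; reads containing N at a
  position contribute to coverage but to no base column, so strictly the
  row sum can fall below 1 in the presence of Ns (absent in simulated
  data).
- The exact binomial test and two-sided p-value come from
  `scipy.stats.binomtest`; tests cross-check it against direct pmf
  summation.

## Known limitations

- The aligner is exact only for ≤ 1 mismatch (the pigeonhole guarantee with
  two seed halves); it does not generalize to higher mismatch budgets or
  indels, and it holds whole-genome seed tables in memory — appropriate for
  kilobase viral genomes, not chromosomes.
- Reads shorter than 18 nt fall back to a full scan; the default length
  window makes this path rare.
- Hotspot calls and the α = 0.01 bias threshold are operational
  conventions for screening and reporting, not inferential claims; heat
  maps and histograms remain the primary evidence.
- Multi-mapped reads within one genome are counted once (best stratum,
  random tie-break); positional profiles of perfect repeats therefore split
  signal stochastically, though reproducibly under the run seed.
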