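# Methods

## The telomere-likeness score

Yeast telomeric DNA is an irregular repeat — on the G-rich strand, a
single T followed by one to three Gs (TG₁₋₃). The score of a sequence
window measures how much of it conforms to that pattern while tolerating
deviation from it.

**Tract rules.** A *candidate tract* opens at a G that begins a run of at
least four consecutive G/T characters. Walking rightward, extension stops
(inclusively) at the first T of a TT pair or at the third G of a run of
four or more Gs — neither TT nor GGGG occurs in the telomeric pattern.
The scan resumes at the character immediately after the stop point, so a
single long G/T run can contribute several tracts. After truncation,
fragments shorter than four bases and fragments containing no T (pure G
runs carry no TG₁₋₃ information) are discarded. Characters outside
A/C/G/T (e.g. N) break runs; lowercase is uppercased, so soft-masking is
ignored.

**Window score.** The score is the summed length of all candidate tracts
in the window, minus `ggtgg_penalty` points per occurrence of the literal
`GGTGG` (occurrences may overlap: `GGTGGTGG` counts twice; the
pentanucleotide is counted window-wide, not only inside tracts), minus
`tt_penalty` points per T immediately adjacent to a tract on either side.
Scores are not floored at zero. Defaults apply no penalties; the
genome-analysis parameter set (`GENOME_SCAN_PARAMS`) uses a 75-nt window,
step 1 and a 1.5-point GGTGG penalty, the combination that best separates
sequences with and without measured hotspot activity. A merged region
score of **20** is the operating threshold for calling a putative SiRTA.

**Scanning and clustering.** Only complete windows are scored (positions
0 … L−75, stride = step); a sequence shorter than the window is scored
whole rather than rejected, so short FASTA entries work in score mode.
Windows meeting or exceeding the threshold that overlap or abut are
merged; the merged region spans the most upstream to the most downstream
window and carries the maximum member score. Integer reporting (the score
spectrum) rounds scores down.

The scanner skips windows that touch no G/T run of ≥ 4 nt (their score is
provably 0, since tracts and `GGTGG` both require such a run), which
makes scans of low-GC backgrounds fast without changing any result.

A second, independently written tract enumerator (regex run
decomposition with recursive truncation, `cathi.reference`) implements
the same declared rules with a different mechanism; the test suite checks
exact agreement between the two on thousands of random windows, and
fixture truth tables use the reference path. Note that the scanning
semantics are part of the tract definition: a naive "all substrings
satisfying the local rules" enumeration would differ (e.g. in `GGGGT…` it
would open a tract at the second G, which the scanner — resuming at the
fourth G after truncation — never does).

## Genome mapping

Each chromosome is restricted to its analysis bounds (terminal telomeric
repeats trimmed); when subtelomeric X/Y′-element intervals are excluded,
the chromosome is split into segments at those intervals before
windowing, so no window straddles an excluded region. The plus strand is
scanned directly; the minus strand is scanned as the reverse complement
with window coordinates mapped back to forward coordinates. All internal
coordinates are 0-based half-open; layout files may be declared 1-based
inclusive and are converted on load; BED output is always 0-based.

Annotation of a merged region:

- **arm** — midpoint relative to the centromere midpoint (a deterministic
  rule for the theoretical edge case of a centromere-spanning region);
  without a centromere, relative to the chromosome midpoint;
- **orientation** — TG if (left arm, minus strand) or (right arm, plus
  strand), i.e. the TG-rich strand matches the strand carrying the 3′ TG
  overhang at the nearest telomere; CA otherwise;
- **name** — `{chromosome number}{arm}{kb}({strand})`, where kb is the
  region's forward-strand start divided by 1000, rounded half-up; the
  minus strand is printed as an ASCII `-`;
- **gene overlap** — genic if ≥ 1 bp overlaps a gene (start codon to stop
  codon, from GFF3); the region's TG-rich strand is the transcription
  *template* when region and gene strands differ. Multi-gene overlaps
  resolve to the largest overlap, ties to the leftmost gene start.

## Null models

**Shuffled genomes.** Each chromosome's nucleotides are permuted within
its adjusted bounds (analysis bounds with subtelomeres excised), exactly
preserving length and base multiset. Five replicates by default, with
per-replicate generators spawned from a master seed (`SeedSequence`), so
replicates are independent yet reproducible. Only mononucleotide
composition is preserved — no dinucleotide-preserving mode.

**GCR placement model.** Each trial places `n_events` points uniformly
i.i.d. on `[0, region_len)` and counts those inside a fixed window of
`target_len` (events are points, not intervals). Defaults are the study
conditions of the break-induction assay: 30 recovered events, a 300-bp
test insert, and the 21,922-bp interval between the induced break and the
first essential gene. The Monte-Carlo tail P(X ≥ k) is the reproduction
path; the exact Binomial(n, target/region) tail is computed alongside as
an analytic oracle and the two must agree within Monte-Carlo error. These
tails motivate the activity cutoff: two or more of 30 events in the
window occurs in ≈ 6.3 % of random trials, so an *average* above 2/30
(> 6.6 % efficiency) is unlikely by chance.

**Strand-switch model.** Observed statistic: within each chromosome,
regions sorted by start; a *switch* is a neighbouring pair on opposite
strands; runs and singlets (runs of length 1) are tabulated; statistics
are summed across chromosomes. The null permutes strand labels uniformly
within each chromosome, preserving per-strand counts, and sums statistics
across chromosomes *per iteration* (never pooling across iterations,
which would hide edge effects). The closed form E[switches] =
Σ_chrom 2·n₊·n₋/(n₊+n₋) serves as an oracle in the tests only; the
permutation path is the product. Chromosomes with fewer than two regions
contribute zero switches and (for one region) one singlet.

## Overlap enrichment

Observed count: queries with at least one qualifying overlap, where
qualification requires the overlap to cover ≥ `min_fraction` (default
0.5) of the declared side — the annotation for compact binding sites and
G-quadruplex calls, the query for broad essential/nonessential territory
— and matching strands when the annotation set is stranded. Annotations
(never queries) are re-placed for the null: each interval keeps its
length and strand label and is dropped uniformly into the currently free
genomic space, genome-wide by default (chromosomes weighted by free
space; a per-chromosome mode exists for sensitivity analysis), avoiding
exclusions and previously placed intervals.

Placement is implemented by free-gap bookkeeping: the allowed space is a
list of gaps; an interval's start is drawn uniformly over every position
where it fits, and the chosen gap is split. This is exactly uniform per
placement, cannot loop, and raises a `PlacementError` when no slot
remains (the rejection-sampling failure mode, surfaced deterministically).

The empirical p is one-sided in the direction of the observed effect and
reported as the raw fraction r/n with the (r+1)/(n+1) variant alongside;
the Bonferroni multiplier is the number of annotation sets tested in one
run. 1000 permutations by default.

## PT-seq quantification

Reads are assigned to the 300-bp target or control locus by the longest
contiguous exact match to either strand (default minimum 30 nt; ties go
to the longer match). Alignments from an external local aligner (SAM/BAM)
are accepted as an alternative assignment source; motif detection,
junction calling and normalisation are identical either way.

A target read is a telomere-addition event iff it contains the telomeric
seed (`GGGTGTGG` on the TG-rich strand, `CCACACCC` on the other) **beyond
its chromosome-matching segment** — target sequences are themselves
TG-rich, so a seed inside the matching segment is chromosomal, not
telomeric. A lenient contains-the-motif-anywhere mode is available behind
a flag. The junction is the last target-matching base on the TG-rich
strand (local 0-based target coordinate); reverse-complement reads give
the same junction with flipped orientation. Reads are the counting unit;
no deduplication.

Event counts are normalised as a percentage of control reads and mapped
to per-clone efficiency by a linear standard curve (defaults calibrated
at the two assay loci: slope 3.961/intercept −2.039 and
3.8022/−0.5505), with the output clamped to [0, 100] %. The x axis is
taken to be the normalised read percentage. A hotspot is *active* when
efficiency is strictly greater than 6.6 %.

## Synthetic fixtures

The planted-genome generator emulates a genome in which the only
telomere-like signal is placed deliberately. Its G-free background draws
from **A/T only**: a background of A/C/T would be G-free on the plus
strand yet G/T-rich on the minus strand (the complement of C is G), so
A/T is the only background that guarantees zero false positives in a
two-strand scan. Each plant is flanked by a one-base guard (A for plus
plants, T for minus plants — a non-G/T base on the plant's TG-rich
strand) so background bases can never extend a planted tract; the truth
table's expected score is then exactly the tract's own reference score.
The composition-matched background draws from user frequencies (default
A/T-rich, yeast-like) and makes no false-positive guarantee.

The read simulator builds event reads as a target prefix ending at the
planted junction followed by a telomeric tail: a fixed head
(`GTGTGGGTGTGG`, which contains the seed, so every simulated event is
detectable) then random T·G₁₋₃ repeats. The degenerate-tail mode uses
plain `TGG` repeats, which contain no seed, to exercise the detector's
miss behaviour. An optional uniform substitution rate is the only error
model.

What the fixtures do **not** emulate: real subtelomeric repeat structure,
sequencing quality profiles and indels, library-preparation artefacts,
PCR duplicates, and the composition heterogeneity of real chromosomes.
Passing the recovery tests therefore demonstrates correctness of the
algorithms under clean conditions, not robustness to noisy real data —
for real data, alignment-based assignment (SAM input) and the documented
thresholds are the intended path.

## Numerical and design choices

- Determinism: every stochastic routine takes a seed (or a NumPy
  `Generator`); identical inputs give bit-identical outputs.
- Monte-Carlo sizes: 10,000 iterations for the GCR and strand nulls
  (matching the analysis design), 1000 permutations for enrichment;
  tests use smaller sizes with 3-standard-error tolerances against
  closed-form oracles.
- The kb in region names rounds half-up (499 → 0, 500 → 1); start
  coordinate, not midpoint, anchors the name.
- Clustering threshold comparisons are inclusive (score ≥ threshold).
- Raising the cluster threshold never widens a region and never grows
  total coverage, but *can* split a region in two when a bridging window
  falls below the new threshold; the property tests assert the true
  containment form of the invariant.
- Genome-scale reproduction (the full yeast chromosome set with
  supplementary trim coordinates) is supported by the same code paths via
  `cathi genome-scan`; the bundled tests and the acceptance script run on
  synthetic and closed-form inputs only, with problem sizes (100-kb
  planted genomes, 10⁵–2×10⁵ Monte-Carlo trials) chosen to give exact or
  3-SE-tight checks in seconds.

## Known limitations

- The tokenizer's resume-after-truncation rule and the post-truncation
  length/all-G filters are declared design decisions; genome-scale counts
  are sensitive to them, so alternative conventions would shift absolute
  region tallies.
- The magnitude of the flanking-T penalty is unspecified by the scoring
  model's published form; it defaults to 0 and is configurable.
- The built-in read assigner is exact-match only; reads with sequencing
  errors inside their anchoring segment shorten the match and may fall
  below `min_match` — use an external aligner for error-prone data.
- Enrichment placement treats annotations as rigid intervals; no
  composition- or distance-matching of the shuffled intervals.
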