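# Methods

## Deamination model

Editing is modelled per position and per strand. An `EditingModel` maps
`(position, strand)` to a conversion probability for the cytosine at that
position: reference C positions are edited on the plus strand (observed
C→T), reference G positions carry the cytosine on the minus strand
(observed G→A in plus coordinates). Probabilities are resolved inside a
single editing window — the spacer between the two zinc-finger half-sites —
either explicitly per position or from dinucleotide-context defaults, where
the context is the base 5′ of the C *on its own strand* (TC, AC, GC, CC).
TC is the preferred substrate of the split deaminase; sensible defaults give
TC a much higher rate than the other contexts.

Three further channels:

- `seq_error_rate` — per-base substitution error, uniform over the three
  alternative bases (default 0.001, a round figure for short-read
  platforms). There is no per-cycle or quality-dependent error profile.
- `indel_rate` — per-read probability of a single 1-bp insertion or
  deletion inside the window (default 0; deaminases do not cut DNA, the
  channel exists so the indel estimator has something to recover in tests).
- `dose_scale` ∈ [0, 1] — multiplies every rate, emulating titration of the
  delivered editor; 0 is an identity channel apart from sequencing error.

## Read simulation

Amplicon mode emits single-end reads covering the whole amplicon (amplicon
deep sequencing is effectively full-coverage); genome mode tiles fixed-length
reads (default 150 nt) at uniformly random start positions over a *circular*
genome to a requested mean depth, wrapping the origin. All bases get one
constant high quality symbol; read layout is a stand-in, not a
reconstruction of any particular instrument. Every generator takes a seed
and is byte-deterministic: identical inputs and seed give identical FASTQ.

Clonal populations model heteroplasmy: the positions with positive rate
define a fully converted mutant haplotype, and a clone with fraction *f*
draws each read from that haplotype with probability *f* — so the measured
conversion frequency estimates *f* directly, matching how single-cell-derived
clones carry a variant at a defined heteroplasmic fraction rather than
re-rolling each molecule.

Whole-genome samples additionally plant `n_sites` off-target edits at C/G
positions outside the on-target window, a configured fraction of them in TC
context (default 0.8), with rates drawn uniformly from a range (default
2–10%, matching the scale of calls just above the 1% threshold); off-target
rates share the on-target model's `dose_scale` so a dose series moves both
together. Planted SNVs (position, alt, fraction ≈ 1) emulate cell-line
variants shared across samples. Ground truth (positions, strands, true
rates, contexts) is emitted beside the reads and never consumed by analysis.

What the simulator does *not* emulate: PCR duplicates and chimeras,
paired-end geometry, quality-score profiles, strand bias, alignment
ambiguity from NUMTs or repeats. Passing recovery tests therefore shows the
estimators are correct for clean planted signals, not that real-data
artefacts are handled.

## Alignment and quantification

Reads are aligned semi-globally — read global, reference ends free — under
affine gaps (defaults: match +2, mismatch −3, gap open −5, gap extend −2; a
gap of length L costs open + (L−1)·extend). The engine is Biopython's
`PairwiseAligner`; co-optimal ties are broken by the engine's deterministic
enumeration order. Test suites check the score against an independent
memoized affine-state recursion on small random pairs. Whole-genome reads
are first anchored by a unique k-mer seed (k = 20) and then aligned inside
the local window, which handles origin wrap and keeps one alignment code
path; reads with no unambiguous seed are dropped.

Coordinates are 0-based half-open internally and 1-based in every TSV/JSON
report; BED input is 0-based half-open.

The pileup counts A/C/G/T/deletion per reference position; depth includes
deleted bases (the read still overlaps), and insertions are anchored to the
preceding position without consuming reference coordinates. Substitution
frequency is count/depth. Positions with depth below `min_depth`
(default 10) are reported *missing*, not zero, so sparse positions cannot
deflate averages. Window profiles label each spacer cytosine `C_n` with n
counted 1-based from the spacer's 5′ end on the displayed strand, for both
plus- and minus-strand cytosines.

Indel frequency over a window is the fraction of window-overlapping reads
whose alignment has a deletion intersecting the window or an insertion point
strictly inside it.

Allele tables group reads spanning the whole window by their exact aligned
window sequence; indel-containing alleles are flagged frameshift and not
translated. Amino-acid changes use NCBI translation tables (vertebrate
mitochondrial, table 2, for mtDNA genes; standard, table 1, otherwise),
with stop gains marked `*`. Clone classification uses two inclusive
thresholds (background ≤ 2%, edited ≥ 5% by default — any pair between the
observed ≤1% error background and ≥26% real heteroplasmy behaves
identically); the gap between them is labelled indeterminate.

## Off-target analysis

Conversion tables cover every C/G position of the circular genome with
depth ≥ 10 (sequencing depth in the motivating experiments was well above
this). Masking, calling and reporting follow three explicit rules, all with
inclusive comparisons: (1) positions converted at ≥ 50% in **all** samples
are SNVs and are masked; (2) C/G positions inside the on-target spacer are
excluded (half-site inclusion is a caller option via the interval passed);
(3) remaining positions with rate ≥ 1% are off-target calls. The
specificity report gives the mean rate over on-target C/Gs, over called
off-target sites, and over all C/Gs genome-wide; the ratio uses the
off-target-call mean and is reported as undefined (never infinity) when
there are no calls. Context matrices extract ±k bases around each call on
the edited strand (minus-strand calls reverse-complemented, circular wrap),
giving a position-frequency matrix for logo tools; the offset −1 row carries
the TC preference. Dose series share one mask across all samples.

A note on background: with per-base error e and depth d, a position crosses
the 1% threshold when ⌈0.01·d⌉ error reads agree; at d = 200 and e = 0.001
this happens at roughly 0.2% of C/G positions, which is why the false-call
guarantee is stated as ≤ 1% of unplanted C/Gs rather than zero.

## Design

Architecture space: linker ∈ {2, 5, 10, 16, 24, 32} AA × split ∈
{G1333, G1397} × N-terminal-half side ∈ {left, right} — 24 constructs — with
the CC/NC fusion configuration as an additional axis held fixed by default.
Site scanning enumerates every (half-site, spacer, half-site) placement on
both strands (12-bp half-sites, 7–15-bp spacers by default, circular wrap
optional); the editable-C filter requires a TC-context cytosine on either
spacer strand, the 5′ neighbour possibly coming from the flanking
half-site, while AC/GC/CC cytosines are reported but not required since they
edit less efficiently. ZFN→ZFD conversion removes spacer-proximal fingers
(3 bp each) until the spacer reaches 7 bp, then appends distal fingers to
restore a 4-finger minimum, and fails rather than go below three fingers.
The QQ variant substitutes Q for R at framework position −5 in each finger,
falling back to the nearest annotated K/R in the fixed order −4, −6, −3, −7
("nearby" is otherwise underdetermined); converted fingers are flagged,
making the transformation idempotent. Framework numbering is user-supplied
annotation; no binding-affinity or efficiency prediction is attempted. The
module-table format (triplet → finger id) is defined here with toy fixtures;
curated public module resources can be dropped in as TSV.

## Problem sizes and determinism

Default test and acceptance workloads: 200-nt amplicons at 10,000 reads,
3-kb circular genomes at depth 150–200 with 15–25 planted off-target sites —
sizes at which every planted quantity is recoverable within 3 binomial
standard deviations while whole suites run in well under a minute apiece.
Recovery assertions use exactly that 3-SD band. All randomness flows through
`numpy.random.default_rng(seed)`; pipelines echo their resolved
configuration and seed into every report bundle.

## Known limitations

- The mapper requires one unique error-free k-mer per read; highly
  repetitive genomes would need a real seed-chain aligner.
- Minus-strand reads are not simulated (edits on the minus strand are
  represented in plus coordinates, which is equivalent for counting).
- Allele translation skips indel alleles instead of attempting frameshift
  consequences.
- No base-quality modelling or filtering: simulated reads carry a constant
  quality symbol and quality strings of external reads are ignored.
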