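# Methods

`ampliopt` benchmarks 16S rRNA amplicon-sequencing *conditions* — read
length, truncation lengths, primer region, and reference database — by
running a complete, simplified analysis pipeline on synthetic reads whose
ground truth is known exactly. This note records the models, the defaults
and why they hold, and what the synthetic substrate can and cannot say
about real data.

## Ground truth: mock-community theory

A DNA-pooled mock community mixes known masses of genomic DNA. Each
member's contribution of 16S gene copies is

    copies = dna_mass (g) × bp_per_gram (bp/g) / genome_size (bp) × copies_per_genome

and the theoretical relative abundance is each member's share of the
total. `bp_per_gram` defaults to 9.27e20 bp/g (Avogadro's number over
~650 g·mol⁻¹ per base pair of double-stranded DNA) and is configurable.
Expected read counts at a given depth are kept real-valued; rounding
happens only in report writers, so the composition is never distorted by
integer truncation.

The two bundled mock fixtures (15 environmental taxa; 6 oral taxa) carry
**synthetic** genome sizes and operon counts — plausible magnitudes, not
strain-certificate values. Their copy-density profiles are deliberately
two-tiered (dense high tier, sparse low tier, a >2× gap between them) so
that no taxon's theoretical CLR value sits near zero. This matters
because accuracy is graded as *relative* percent error of CLR values: a
taxon whose abundance equals the geometric mean has CLR ≈ 0 and an
ill-conditioned relative error, which would make the grade meaningless
rather than informative. The profiles were fixed from this conditioning
argument (minimum |CLR| ≈ 0.35, ≥3σ multinomial margin at the study
depth below) before any end-to-end run.

## Synthetic 16S scaffold and primers

References follow the real architecture of the 16S gene: nine conserved
blocks C0..C8 interleaved with eight taxon-specific variable blocks
V1..V8, plus 30 bp flanks. A primer pair spanning regions Vi..Vj uses
the conserved block 5′ of Vi as forward primer and the reverse
complement of the block 3′ of Vj as reverse primer, so the post-primer
amplicon is `Vi Ci … Vj`. The V3-V4 pair is the real degenerate
341F/806R (806R also serves as V4's reverse primer); C2 and C4 are
concrete IUPAC realizations of those primers, so degenerate matching is
exercised on every reference. The other seven primer sequences are
synthetic stand-ins named only for the regions they span.

Variable-block lengths put the amplicons in familiar territory (V3 ≈
142 bp, V4 = 251 bp, V3-V4 ≈ 411 bp, V3-V5 ≈ 512 bp) and make the two
longest regions unmergeable on a 250 bp paired-end grid capped at 230 bp
trims — the "overlap less than zero" regime — while remaining marginally
mergeable at 300 bp. Per-taxon variable blocks are derived from shared
templates by seeded substitutions at 10% per base; sequences are
deterministic in `(seed, taxon name)` alone, so simulator amplicons and
database entries always agree.

All coordinates are 0-based half-open internally; every trim length and
amplicon length in the package is measured **after primer removal**, one
convention everywhere.

## Read simulator

Templates are drawn multinomially from the theoretical composition.
A forward read is the 5′ prefix of the amplicon, a reverse read the 5′
prefix of its reverse complement, each of length
`min(read_len, amplicon_len)` — reads do **not** run past the amplicon
into adapter, so truncation lengths exceeding the available template
discard the pair downstream, reproducing the over-trimming survival
collapse.

Per-base Phred qualities decay from `q_start` to `q_end` (linear by
default; a logistic ramp with midpoint at 60% of the read is available),
with Gaussian jitter (sd 2) and clamping to [2, 41]. Defaults: forward
38→24, reverse 37→15 — reverse reads decay harder, as on a real flow
cell. Substitution errors occur per base with probability 10^(−Q/10);
there are no indels (the dominant MiSeq error mode is substitution, and
exact-overlap merging stays decidable). `ERROR_FREE_QUALITY` sets a
`perfect` flag: maximal written quality and no substitutions at all,
giving exact reads for the identity-regime contracts.

Chimeras: with configurable probability (default 5%) a template is
`parent_a[:k] + parent_b[k:]` with both parents drawn
abundance-weighted (distinct) and the breakpoint uniform over the
interior 20–80% of the amplicon, which keeps chimeras detectable by
two-parent segment matching. Every read carries full provenance in a
sidecar truth table; FASTQ files stay standard.

All randomness flows from a single integer seed; identical
configurations give byte-identical FASTQ output.

## Denoising emulator

The central simplification of the package: a learned error model is
**not** re-implemented. The stage chain is

1. **Truncate & filter** — cut both mates to fixed lengths; drop a pair
   if either mate is shorter than its truncation length or its truncated
   expected errors Σ10^(−Q/10) exceed `max_expected_errors` (default 2.0
   per read, the common practice value).
2. **Merge** — reverse-complement the reverse mate and accept the
   *longest* overlap of at least `min_overlap` (default 16 bp) with at
   most `max_mismatch_in_overlap` mismatches (default 0; with a budget,
   the higher-Phred base wins inside the overlap). The longest-overlap
   rule is the deterministic tie-break; a seeded substring search makes
   the exact-overlap case fast without changing its result.
3. **Dereplicate** — exact-identity ASVs, then a single-pass collapse of
   any sequence into a Hamming-distance-1 neighbour at least 8× more
   abundant (fold configurable, pre-collapse abundances, most-abundant
   neighbour first, ties by sequence order). This absorbs singleton
   sequencing errors the way error-model denoising would, and no more.
4. **De-bimera** — an ASV is removed iff two *distinct* ASVs, each at
   least `parent_fold` (default 2.0) times as abundant, explain it
   exactly as a prefix of one plus a suffix of the other (equal lengths;
   substitution-only simulation preserves length). The most abundant ASV
   is structurally immune.

Survival percentages are always relative to the primer-removed input
pairs, exact internally, rounded to two decimals only in writers, with
negative overlaps printed as the literal `Less than 0`. Zero input
yields all-zero percentages with a warning. The chain
filtered ≥ merged ≥ non-chimeric is monotone by construction and
asserted by the `SurvivalStats` invariant.

## Trim-length grid

Both read directions share one arithmetic truncation sequence: 90–230 bp
step 10 for 250 bp reads (15 positions, 225 ordered pairs per primer),
90–280 bp for 300 bp reads (20 positions, 400 pairs). "Between" is read
inclusively — that is what makes the advertised position counts come
out. Every cell is evaluated against the same input; the winner
maximizes the non-chimeric read *count*, with ties broken by larger
total retained length, then larger forward trim (the tie-break is this
package's choice; plateaus of perfect survival occur in the error-free
regime and need a deterministic rule). An all-zero surface still
returns a best cell and is flagged degenerate. The full surface is
retained for plotting without re-runs. Cell ranking may run on a seeded
random subsample (`max_pairs`) since percentages, not totals, are
compared.

The quality heuristic `suggest_trim_by_quality` returns the longest
truncation at which the 25th-percentile Phred quality still reaches 20 —
the standard rule of thumb for choosing forward trims before any grid
search.

## Taxonomy and database coverage

A reference database is a list of full-length entries with seven-rank
lineages plus an alias map and a blocklist of non-names ("metagenome",
"uncultured", …) that are never assigned. Fixture databases reuse the
scaffold sequences and drop chosen taxa to emulate coverage gaps;
dropped taxa can never be returned, so their reads become "Unassigned".

Assignment is top-hit global-alignment identity (edlib) of each ASV
against region-extracted references, thresholded at 0.97 for species
and 0.90 for genus (configurable); below threshold → "Unassigned".
Ties break by lexicographic label, then entry id. This replaces a
fitted naive-Bayes classifier — the package's second deliberate
simplification — and is justified because the synthetic scaffold makes
the correct mapping exact; it does not model classifier confidence.
Collapsing ASV counts to a rank conserves totals exactly, with
"Unassigned" kept as its own row.

## Compositional scoring

Counts are compositional, so profiles are compared in centered log-ratio
coordinates (natural log). Zeros are first replaced multiplicatively
with a pseudo-proportion of **half the smallest nonzero proportion**,
shrinking nonzeros so the vector still closes to 1. CLR output sums to
zero within 1e-10 and ignores input scale. ASV rows averaging fewer
than one read across samples are removed first (strict "fewer than":
a mean of exactly 1.0 stays).

Accuracy per taxon: relative percent error of observed vs theoretical
CLR, `100·(obs − theo)/|theo|`; within ±5% "+", within ±25% "○",
beyond "-", and "×" for unregistered taxa regardless of values. When
the theoretical CLR is exactly 0 the relative error is undefined and an
absolute-difference fallback (same bands in CLR units/100) applies with
a warning — one of two readings the grading legend admits; grading on
relative abundances instead of CLR is available as an option. Shannon
diversity uses log base 2 (which is what reconciles uniform-mock values
with their expected ranges: log₂15 ≈ 3.91, log₂6 ≈ 2.59). Rank
similarity is Spearman's correlation with average ranks and a two-sided
p; identical (or exactly reversed) rankings return ±1 exactly rather
than Pearson-on-ranks roundoff. PCA centers the CLR matrix column-wise
and decomposes by SVD, components ordered by variance with each
component's largest-magnitude loading made positive; the "ideal" sample
built from expected read counts enters as an ordinary column.

## Problem sizes

Defaults and the sizes the test suite and acceptance script run at,
chosen as this package's study conditions: 10,000-pair runs for survival
accounting and chimera recovery (injected rate 10% for the recovery
check, 5% otherwise); 20,000 pairs with 400-pair subsampling to rank the
225-cell grid; 3 replicates × 140,000 error-free pairs for the grading
and similarity checks. The last figure is a typical MiSeq per-sample
yield and gives the rarest fixture taxon (p ≈ 0.9%) a ≥3σ multinomial
margin inside the ±5% grade band — at meaningfully smaller depths the
grade of the rare tail is sampling noise, not pipeline accuracy.

## What passing does and does not show

The simulator emulates the features the trimming problem responds to —
positional quality decay, quality-driven substitutions, amplicon-length
geometry, chimera formation, database coverage gaps — and omits indels,
PCR-cycle chimera kinetics, flow-cell artifacts, instrument quality
binning, primer-template mismatch bias, and contamination. Green tests
therefore certify the *procedure* (the survival accounting, the
geometry arithmetic, the compositional scoring) on data satisfying the
simulator's assumptions; they do not certify absolute survival
percentages or taxonomic accuracy on any real MiSeq run, which depend
on a real error model and real databases. Likewise the top-hit
assigner bounds what database dropout does to accuracy, not how a
trained classifier behaves near its confidence threshold.
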