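# Methods

## The enzymatic library model

Reference transcripts are single-stranded cDNA in sense orientation over a
strict ACGT alphabet; coordinates are 0-based half-open, and the AluI cut
position is recorded as the index of the C in `AGCT`. Digestion scans for
overlapping motifs (`AGCTAGCT` cuts twice) and always yields a partition of
the transcript, so fragment lengths sum to the transcript length.

Each AluI site can yield two guides: the *right* guide is the first
`stem_len` nucleotides of the downstream fragment on the top strand, the
*left* guide the first `stem_len` nucleotides of the reverse complement of
the upstream fragment — both read away from the cut and both start with
`CT`. Guides from fragments shorter than `stem_len` are *unrealizable* but
still counted, because the ranking percentage divides by the per-site
theoretical maximum (2 × sites). The default guide length is 20 nt
(MmeI's 18-bp capture plus its 2-nt overhang); 19 nt is configurable.

The simulated BpmI digestion cuts exactly at the restored AluI junction,
so the released 91-bp insert carries no residual adapter-A arm:
91 = 2 × 20 (stems) + 51 (adapter-C-derived palindromic center containing
the 9-nt loop). The geometry object enforces
`2·arm + 2·stem + core = 91` and raises on any inconsistent combination.
The true adapter base sequences are not public; the center is therefore a
synthetic stand-in (constant `SYNTHETIC_C_ARM`, labelled synthetic in the
source) that carries a BsgI recognition motif at the documented offset and
is free of AluI sites and of the loop sequence. The insert's released ends
are annotated with the 2-nt `AG` extensions that ligate into the vector's
`CT` overhangs; the main-text description speaks of CT overhangs on the
fragment and the supplementary scheme of AG overhangs on the insert — the
two are the complementary ligation partners, and the package records the
insert side as `AG`.

The transcribed hairpin is modeled as `G + guide + loop +
revcomp(G + guide) + TTTTT`: the vector G restores part of the AluI site
(hence the `GCT` start), the loop is 9 nt, and `TTTTT` marks the
transcription terminator. The default loop, `TTCAAGAGA`, is the standard
pSUPER-family hairpin loop; it is configurable, and every stage reads it
from the shared `Config`.

## SSH kinetics

Re-annealing after melting is second order. For species *i* with tester
concentration `t_i` and driver concentration `d_i` mixed at driver excess
`E` (default 60), the complementary single-strand pool is
`c_i = t_i + E·d_i` and the adapter-ligated single strands decay as

    s_i(τ) = t_i / (1 + k · c_i · τ),

the exact solution of `ds/dt = −k·s·c`, `dc/dt = −k·c²`. This single
closed form produces both SSH behaviors: *normalization* (abundant species
anneal away faster, so the coefficient of variation across equally
expressed species is non-increasing in time) and *enrichment* (species
repressed in the driver have small `c_i` and stay single-stranded).

Modeling choices, in the package's own terms:

- **Species independence.** Cross-hybridization between distinct fragments
  is ignored; each fragment anneals only with its own complement. No
  melting-temperature or sequence-dependent model is attempted.
- **Rate constant.** No physical rate constant is available, so `rate_k`
  defaults to auto-calibration with `k·c_max·t₁ = 10` for the most
  abundant species: strong but incomplete removal of abundant shared
  fragments, with the dimensionless product — not the absolute
  concentration scale — controlling the outcome. Any explicit value
  overrides this.
- **Second hybridization.** The A- and B-ligated reactions are mixed and
  anneal with rate `k × peg_rate_multiplier` (default 3, the ratio of the
  two PEG concentrations used experimentally; 0 models omitting PEG) over
  `t₂ = 24 h`. Among the duplexes a species forms, random pairing gives the
  A–B fraction, so the amplifiable yield is
  `φ_i · sA_i · sB_i / (sA_i + sB_i + driver remnant)`, which is
  symmetric in A/B, monotone in time, and never exceeds `min(sA, sB)`.
  The driver remnant of both reactions competes in the denominator.
- **Suppression PCR** multiplies every A–B duplex by the same exponential
  factor and normalizes to a composition; A–A and B–B products contribute
  zero. Polymerase saturation is not modeled, so amplification preserves
  rank order by construction.

Default times (45 h and 24 h) and the 60-fold driver excess follow the
optimized experimental protocol.

## The synthetic screen

The generator emulates the study conditions rather than any particular
dataset. Defaults: 200 transcripts (normal lengths, mean 1500 nt, sd 300,
floor 200), 10 planted suppressors, expression log-normal
(`lognormal(3, 1)` arbitrary units). Planted suppressors are repressed
2–5-fold in both transformed driver genotypes and induced 2–4-fold on
anchor loss (all beyond the 1.66-fold flag threshold, by construction);
other transcripts receive folds uniform in 0.7–1.4. Planted suppressors
are resampled until they carry at least 5 AluI sites, matching the
multi-site transcripts the published profile reports (its entries imply
roughly 4–36 sites each); without this the enzymatic chemistry could not
produce the three independent vectors the hit criterion demands, and the
scenario would test sampling noise rather than the method.

Per-vector knockdown efficacy is a property of the guide, drawn once and
shared by both libraries: zero with probability 2/11 (the published
validation found 9 of 11 enzymatically produced vectors functional),
otherwise uniform in 40–80 %. A vector transforms when it targets a
planted suppressor and its efficacy reaches the transformation threshold
(default 0.5); an optional off-target Bernoulli (default 0) lets the
false-positive behavior of the dual-library criterion be studied.

Selection draws 150,000 infected cells (the library's colony complexity)
multinomially from the SSH-shaped vector composition, then runs two rounds
in which transforming vectors' weights are boosted by a colony-growth
factor (default 50×; the real magnitude is unquantified and is a free
scenario parameter) while non-transforming vectors persist at single-cell
carryover weight. Counts are plain multinomial draws — the minimal noise
model; overdispersion is not simulated.

Reads cover the integrated hairpin
(`flank + G + guide + loop + revcomp(guide) + C + TTTTT + flank`, synthetic
flanks) with i.i.d. per-base substitution errors at rate 0.002 and default
depth 50,000 reads per sample — deliberately below real sequencer depth so
a full two-library, six-sample screen deconvolves in seconds; depth is a
scenario knob. What the generator does **not** emulate: PCR duplicates and
jackpots, quality-score structure, indels, chimeric reads, infection
multiplicity, and real transcriptome homology families (transcripts are
i.i.d. random, so redundancy clusters arise only when planted). Passing
tests therefore demonstrate the correctness of the machinery and the
self-consistency of the model, not performance on real HiSeq data.

## Deconvolution

A read is accepted when the 9-nt loop can be located (exactly, else by a
≤1-mismatch scan) flanked by `stem_len` bases on each side whose
reverse-complement disagreement plus the loop mismatches stay within the
joint budget of 1. The budget is interpreted jointly over loop and stems
(the stricter reading of the published one-mismatch allowance) and is
configurable. The canonical tag is the upstream stem 5'→3'; at a
disagreeing position each stem contributes one vote and the upstream base
wins the tie, so a downstream-stem error still yields the true tag while
an upstream-stem error yields a Hamming-1 neighbor. Those neighbors are
absorbed by the tag-merging step (a tag folds into a ≥10×-more-abundant
Hamming-1 neighbor; disable-able). Tags not in any vector catalog are
retained — the stage is reference-free — and resolved only at mapping.

Counts are normalized to counts-per-million per sample. Enrichment is
`(post_cpm + ε)/(pre_cpm + ε)` with ε = 0.5 cpm, a standard pseudocount
that keeps tags appearing from zero callable (10 cpm from zero → ratio 21);
a vector is transforming iff the ratio strictly exceeds 3. The default
contrast is pre-selection vs post-round-2; both rounds' counts are kept.

## Target identification

Mapping requires, by default, an exact `stem_len`-mer match that abuts an
AluI cut in the orientation the enzymatic model produces — implemented as a
lookup in the enumerated guide index over both strands. A mismatch-tolerant,
cut-agnostic substring mode (edlib) is available for degraded or
reference-free inputs. Database transcripts with more than 500 AluI sites
are excluded (strictly greater).

Redundancy clustering links two transcripts when the best local alignment
reaches 95 % identity with 90 % coverage; "single-sided" coverage is read
as coverage of the shorter sequence (the aligned span over its length),
and identity is matching columns over that span. Clusters are connected
components (transitive closure, not cliques), with the longest member as
representative (ties by id). Alignments use Biopython's PairwiseAligner
(match 1, mismatch −2, gap open −2.5, extend −0.5); parameters only need
to separate ~95 %-identical pairs from ~94 %-identical ones, which they do
with margin.

The minimal explaining set is an exact minimum-cardinality set cover found
breadth-first over subset sizes 1, 2, …; ties prefer covers explaining
more total tags, then lexicographic cluster ids. Above 24 candidate
clusters the search falls back to a logged greedy cover (enumeration cost
doubles per cluster; real instances sit far below the bound). The >15 %
AluI-site coverage filter — distinct transforming tags over the
representative's `2 × sites` maximum, strict inequality — runs *after* the
cover, following the stated order of operations; the ordering is
configurable in the pipeline code. Clusters mixing gene labels are removed
as ambiguous. Every transforming tag ends in exactly one bin: explained by
a surviving cluster, explained by a removed cluster (with its reason), or
unmapped — the partition is asserted in tests.

## Hit calling and ranking

A suppressor needs at least three *distinct* transforming vectors —
distinct (transcript, AluI site, side) identities, not distinct read
sequences — in each of the two libraries. The ranking percentage is
rounded half-up to an integer before multiplication because the published
scores are exact integer products of the two printed columns. The
percentage denominator is the theoretical maximum (2 × sites of the
representative); the published profile appears to use a realizable-vector
denominator for at least one entry (one row's count/percentage pair implies
an odd maximum), so the realizable count is also carried on each record,
with the theoretical denominator as the default. Sorting is by score
descending, then percentage descending, then stable input order — the
ordering that reproduces the published table, whose remaining ties are not
lexicographic. Expression flags are strict (`fold > 1.66`); a fold of
exactly 1.66 is not flagged.

## Numerical and degenerate-input conventions

- Zero hybridization time or rate returns the input pool unchanged; an
  all-zero duplex pool raises "empty subtracted library".
- Empty samples cannot be cpm-normalized (error), and a missing pre/post
  sample is an error rather than a silent skip.
- A transcript with zero AluI sites yields one uncut fragment, no vectors,
  and a zero theoretical maximum; such records are excluded from ranking
  with a warning.
- All randomness flows from one integer seed through
  `numpy.random.SeedSequence.spawn`, so every artifact, FASTQ byte
  included, is reproducible bit-for-bit.

## Problem sizes

The default scenario (200 × ~1.5 kb transcripts, two libraries, three
samples each at 50,000 reads) runs the complete pipeline in well under a
minute on one core; the kinetics oracle, the 1000-instance set-cover
comparison, and the 100,000-read extraction checks are sized to keep the
full test suite in the tens of seconds. These sizes are the package's
defaults, chosen to make desk-scale experimentation pleasant; every one of
them scales up through the scenario/config objects.
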