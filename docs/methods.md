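# Methods

This note documents the models, parameters and design choices behind
`cliptome`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and transcript models

All intervals are 0-based half-open; GTF input is converted on read.
Transcript coordinates run 5'→3' in transcript orientation, so position
0 is the 5' end on either genomic strand, and the 5'UTR/CDS/3'UTR
partition is computed by classifying every exonic base against the CDS
span. Splicing is handled by an explicit per-base genome↔transcript map;
projection of a genomic interval returns the covered spliced interval
(intronic-only intervals map to nothing). Representative transcripts are
the longest protein-coding isoform per gene with ≥ 30 % of spliced
positions covered by at least one RNA-seq base call ("at least" read as
inclusive, ≥ 0.30); length ties break deterministically by smallest
transcript id. Coverage for this rule is counted over the whole spliced
transcript.

## Coverage and enrichment

A read contributes one base call to every exonic transcript position its
genomic interval covers; libraries are stranded, and only reads matching
the transcript's orientation are counted. The cross-link site of a read
is the position immediately 5' of its first base (iCLIP truncation
chemistry), clamped at position 0. Inputs are assumed PCR-deduplicated
upstream; `collapse_duplicates` exists for synthetic-data realism.

Per-position enrichment is e_i = M·L·c_i / (N·Σr_j) with library sizes
taken over whole libraries, not per transcript. e is undefined — flagged,
never zero-filled — for transcripts without RNA-seq signal. Useful
identities used as tests: e is invariant under joint scaling of a
library and its size; the transcript mean of e equals the ratio of
library mass fractions; e ≡ 1 exactly when CLIP is proportional to
RNA-seq. The RIP enrichment factor is the library-normalized
whole-transcript IP:input ratio (per-nucleotide and whole-transcript
forms coincide; transcript length cancels).

## Clusters, segmentation, windows

Clusters are maximal covered runs, with runs ≤ `cluster_gap_max` (15 nt)
apart merged. Clusters with fewer than 6 reads, or on transcripts
averaging under 5 RNA-seq reads/nt, are discarded. Because CLIP clusters
can span entire 3'UTRs, each cluster is segmented at sharp enrichment
changes: at every boundary the means of the adjacent 10-nt windows are
compared, a boundary is a cut candidate when their ratio leaves
[0.5, 2.0], and within each maximal run of consecutive candidates only
the sharpest change (largest |log ratio|) is cut — cutting every
candidate would shatter a single step edge into 1-nt fragments, whereas
the sharpest-change rule reproduces the two-segment least-squares
change-point on a clean step. Segments shorter than 10 nt merge into the
neighbour with the closer mean; segments always tile their parent
exactly. Each segment is labelled 5'UTR/CDS/3'UTR by the majority of its
own bases (not its parent's: a whole-transcript cluster still yields
3'UTR-labelled sub-segments, which is what the 3'UTR segment ranking
needs). All four segmentation constants are config keys; they are
pragmatic defaults, not measured quantities.

Ranking takes the top *n* 3'UTR segments by maximal enrichment with a
deterministic (id, position) tie-break. The cross-link region is
[s−5, s+5) at the segment 5' start s, flanked by [s−50, s−5) and
[s+5, s+50), clipped to the transcript; widths are configurable and were
chosen to cover the read-start pileup and the flanking repeat blocks.

Background intervals for word statistics are drawn uniformly from
expressed transcripts' 3'UTRs, length-matched to the foreground by
resampling with replacement, avoiding foreground overlap where the UTR
space permits (when foreground covers an entire UTR complement, overlap
is allowed rather than failing; drawn lengths exceeding every available
UTR are an error unless the caller opts into clamping). Sampling is
fully seeded.

## Word statistics

Tetramer occurrences are assigned to cross-link vs flank by their start
position; overlapping occurrences all count. Z-scores use the empirical
mean and sd over ≥ 20 independent seeded background samples rather than
an analytic null — the counting process is not Poisson across windows of
correlated sequence. Under resampling from the background process the
word Z-scores are approximately standard normal (checked). The
positional profile is the foreground/background ratio of word-family
start frequencies per offset from the segment start, smoothed by a
centred 5-nt running mean. MACA co-occurrence histograms ordered match
pair lags ≤ 30 nt, normalized by dinucleotide-shuffled sequences
(Altschul–Erikson Euler-walk shuffle, written here because no installed
library provides one). The 3'UTR length correlation uses Spearman rank
correlation: the length distribution is heavy-tailed and no linearity is
implied.

## The composite-motif HMM

Topology (data-driven config, not hard-coded): background B with uniform
emissions; CA module {C_ca, A_ca} with C_ca→A_ca forced and
A_ca→{C_ca, A_ca}, generating CA and CAA repeats; UA module
{U_ua, A_ua} fully connected, generating UA/UU-rich runs. Each motif
state emits its letter with probability 0.9 (others 0.1/3). The single
parameter t1 = 0.95 is the probability of remaining inside the current
module, shared uniformly over the allowed intra-module moves, with 1−t1
exiting to B; motif length is then geometric with mean 20 nt, matching
the extended elements seen in CLIP clusters. B moves uniformly over
{B, C_ca, U_ua}. The initial distribution is uniform over states so
motifs at sequence starts are not penalized (chunked decoding makes
"start" arbitrary anyway). Unknown letters (N) emit uniformly in every
state.

Viterbi decoding runs in log space (a 1 Mb sequence decodes without
non-finite values) and is vectorized across same-length sequence
batches; ties prefer the lowest state index, i.e. background —
conservative motif calling. Exactness is tested against exhaustive path
enumeration on short random sequences.

Post-processing: maximal same-module runs become CA/UA instances.
Same-module runs separated by fewer than 4 background positions (one
tetramer) are bridged first — they are not independent instances — and
runs still shorter than `min_motif_len` = 4 are dropped. For composite
calling, same-type instances within the 50-nt gap are coalesced (a
repeat element decoded as two nearby runs is one element; same-type
pairs can never form a composite on their own), after which alternating
neighbours with end-to-start gaps ≤ 50 nt (inclusive) chain into
composite sites spanning first start to last end. Instances in no chain
of length ≥ 2 are removed entirely, so no single unmerged instance
survives. Genome annotation decodes overlapping chunks (100 kb, 500 nt
overlap); instances touching an interior chunk edge are dropped because
the overlap guarantees they reappear intact in the neighbouring chunk,
and duplicates from the overlap are removed before merging. A composite
straddling a region boundary counts toward the region holding the
majority of its exonic bases.

## Metagene profiles

Each region is divided into equal-width bins (20/50/50) by fractional
position, a bin's value being the mean of its per-nucleotide values.
Regions shorter than their bin count leave the unfilled bins missing
(NaN), excluded from cross-transcript averaging — zero-filling would bias
the mean downward for short regions. When a region length divides evenly
into the bins, binning conserves mass (Σ bin-mean × bin-width = Σ
values).

## Ranking and intersection

Per dataset, transcripts must be expressed strictly above the dataset's
mean expression (measured from its matched RNA-seq control: the
replicate-matched control for iCLIP, pooled controls for PAR-iCLIP, the
input library for RIP); an optional `max_n` truncation to the most
expressed transcripts is exposed but unbounded by default, since any
specific retained-set size is an outcome of the data, not a constant.
Scores are the mean 3'UTR enrichment per nucleotide (CLIP) or the
whole-transcript RIP factor; an all-equal score vector is flagged as
degenerate. Replicates merge by rank sum over the transcripts retained
in all replicates — scale-free across replicates with different library
depths — re-ranked ascending with id tie-breaks. Per method, the
replicate top-200 sets intersect into a pool; the final targetome is the
intersection of the three pools. Enrichment curves use pooled replicates
(counts and library sizes summed; the statistic is invariant to
duplicating a library) and report the count of transcripts above
three-fold.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with all randomness flowing from one seed (same seed → byte-identical
outputs):

- **Transcriptome**: 2,000 single-exon genes on both strands of
  synthetic chromosomes, ≥ 1 kb apart, with log-normal 5'UTR/CDS/3'UTR
  lengths (medians ≈ 150/900/600 nt) and i.i.d. uniform ACGT background
  sequence — chosen so chance-motif counts have analytic expectations.
  Intron-less genes keep read projection trivial; spliced projection is
  exercised against hand-built multi-exon models in the unit tests, so
  the generator emulates mature-mRNA-space signal only.
- **Expression**: log-normal (σ = 1) per gene; RNA-seq reads (50 nt,
  uniform starts) multinomial with probabilities ∝ expression × length,
  10⁶ reads per replicate.
- **Targets and motifs**: 200 true targets drawn among genes expressed
  above 1.3× the mean — the ranking stage's expression filter means only
  expressed targets are discoverable in principle, so drawing targets
  uniformly would cap recovery by construction rather than measure the
  method. Each target 3'UTR carries one planted composite:
  (CA)₆ · gap · UUAUU · gap · (CAA)₄ with random 5–20 nt gaps; the
  core's constituent tetramers (UUAU, UAUU) belong to the UA-rich word
  family the word statistics highlight.
- **CLIP**: a target transcript's sampling weight is multiplied by the
  binding enrichment (5×), which makes the transcript-level mean CLIP
  enrichment of targets ≈ 5× non-targets (verified within ±30 %);
  within a target 3'UTR, 70 % of reads cross-link at the planted UA core
  with Gaussian positional jitter (sd 2 nt), producing the read-start
  pileup, and the rest follow per-region weights (3'UTR 4.0 vs 0.5
  elsewhere) that encode the protein's 3'UTR preference. Reads start one
  nucleotide 3' of the cross-link. 4×10⁵ reads per CLIP replicate;
  PAR-iCLIP replicates use the same generative model (no 4sU chemistry
  simulated).
- **RIP**: input ∝ expression × length; IP additionally weights targets
  by the binding enrichment; positions uniform (no positional signal).
  Note the measured IP:input factor of a target is below the nominal
  enrichment whenever targets hold a non-negligible share of the IP
  library (the multinomial library normalizer absorbs it) — exactly as
  in real IP experiments; rankings are unaffected since the compression
  is monotone.
- **Cooperative mode**: optional tag rate ∝ (3'UTR length)^α for
  reproducing a positive tag-density/UTR-length correlation (α = 0.5 in
  the acceptance check). Raw tag density correlates only weakly with UTR
  length under log-normal expression (expression noise dominates,
  ρ ≈ 0.25); the acceptance check therefore correlates
  expression-normalized density (the package's natural normalized
  quantity), isolating the length effect (ρ ≈ 0.7). The pipeline's
  observational length-correlation output stays on raw density.

What the synthetic tests do **not** show: robustness to non-uniform
sequence composition, splicing, PCR duplicates, sequencing error,
cross-link-site miscalls, multi-mapping, partial 3'UTR annotation, or
correlated replicate artefacts. Passing them demonstrates the pipeline's
internal correctness and sensitivity under its own model assumptions,
not performance on real libraries.

## Problem sizes and numerics

Default analysis scale is 2,000 genes (~5 Mb genome, ~3×10⁶ reads
across libraries), which runs end to end in a couple of minutes on one
CPU; the generator scales linearly if larger studies are needed.
Segmentation guards ratio computations with ε = 10⁻¹². Z-scores with
zero background sd are NaN and excluded from maxima. Degenerate inputs:
empty sequences decode to empty paths; zero-length regions yield
all-missing bins; transcripts without RNA-seq signal are excluded from
ranking with a log message.

## Known limitations

- The HMM state diagram is a minimal reading of the published model
  class; a different topology is a config change (states, transitions
  and emissions round-trip through a plain-text config), not a code
  change.
- No posterior decoding or parameter re-estimation; the model is used
  with fixed hand-set parameters only, as in the original analysis
  design.
- No statistical peak calling with local null models, and no
  significance testing of overlap sizes; cluster selection is
  rank-based.
- Multi-mapping reads are assumed resolved upstream ("confidently
  mapped" = unique); no read weighting is implemented.
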