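# cliptome

Transcriptome-wide inference of an RNA-binding protein's targetome from
iCLIP / PAR-iCLIP cross-linking data and RIP-seq, with RNA-seq
normalization. The package implements the full analysis chain for a
KH-domain protein of the IGF-II mRNA-binding protein (Imp/IMP) family,
whose binding in *Drosophila* S2 cells concentrates in 3'UTRs on a
bipartite sequence element — a UA-rich core flanked by CA-rich repeats —
together with a synthetic-data generator so that every stage is testable
end to end without any sequencing downloads.

## What it computes

**Per-nucleotide CLIP enrichment.** For a transcript of spliced length
*L* with CLIP base calls *c<sub>i</sub>* at position *i* (library size
*N*) and RNA-seq base calls *r<sub>j</sub>* (library size *M*):

```
e_i = (M · L · c_i) / (N · Σ_j r_j)
```

so *e<sub>i</sub>* = 1 means CLIP signal exactly proportional to
transcript abundance. RIP-seq uses the analogous whole-transcript
IP:input enrichment factor.

**Clusters and cross-link regions.** Contiguous CLIP-covered runs are
called as clusters, split into segments at sharp enrichment
change-points, filtered (≥ 6 reads; host transcript ≥ 5 RNA-seq
reads/nt), and ranked by maximal segment enrichment. The cross-link
region of a segment is a ±5 nt window at its 5' start, where truncated
iCLIP read starts pile up one nucleotide downstream of the cross-linked
base.

**Positional word statistics.** All 256 tetramers are counted in
cross-link regions and 50-nt flanks of the top segments and turned into
Z-scores against repeatedly resampled, length-matched background
intervals from 3'UTRs — separating the UA-rich words (UAUA, AUAU, AUUU,
UAUU, UUAU, UUUU) at the cross-link site from the CA-rich words (ACAC,
CACA, AACA, ACAA, CAAA, AAAC, CAAC) in the flanks. MACA (M = A/C)
co-occurrence lags and the 3'UTR-length/tag-density correlation are also
provided.

**Composite-motif HMM.** A 5-state hidden Markov model (uniform
background; a CA module generating CA/CAA repeats; a UA module
generating UA-rich cores; stay-in-module probability t1 = 0.95, motif
emissions 0.9) is decoded genome-wide on both strands with Viterbi.
Alternating CA/UA instances at most 50 nt apart merge into composite
sites; lone instances are discarded.

**Metagene profiles and ranking.** Per-region binned profiles (20 bins
for the 5'UTR, 50 for the CDS, 50 for the 3'UTR) over representative
transcripts (longest coding isoform with ≥ 30 % RNA-seq coverage);
per-dataset transcript rankings (mean 3'UTR enrichment for CLIP,
enrichment factor for RIP) after an expression filter; rank-sum merging
of replicates; and the conservative targetome as the intersection of the
top-200 lists across two replicates each of three methods.

## Worked example

Simulate a small dataset (300 genes, 40 true targets with planted
composite motifs) and run the whole pipeline:

```
$ cliptome simulate --out demo/data --seed 11 --n-genes 300 --n-targets 40
dataset written to demo/data
$ printf 'data_dir: demo/data\nout_dir: demo/run\nseed: 11\ntop_n: 50\n' > demo/config.yaml
$ cliptome run-all --config demo/config.yaml
n_transcripts: 300
n_representatives: 300
n_clusters: 687
n_segments: 1969
pool_sizes:
  iclip: 43
  pariclip: 44
  rip: 42
final_intersection_size: 40
n_three_fold_clip: 40
n_three_fold_rip: 0
utr_length_corr:
  rho: -0.027977317874679015
  p: 0.6293422235932916
  n: 300
metagene_utr3_cds_ratio: 12.007062796302568
target_recovery: 1.0
false_positive_fraction: 0.0
```

Reading this: 687 CLIP clusters were called and segmented into 1,969
enrichment segments; each method's replicate top-50 lists intersect to
pools of 42–44 transcripts, and the three pools share exactly the 40
planted targets (`target_recovery: 1.0`, no false positives). 40
transcripts exceed three-fold CLIP enrichment over RNA-seq — the planted
targets at 5× binding — and mean 3'UTR enrichment exceeds the CDS
twelve-fold in the metagene profile, reflecting the generator's
3'UTR-biased binding. The length correlation is near zero because
cooperative length-dependent binding is off by default
(`cooperative_alpha`). Per-stage tables (segments, tetramer Z-scores,
positional profiles, motif annotations as BED, rankings, curves) are
written under `demo/run/`.

Stage subcommands (`cliptome coverage|enrich|clusters|words|metagene|hmm|rank`)
run the pipeline up to that stage; `--set key=value` overrides any
config key.

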