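# Methods

## Problem and model

Small RNA-seq libraries contain, besides mature miRNAs, miRNA-sized
fragments excised from longer noncoding RNAs: tsRNAs (from tRNAs), ysRNAs
(from yRNAs), rsRNAs (from rRNAs) and snoRNA/snRNA-derived fragments. The
pipeline quantifies both feature types against a class-labelled catalog of
parent ncRNAs and asks, per feature and per ncRNA class, whether expression
changes when a canonical miRNA biogenesis enzyme (DROSHA, DGCR8, XPO5,
DICER) is knocked out.

The quantification model is deliberately minimal: a fragment is evidenced
only by reads that reproduce a parent subsequence *exactly*, at full read
length, in the miRNA-sized window of 16–32 nt. No mismatches, gaps or
partial-read (local) alignments are accepted. This makes counting
unambiguous and auditable at the cost of losing reads with sequencing
errors or untemplated additions — a deliberate trade, since modification-
or error-tolerant alignment would blur the fragment boundaries that define
the features.

### Exact matcher

A seeded aligner run permissively (word size 6, ungapped, E ≤ 0.001) and
then filtered to 100%-identity matches of 16–32 nt returns exactly the set
of full-read perfect placements, so the matcher implements that filtered
result directly: an exhaustive k-mer index (seed length 16 = the minimum
accepted read length, recorded occurrences for *every* k-mer position of
every parent) proposes candidate placements for a read's first 16-mer, and
each candidate is verified by full-read comparison. The seed length affects
speed only, never results; property tests hold the matcher equal to a
brute-force all-offsets scan on randomized instances. The permissive
seeding parameters may be recorded in a run config (`blast_provenance`) for
provenance, but nothing reads them.

Strand policy defaults to sense-only, since ncRNA fragments are
sense-derived copies of their parent; antisense search (reverse complement
vs parent) exists behind a flag. Reads are processed individually, without
pre-collapsing identical sequences, so each sequenced read counts once.
Reads of accepted length containing non-ACGT characters can never match;
they still count in the RPM denominator (they are sequenced small-RNA
reads) and are tallied separately.

### Fragment loci

Fragment boundaries are not annotated a priori, so loci are called from the
data: read 5′ starts are pooled across **all** libraries of the experiment
(WT and KO share one feature set — essential, otherwise per-condition
feature sets would bias the comparison), and per parent the starts are
clustered greedily. The most frequent remaining start seeds a cluster
(ties go to the leftmost), starts within δ nt join it, and a cluster with
at least `min_reads` pooled reads becomes a locus spanning its leftmost
clustered start to the furthest 3′ end among its reads; overlapping spans
merge. Defaults δ = 2 nt, `min_reads` = 10 were chosen so a sharply
processed fragment population yields exactly one locus while two distinct
fragments of a 75-nt tRNA (5′ and 3′) resolve into two. The greedy
procedure is this package's own construction — fragment-locus definitions
in the literature vary and are rarely algorithmic — and is exercised
end-to-end by the simulator's jitter option.

miRNA-class parents are exempt: catalog entries for miRNAs are the mature
sequences themselves, so any covered miRNA parent becomes a single
whole-parent feature.

### Quantification

An alignment counts toward a called locus when its start lies within δ nt
of the locus start and the alignment lies inside the locus span extended by
δ on either side (the extension keeps cluster-edge reads admitted by the
start window from being rejected by strict containment); whole-parent
miRNA features take every alignment to their parent. A read matching n > 1
features (e.g. identical tRNA isodecoders kept as separate records)
contributes 1 to each under the default `all` policy — per-alignment
counting — or 1/n under the `fractional` policy, which conserves the total
assigned-read count exactly and is the right choice when column sums
matter.

RPM uses denominator = reads surviving the 16–32 nt length filter, per
library: the closest computable analogue of "per million sequenced
small-RNA reads" that needs no external annotation. An aligned-reads
denominator is available by flag; it rescales all RPM in a library by a
common factor and therefore never changes up/down/unchanged calls, only
the absolute threshold's bite.

### Classification and class summaries

Per KO contrast, features are kept when WT mean RPM or that KO's mean RPM
reaches 20 (so each contrast has its own expressed set), and classified by
the KO/WT ratio with inclusive boundaries: up at ≥ 1.5, down at ≤ 0.5,
unchanged between. A feature with WT mean 0 but expressed in KO is called
up (its ratio exceeds any finite threshold). The fold-change rule *is* the
per-feature call; no replicate-based test gates it. An optional Welch test
on log2(RPM+1) across replicates can be switched on purely as a
supplementary column.

Class-level significance uses Fisher's exact test, two-sided, on the 2×2
table [decreased, not-decreased] × [class, miRNA] (and symmetrically for
increased), chosen as the minimal-assumption exact test for comparing
proportions between classes. The p-value is computed by exhaustive
enumeration of the hypergeometric support in exact integer arithmetic:
all candidate tables share the denominator C(N, c₁), so "probability ≤
observed" reduces to integer comparisons and the result is exact to float
conversion. `scipy.stats.fisher_exact` serves as an independent
cross-check in the tests, never as the implementation.

Interpretation caveat: under fixed-depth RPM, depleting the dominant miRNA
pool necessarily inflates every other class's share of reads, so
"increased" calls for fragment classes in miRNA-machinery KOs partly
reflect compositional renormalisation rather than absolute copy-number
increases. The pipeline reports the relative quantities; absolute claims
need spike-ins.

## Synthetic data

The simulator emulates the knockout-study design: random parent sequences
per class (defaults miRNA 22 nt, tRNA 75, yRNA 100, rRNA 1500 — capped far
below the real 45S since parent length never enters per-read computation —
snRNA 150, snoRNA 120); one fragment window per fragment-class parent
(length uniform in 16–32 nt); WT expected RPM log-normal with median 100
(σ = 1 natural-log); per-KO fold changes class-patterned (miRNA 0.2,
fragment classes 2.0) with a 10% unchanged fraction per class; 3 replicate
libraries per condition at 2 million reads; optional per-base substitution
errors and ±2 nt start jitter; optional exact-duplicate parents to
exercise multi-mapping.

Each library is one multinomial draw at fixed depth with probability
proportional to WT RPM × fold change, plus a background pool of random
16–32-mers whose constant weight is 10⁶ − Σ(WT RPM). The background makes
the library realistic (most reads are not from the designed loci) and
pins the WT expected RPM of each locus to its design value exactly; KO
expected RPM deviates from WT RPM × fold change only by the compositional
renormalisation of fixed-depth sampling (< 2% at the default design), the
same effect real libraries show. Per-locus counts are marginally binomial.
Sequencing errors are substitutions only — the matcher is ungapped, so
indels could only deflate retention without changing which reads match —
giving the closed-form retention law (1−ε)^L that the tests verify.

What the simulator does **not** emulate: 5′/3′ raggedness beyond uniform
start jitter, adapter-ligation and GC biases, RNA modifications that block
reverse transcription, realistic quality scores, and non-uniform genomic
background. Passing recovery tests therefore demonstrate correctness of
the pipeline's computations under the stated model, not robustness to
those real-data artefacts.

Determinism: every random stream derives from the design seed through
fixed integer key tuples (catalog, locus design, and each
(condition, replicate) library), so a rerun with the same design is
byte-identical file for file.

## Parameter defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| read length window | 16–32 | nt | miRNA-sized fragments; defines an accepted match |
| index seed length | 16 | nt | minimum accepted read; speed-only choice |
| strand policy | sense | — | fragments are sense-derived |
| locus δ | 2 | nt | tolerates slight 5′ raggedness without fusing nearby fragments |
| locus min_reads | 10 | pooled reads | suppresses stray-placement loci |
| multimap policy | all | — | per-alignment counting; `fractional` for conservation |
| RPM denominator | length-filtered reads | reads | computable proxy for sequenced small-RNA reads |
| expression filter | 20 | mean RPM | excludes noise-level features |
| up / down ratio | 1.5 / 0.5 | — | inclusive breakpoints of the three-way call |

## Numerical and design choices

- Coordinates are 0-based half-open everywhere, including locus names
  (`parent:start-end`) and BED; only SAM export is 1-based.
- Locus-calling ties (equal start counts) resolve to the leftmost start;
  all outputs are sorted (parent id, then start), so every table is
  byte-reproducible.
- The exact test uses integer arithmetic; the enumeration contract is
  "sum of all tables with probability ≤ observed", with exact tie
  handling (no floating-point tie tolerance is needed).
- Degenerate inputs: empty catalog, empty locus set, zero RPM denominator
  and zero-margin tables are errors or warned p = 1, never silent zeros.
- The pipeline config is a single YAML file; thresholds are flat keys and
  the two unavoidable structured entries (class → FASTA, condition →
  libraries) are shallow mappings. The full config is validated before any
  compute.
- Identical sequences under different ids are kept as separate records by
  default (isodecoders multi-map; the counting policy handles them);
  `collapse_duplicates` exists for users who prefer one representative.
- The test suite and the acceptance script run the full-scale design
  (200 loci, 6 × 2M reads) for end-to-end recovery and the scaled-down
  designs elsewhere; the sizes are stated in each test and were chosen as
  the smallest that make the measured proportions statistically stable.

## Known limitations

- Full-read matching discards reads with untemplated 3′ additions (e.g.
  CCA-tailed tRNA reads if the catalog lacks the tail) and all reads with
  ≥ 1 sequencing error; retention follows (1−ε)^L, so long fragments are
  penalised more.
- The locus caller assumes fragments have a dominant 5′ start; diffuse
  degradation ladders produce merged or dropped loci by design.
- Per-feature calls carry no replicate-level error control; the
  classification is a descriptive fold-change rule, and class-level
  inference is where significance is assessed.
- RPM is compositional (see caveat above); cross-condition comparisons
  inherit that property.
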