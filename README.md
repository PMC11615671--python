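# sncfrag

Quantification of miRNA-sized fragments excised from longer noncoding RNAs
(tRNA-derived tsRNAs, yRNA-derived ysRNAs, rRNA-derived rsRNAs, snoRNA- and
snRNA-derived fragments) in small RNA-seq libraries, and classification of
their expression changes in knockouts (KO) of the canonical miRNA
biogenesis machinery (DROSHA, DGCR8, XPO5, DICER) versus wild type (WT).

The package is for transcriptomics researchers who have adapter-trimmed
small RNA-seq libraries and want to ask: do ncRNA fragments depend on the
miRNA processing enzymes the way miRNAs do?

## Method

1. **Reference.** Class-labelled parent ncRNAs (mature miRNAs plus
   full-length tRNAs, rRNAs, yRNAs, snoRNAs, snRNAs) are merged into one
   catalog; one class per input FASTA.
2. **Exact matching.** Each read *r* is accepted on parent *P* at offset
   *i* iff `P[i : i+|r|] == r` with `16 ≤ |r| ≤ 32` — full-read, ungapped,
   100% identity. A k-mer seed index (seed = 16 nt) makes this exhaustive
   and fast; all multi-mapped placements are kept.
3. **Fragment loci.** Read 5′ starts, pooled over *all* libraries, are
   clustered greedily (most frequent start first, window ±δ, default
   δ = 2 nt, ≥ 10 pooled reads); each cluster becomes a locus spanning its
   clustered starts to its furthest 3′ end. miRNA entries are themselves
   the feature.
4. **RPM.** For feature *f* in library *ℓ*:
   `RPM[f,ℓ] = count[f,ℓ] / N_ℓ × 10⁶`, with *N_ℓ* the reads surviving the
   16–32 nt filter.
5. **Classification.** With condition means `wt = mean RPM in WT`,
   `ko = mean RPM in KO`, a feature is kept when `max(wt, ko) ≥ 20` RPM and
   called **up** if `ko/wt ≥ 1.5`, **down** if `ko/wt ≤ 0.5`, otherwise
   **unchanged** (boundaries inclusive).
6. **Class summaries.** Percent up/down/unchanged per ncRNA class, with a
   two-sided Fisher exact test (exact integer enumeration) of each class's
   decreased-vs-not split against the miRNA class.

A synthetic-data module simulates the whole design — parents, fragment
windows, replicate WT/KO libraries with known fold changes and substitution
errors — so every stage is testable without downloading data.

## Worked example

Simulate a knockout experiment at the study conditions (200 loci over four
classes, WT median 100 RPM, miRNA ×0.2 and fragment classes ×2 in the KO,
10% of loci unchanged, 3 replicates/condition, 2M reads/library) and run
the pipeline:

```bash
python analysis/01_simulate.py
python analysis/02_run_pipeline.py
python analysis/03_evaluate.py
```

which prints (seed 1):

```
                     metric      value   n
locus_boundary_recovery_pct 100.000000 200
classification_accuracy_pct 100.000000 105
  wt_rpm_mean_rel_error_pct   2.378969 105
ko_name class_label  n_expressed  pct_up  pct_down  pct_unchanged  p_down_vs_mirna
     KO       miRNA           48  0.0000   89.5833        10.4167     1.000000e+00
     KO        rRNA           49 89.7959    0.0000        10.2041     2.482580e-22
     KO        tRNA           49 89.7959    0.0000        10.2041     2.482580e-22
     KO        yRNA           50 90.0000    0.0000        10.0000     1.393280e-22
```

Every called locus boundary lands within ±2 nt of its true window; every
well-expressed feature (design WT ≥ 100 RPM) is classified to its designed
direction; the class summary shows the knockout signature — miRNAs
majority-decreased, fragment classes majority-increased, each fragment
class differing from miRNAs at p ≪ 10⁻⁴ (the ~10% "unchanged" rows are the
loci designed with fold change 1).

The same run is available as one shell command over real or simulated data:

```bash
sncfrag run --config sim/config.yaml --out out/
```

with subcommands `build-ref`, `align`, `quantify`, `compare`, `simulate`
and `report` exposing the individual stages.

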