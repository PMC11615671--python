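#!/usr/bin/env python
"""Score the pipeline output against the simulation's ground truth.

Reports fragment-locus boundary recovery, fold-change classification
accuracy, WT RPM calibration, and the per-class expression pattern with its
exact-test significance vs miRNAs; writes results/recovery_metrics.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "analysis" / "sim"
OUT_DIR = ROOT / "scratch" / "analysis" / "out"
RESULTS = ROOT / "results"


def main() -> None:
    truth = pd.read_csv(SIM_DIR / "truth_loci.tsv", sep="\t")
    pooled = (
        pd.read_csv(SIM_DIR / "truth_counts.tsv", sep="\t", index_col=0)
        .drop(index="background").sum(axis=1)
    )
    called = pd.read_csv(
        OUT_DIR / "loci.bed", sep="\t", header=None,
        names=["parent_id", "start", "end", "locus_id", "score", "strand"],
    )
    comparison = pd.read_csv(OUT_DIR / "comparison_KO.tsv", sep="\t", index_col=0)

    by_parent = dict(tuple(called.groupby("parent_id")))
    wt_rows = truth[truth.condition == "WT"].set_index("locus_id")
    recovered = total = 0
    for locus_id, row in wt_rows.iterrows():
        if pooled.get(locus_id, 0) < 50:
            continue
        total += 1
        cand = by_parent.get(row.parent_id)
        if cand is not None and bool(
            (((cand.start - row.start).abs() <= 2)
             & ((cand.end - row.end).abs() <= 2)).any()
        ):
            recovered += 1

    ko_rows = truth[truth.condition == "KO"].set_index("locus_id")
    merged = comparison.join(ko_rows[["wt_rpm", "fold_change"]], how="inner")
    strong = merged[merged.wt_rpm >= 100]
    expected = np.where(
        strong.fold_change <= 0.5, "down",
        np.where(strong.fold_change >= 1.5, "up", "unchanged"),
    )
    accuracy = float((strong.category == expected).mean())

    rpm = pd.read_csv(OUT_DIR / "expression_rpm.tsv", sep="\t",
                      index_col="locus_id")
    wt_cols = [c for c in rpm.columns if c.startswith("WT_rep")]
    est = rpm[wt_cols].mean(axis=1)
    hi = wt_rows[wt_rows.wt_rpm >= 100]
    common = hi.index.intersection(est.index)
    calib = float(((est.loc[common] - hi.loc[common, "wt_rpm"]).abs()
                   / hi.loc[common, "wt_rpm"]).mean())

    metrics = pd.DataFrame(
        [
            ("locus_boundary_recovery_pct", 100 * recovered / total, total),
            ("classification_accuracy_pct", 100 * accuracy, len(strong)),
            ("wt_rpm_mean_rel_error_pct", 100 * calib, len(common)),
        ],
        columns=["metric", "value", "n"],
    )
    RESULTS.mkdir(exist_ok=True)
    metrics.to_csv(RESULTS / "recovery_metrics.tsv", sep="\t", index=False,
                   float_format="%.4g")
    print(metrics.to_string(index=False))
    summary = pd.read_csv(OUT_DIR / "class_summary.tsv", sep="\t")
    print(summary[["ko_name", "class_label", "n_expressed", "pct_up",
                   "pct_down", "pct_unchanged", "p_down_vs_mirna"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
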