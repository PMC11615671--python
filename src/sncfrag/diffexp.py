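"""KO-vs-WT comparison: expression filter, fold-change classification, class summaries.

Per feature, condition means of RPM are compared between a knockout (KO) and
wild type (WT).  A feature is "expressed" for a contrast when its mean RPM
reaches the expression threshold (default 20 RPM) in WT or in that KO — so
each KO contrast has its own expressed set.  Expressed features are
classified by the KO/WT ratio: up when KO is at least 150% of WT, down when
at most 50%, unchanged when within 50% of WT (both boundaries inclusive).
No replicate-based per-feature test is applied by default — the fold-change
rule is the per-feature call; an optional Welch test on log RPM across
replicates is available for users who want one.

Class-level summaries count up/down/unchanged per ncRNA class and attach a
two-sided exact (Fisher) p-value comparing each class's
decreased-vs-not-decreased split against the miRNA class (and, symmetrically,
the increased-vs-not split).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class AnalysisConfig:
    """Tunable thresholds and policies for the whole pipeline.

    Defaults are the study conditions: 16–32 nt accepted reads, ≥20 RPM
    condition-mean expression filter, 150%/50% up/down breakpoints.
    """

    expression_threshold_rpm: float = 20.0
    up_ratio: float = 1.5
    down_ratio: float = 0.5
    read_len_min: int = 16
    read_len_max: int = 32
    loci_delta: int = 2
    min_reads: int = 10
    strand_policy: str = "sense"          # "sense" | "both"
    multimap_policy: str = "all"          # "all" | "fractional"
    rpm_denominator: str = "length_filtered"  # "length_filtered" | "aligned"
    replicate_test: bool = False          # optional Welch test on log RPM
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.down_ratio < 1 < self.up_ratio):
            raise ValueError(
                f"need 0 < down_ratio < 1 < up_ratio, got "
                f"{self.down_ratio} / {self.up_ratio}"
            )
        if self.read_len_min > self.read_len_max:
            raise ValueError("read_len_min > read_len_max")
        # accepted fragments are miRNA-sized by definition; the window may be
        # narrowed but not widened beyond 16-32 nt
        if self.read_len_min < 16 or self.read_len_max > 32:
            raise ValueError("read length window must lie within [16, 32]")
        if self.expression_threshold_rpm < 0:
            raise ValueError("expression threshold must be >= 0")
        if self.loci_delta < 0:
            raise ValueError("loci_delta must be >= 0")
        if self.strand_policy not in ("sense", "both"):
            raise ValueError(f"bad strand policy {self.strand_policy!r}")
        if self.multimap_policy not in ("all", "fractional"):
            raise ValueError(f"bad multimap policy {self.multimap_policy!r}")
        if self.rpm_denominator not in ("length_filtered", "aligned"):
            raise ValueError(f"bad rpm denominator {self.rpm_denominator!r}")


UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
CATEGORIES = (UP, DOWN, UNCHANGED)


@dataclass(frozen=True, slots=True)
class ConditionComparison:
    """Per-feature WT/KO means, ratio and category for one contrast."""

    locus_id: str
    class_label: str
    wt_mean_rpm: float
    ko_mean_rpm: float
    ratio: float            # KO / WT; inf when WT mean is 0
    expressed: bool
    category: str | None    # one of CATEGORIES when expressed, else None


def condition_means(
    matrix: ExpressionMatrix, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Arithmetic mean RPM per feature per condition.

    ``groups`` maps condition name → library ids; every library must belong
    to exactly one condition and each condition must be non-empty.
    """
    known = set(matrix.libraries)
    seen: set[str] = set()
    for cond, libs in groups.items():
        if not libs:
            raise ValueError(f"condition {cond!r} has no libraries")
        for lib in libs:
            if lib not in known:
                raise ValueError(f"unknown library id {lib!r} in condition {cond!r}")
            if lib in seen:
                raise ValueError(f"library {lib!r} assigned to several conditions")
            seen.add(lib)
    return pd.DataFrame(
        {cond: matrix.rpm[list(libs)].mean(axis=1) for cond, libs in groups.items()}
    )


def classify(
    wt_mean: float, ko_mean: float, config: AnalysisConfig | None = None
) -> tuple[bool, str | None, float]:
    """Classify one feature for one contrast.

    Returns (expressed, category, ratio).  Thresholds are inclusive: a ratio
    of exactly 1.5 is up, exactly 0.5 is down, and a mean of exactly the
    expression threshold is retained.  A feature with WT mean 0 that is
    expressed in the KO is called up (the ratio is unbounded above any
    up threshold); the ratio is reported as inf.
    """
    if config is None:
        config = AnalysisConfig()
    if wt_mean < 0 or ko_mean < 0:
        raise ValueError("mean RPM must be non-negative")
    expressed = max(wt_mean, ko_mean) >= config.expression_threshold_rpm
    if wt_mean == 0:
        ratio = math.inf if ko_mean > 0 else math.nan
    else:
        ratio = ko_mean / wt_mean
    if not expressed:
        return False, None, ratio
    if wt_mean == 0:
        return True, UP, ratio
    if ratio >= config.up_ratio:
        return True, UP, ratio
    if ratio <= config.down_ratio:
        return True, DOWN, ratio
    return True, UNCHANGED, ratio


def compare_conditions(
    matrix: ExpressionMatrix,
    groups: Mapping[str, Sequence[str]],
    wt: str,
    ko: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Full per-feature comparison table for one KO-vs-WT contrast.

    Columns: class_label, wt_mean_rpm, ko_mean_rpm, ratio, expressed,
    category (empty for non-expressed features).  With
    ``config.replicate_test`` a ``p_replicate`` column adds a Welch t-test
    on log2(RPM + 1) across replicate libraries (purely supplementary; the
    category never depends on it).
    """
    if config is None:
        config = AnalysisConfig()
    for cond in (wt, ko):
        if cond not in groups:
            raise ValueError(f"condition {cond!r} missing from groups")
    means = condition_means(matrix, {wt: groups[wt], ko: groups[ko]})
    rows = []
    for locus_id in means.index:
        wt_mean = float(means.at[locus_id, wt])
        ko_mean = float(means.at[locus_id, ko])
        expressed, category, ratio = classify(wt_mean, ko_mean, config)
        rows.append(
            (
                locus_id,
                matrix.feature_meta.at[locus_id, "class_label"],
                wt_mean,
                ko_mean,
                ratio,
                expressed,
                category if category is not None else "",
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "locus_id", "class_label", "wt_mean_rpm", "ko_mean_rpm",
            "ratio", "expressed", "category",
        ],
    ).set_index("locus_id")
    if config.replicate_test:
        wt_log = np.log2(matrix.rpm[list(groups[wt])] + 1.0)
        ko_log = np.log2(matrix.rpm[list(groups[ko])] + 1.0)
        res = stats.ttest_ind(
            ko_log, wt_log, axis=1, equal_var=False, nan_policy="omit"
        )
        out["p_replicate"] = np.asarray(res.pvalue)
    return out


def exact_two_sided_test(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact test on a 2×2 table, by exact enumeration.

    With margins fixed, the p-value is the total hypergeometric probability
    of every table whose probability does not exceed the observed table's.
    Computed in exact integer arithmetic (probabilities share the common
    denominator C(N, c1), so only integer numerators are compared), then
    returned as a float.  A zero margin makes the table degenerate; p = 1 is
    returned with a warning.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        logger.warning("degenerate 2x2 table %s: zero margin, p = 1", table)
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    num = sum(
        w
        for k in range(lo, hi + 1)
        if (w := math.comb(r1, k) * math.comb(r2, c1 - k)) <= obs
    )
    return float(Fraction(num, math.comb(n, c1)))


def summarize_classes(
    comparisons: pd.DataFrame,
    ko_name: str,
    *,
    reference_class: str = "miRNA",
) -> pd.DataFrame:
    """Per-class category counts, percentages and exact tests vs miRNAs.

    For each non-reference class the 2×2 table [down, not-down] × [class,
    reference] is tested two-sided (``p_down_vs_mirna``); the symmetric
    increased-vs-not test is reported alongside (``p_up_vs_mirna``).  The
    reference class rows carry p = 1 by convention.  Only expressed features
    enter any count.
    """
    expressed = comparisons[comparisons["expressed"]]
    if expressed.empty:
        raise ValueError(f"no expressed features in contrast {ko_name!r}")
    rows = []
    by_class = {
        label: sub for label, sub in expressed.groupby("class_label", sort=True)
    }
    ref = by_class.get(reference_class)
    if ref is None:
        logger.warning(
            "class %r absent from contrast %s: exact tests vs it omitted",
            reference_class, ko_name,
        )
    for label, sub in by_class.items():
        n = len(sub)
        n_up = int((sub["category"] == UP).sum())
        n_down = int((sub["category"] == DOWN).sum())
        n_unchanged = n - n_up - n_down
        if ref is None:
            p_down = p_up = math.nan
        elif label == reference_class:
            p_down = p_up = 1.0
        else:
            ref_down = int((ref["category"] == DOWN).sum())
            ref_up = int((ref["category"] == UP).sum())
            p_down = exact_two_sided_test(
                [[n_down, n - n_down], [ref_down, len(ref) - ref_down]]
            )
            p_up = exact_two_sided_test(
                [[n_up, n - n_up], [ref_up, len(ref) - ref_up]]
            )
        rows.append(
            (
                ko_name, label, n, n_up, n_down, n_unchanged,
                100.0 * n_up / n, 100.0 * n_down / n, 100.0 * n_unchanged / n,
                p_down, p_up,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ko_name", "class_label", "n_expressed", "n_up", "n_down",
            "n_unchanged", "pct_up", "pct_down", "pct_unchanged",
            "p_down_vs_mirna", "p_up_vs_mirna",
        ],
    )
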