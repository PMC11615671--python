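"""Coverage profiles, fragment-locus calling, and RPM quantification.

The unit of quantification is the fragment locus: a contiguous window on a
parent ncRNA defined by clustered read 5' starts, pooled across all
libraries of an experiment so WT and KO conditions share one feature set.
Mature-miRNA reference entries are themselves the feature (the whole
parent); fragment classes (tRNA, rRNA, yRNA, snoRNA, snRNA) get loci called
from the pooled start profile.

Expression is reported as reads per million (RPM): the per-library feature
count scaled by that library's reads surviving the 16–32 nt length filter
(an aligned-reads denominator is available by flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .matcher import Alignment, LibraryAlignmentSummary
from .reference import ReferenceCatalog

logger = logging.getLogger(__name__)

WHOLE_PARENT = "whole_parent"
CALLED_LOCUS = "called_locus"

MultimapPolicy = Literal["all", "fractional"]
Denominator = Literal["length_filtered", "aligned"]


@dataclass(slots=True)
class CoverageProfile:
    """Per-parent alignment profile.

    ``start_counts[i]`` is the number of alignments starting at position i;
    ``depth[i]`` the number of alignments covering i.  ``max_end_at_start[i]``
    records the furthest 3' end among alignments starting at i (0 where
    none), which locus calling needs to span a cluster.
    """

    parent_id: str
    length: int
    start_counts: np.ndarray
    depth: np.ndarray
    max_end_at_start: np.ndarray

    @property
    def n_alignments(self) -> int:
        return int(self.start_counts.sum())

    def validate(self) -> None:
        if int(self.depth.max(initial=0)) > self.n_alignments:
            raise ValueError(f"corrupt profile for {self.parent_id}")


@dataclass(frozen=True, slots=True)
class FragmentLocus:
    """A called fragment window on a parent; the feature unit.

    Coordinates are 0-based half-open; ``locus_id`` is
    ``"parent_id:start-end"`` in those coordinates.
    """

    parent_id: str
    class_label: str
    start: int
    end: int
    feature_kind: str = CALLED_LOCUS
    pooled_reads: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad locus bounds {self.start}-{self.end}")
        if self.feature_kind not in (WHOLE_PARENT, CALLED_LOCUS):
            raise ValueError(f"bad feature kind {self.feature_kind!r}")

    @property
    def locus_id(self) -> str:
        return f"{self.parent_id}:{self.start}-{self.end}"


def build_coverage(
    summary: LibraryAlignmentSummary | Iterable[Alignment],
    catalog: ReferenceCatalog,
) -> dict[str, CoverageProfile]:
    """Per-parent coverage profiles for one alignment set.

    Only parents with at least one alignment get a profile.  An alignment
    outside its parent's bounds indicates corrupt input and raises.
    """
    alignments = (
        summary.alignments
        if isinstance(summary, LibraryAlignmentSummary)
        else summary
    )
    profiles: dict[str, CoverageProfile] = {}
    for a in alignments:
        prof = profiles.get(a.parent_id)
        if prof is None:
            rec = catalog.get(a.parent_id)
            if rec is None:
                raise ValueError(f"alignment to unknown parent {a.parent_id!r}")
            n = len(rec)
            prof = CoverageProfile(
                parent_id=a.parent_id,
                length=n,
                start_counts=np.zeros(n, dtype=np.int64),
                depth=np.zeros(n + 1, dtype=np.int64),  # diff array; trimmed below
                max_end_at_start=np.zeros(n, dtype=np.int64),
            )
            profiles[a.parent_id] = prof
        if a.start < 0 or a.end > prof.length:
            raise ValueError(
                f"alignment {a.read_id} at {a.parent_id}:{a.start}-{a.end} "
                f"outside parent bounds (corrupt input)"
            )
        prof.start_counts[a.start] += 1
        prof.depth[a.start] += 1
        prof.depth[a.end] -= 1
        if a.end > prof.max_end_at_start[a.start]:
            prof.max_end_at_start[a.start] = a.end
    for prof in profiles.values():
        prof.depth = np.cumsum(prof.depth[:-1])
        prof.validate()
    return profiles


def merge_profiles(
    parts: Sequence[dict[str, CoverageProfile]]
) -> dict[str, CoverageProfile]:
    """Pool per-library profiles; counts add, cluster spans take the max."""
    pooled: dict[str, CoverageProfile] = {}
    for part in parts:
        for pid, prof in part.items():
            tgt = pooled.get(pid)
            if tgt is None:
                pooled[pid] = CoverageProfile(
                    parent_id=pid,
                    length=prof.length,
                    start_counts=prof.start_counts.copy(),
                    depth=prof.depth.copy(),
                    max_end_at_start=prof.max_end_at_start.copy(),
                )
            else:
                tgt.start_counts += prof.start_counts
                tgt.depth += prof.depth
                np.maximum(
                    tgt.max_end_at_start, prof.max_end_at_start,
                    out=tgt.max_end_at_start,
                )
    return pooled


def pooled_coverage(
    summaries: Sequence[LibraryAlignmentSummary], catalog: ReferenceCatalog
) -> dict[str, CoverageProfile]:
    """Coverage pooled across all libraries of the experiment."""
    return merge_profiles([build_coverage(s, catalog) for s in summaries])


def _cluster_starts(
    prof: CoverageProfile, delta: int, min_reads: int
) -> list[tuple[int, int, int]]:
    """Greedy 5'-start clustering; returns (start, end, pooled_reads) spans.

    Seeds are taken at the most frequent remaining start (ties to the
    leftmost); starts within ``delta`` nt of the seed join its cluster.
    Clusters below ``min_reads`` pooled reads are discarded; surviving spans
    run from the leftmost clustered start to the furthest clustered end.
    """
    counts = prof.start_counts.copy()
    spans: list[tuple[int, int, int]] = []
    while True:
        seed = int(counts.argmax())
        if counts[seed] == 0:
            break
        lo = max(0, seed - delta)
        hi = min(prof.length, seed + delta + 1)
        members = np.nonzero(counts[lo:hi])[0] + lo
        total = int(counts[lo:hi].sum())
        start = int(members.min())
        end = int(prof.max_end_at_start[members].max())
        counts[lo:hi] = 0
        if total >= min_reads:
            spans.append((start, end, total))
    spans.sort()
    # merge overlaps left over from interleaved clusters
    merged: list[list[int]] = []
    for s, e, n in spans:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] += n
        else:
            merged.append([s, e, n])
    return [(s, e, n) for s, e, n in merged]


def call_loci(
    profiles: dict[str, CoverageProfile],
    catalog: ReferenceCatalog,
    *,
    delta: int = 2,
    min_reads: int = 10,
) -> list[FragmentLocus]:
    """Call fragment loci from pooled coverage.

    Parents of class miRNA always yield a single whole-parent feature when
    they carry any reads (the reference entries are the mature miRNAs).
    Other classes get greedy start-cluster loci (see :func:`_cluster_starts`)
    with defaults chosen so one sharply processed fragment population yields
    exactly one locus.  Loci are returned sorted by parent id then start and
    are non-overlapping within a parent.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    loci: list[FragmentLocus] = []
    for pid in sorted(profiles):
        prof = profiles[pid]
        if prof.n_alignments == 0:
            continue
        label = catalog.class_of(pid)
        if label == "miRNA":
            loci.append(
                FragmentLocus(
                    parent_id=pid,
                    class_label=label,
                    start=0,
                    end=prof.length,
                    feature_kind=WHOLE_PARENT,
                    pooled_reads=prof.n_alignments,
                )
            )
            continue
        for s, e, n in _cluster_starts(prof, delta, min_reads):
            loci.append(
                FragmentLocus(
                    parent_id=pid,
                    class_label=label,
                    start=s,
                    end=e,
                    feature_kind=CALLED_LOCUS,
                    pooled_reads=n,
                )
            )
    logger.info("called %d loci on %d covered parents", len(loci), len(profiles))
    return loci


@dataclass(slots=True)
class ExpressionMatrix:
    """Feature × library counts and RPM.

    ``counts`` holds (possibly fractional, under the fractional multi-map
    policy) per-locus read counts; ``rpm`` is counts / denominator × 1e6.
    ``feature_meta`` carries parent, class, window and kind per locus, and
    ``assigned_reads`` the per-library number of reads with ≥1 locus
    assignment (the fractional-policy column sums).
    """

    counts: pd.DataFrame
    rpm: pd.DataFrame
    feature_meta: pd.DataFrame
    denominators: pd.Series
    assigned_reads: pd.Series
    conditions: dict[str, str] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def write(self, outdir: str | Path, prefix: str = "expression") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = self.feature_meta
        counts = pd.concat([meta, self.counts], axis=1)
        rpm = pd.concat([meta, self.rpm], axis=1)
        counts.to_csv(outdir / f"{prefix}_counts.tsv", sep="\t", float_format="%.6g")
        rpm.to_csv(outdir / f"{prefix}_rpm.tsv", sep="\t", float_format="%.6g")


def quantify(
    summaries: Sequence[LibraryAlignmentSummary],
    loci: Sequence[FragmentLocus],
    *,
    delta: int = 2,
    policy: MultimapPolicy = "all",
    denominator: Denominator = "length_filtered",
    conditions: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Count alignments into the fixed locus set and compute RPM.

    An alignment is assigned to a called locus when its 5' start lies within
    ``delta`` nt of the locus start and the alignment sits inside the locus
    span extended by ``delta`` on either side; whole-parent features take
    every alignment to their parent.  A read matching n > 1 loci contributes
    1 to each under the default ``all`` policy (per-alignment counting) or
    1/n to each under ``fractional``, which conserves total assigned reads.
    """
    if not loci:
        raise ValueError("no loci to quantify")
    locus_ids = [l.locus_id for l in loci]
    if len(set(locus_ids)) != len(locus_ids):
        raise ValueError("duplicate locus ids")
    by_parent: dict[str, list[tuple[int, FragmentLocus]]] = {}
    for j, locus in enumerate(loci):
        by_parent.setdefault(locus.parent_id, []).append((j, locus))

    n_feat = len(loci)
    lib_ids = [s.library_id for s in summaries]
    counts = np.zeros((n_feat, len(summaries)), dtype=float)
    assigned = np.zeros(len(summaries), dtype=np.int64)
    denoms = np.zeros(len(summaries), dtype=np.int64)

    for col, summary in enumerate(summaries):
        denom = (
            summary.length_filtered_reads
            if denominator == "length_filtered"
            else summary.aligned_reads
        )
        if denom <= 0:
            raise ValueError(
                f"library {summary.library_id}: zero RPM denominator "
                f"({denominator})"
            )
        denoms[col] = denom
        col_counts = counts[:, col]
        # alignments are grouped per read in input order
        read_id = None
        hits: list[int] = []
        def flush() -> None:
            nonlocal hits
            if not hits:
                return
            assigned[col] += 1
            w = 1.0 if policy == "all" else 1.0 / len(hits)
            for j in hits:
                col_counts[j] += w
            hits = []
        for a in summary.alignments:
            if a.read_id != read_id:
                flush()
                read_id = a.read_id
            cand = by_parent.get(a.parent_id)
            if not cand:
                continue
            for j, locus in cand:
                if locus.feature_kind == WHOLE_PARENT:
                    hits.append(j)
                elif (
                    locus.start - delta <= a.start <= locus.start + delta
                    and a.end <= locus.end + delta
                ):
                    hits.append(j)
        flush()

    counts_df = pd.DataFrame(counts, index=locus_ids, columns=lib_ids)
    counts_df.index.name = "locus_id"
    rpm = counts_df / denoms * 1e6
    meta = pd.DataFrame(
        {
            "parent_id": [l.parent_id for l in loci],
            "class_label": [l.class_label for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "feature_kind": [l.feature_kind for l in loci],
        },
        index=pd.Index(locus_ids, name="locus_id"),
    )
    return ExpressionMatrix(
        counts=counts_df,
        rpm=rpm,
        feature_meta=meta,
        denominators=pd.Series(denoms, index=lib_ids, name="denominator"),
        assigned_reads=pd.Series(assigned, index=lib_ids, name="assigned_reads"),
        conditions=dict(conditions or {}),
    )


def write_loci_bed(loci: Sequence[FragmentLocus], path: str | Path) -> None:
    """BED6 export (0-based half-open): parent, start, end, locus_id, pooled reads, +."""
    with open(path, "w") as out:
        for l in loci:
            out.write(
                f"{l.parent_id}\t{l.start}\t{l.end}\t{l.locus_id}\t"
                f"{l.pooled_reads}\t+\n"
            )
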