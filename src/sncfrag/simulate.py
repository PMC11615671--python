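"""Synthetic small RNA-seq experiments with known ground truth.

The generator emulates the data-generating situation of a
biogenesis-machinery knockout study: parent ncRNAs of several classes carry
fixed fragment windows of 16–32 nt; replicate WT and KO libraries sample
reads from those windows at designed expected RPM, with class-patterned
fold changes (miRNA features depleted in KO, fragment features enriched);
reads optionally suffer per-base substitution errors.

Library composition: each designed locus contributes reads in proportion to
its WT expected RPM times its condition fold change, and a constant-weight
background pool of random non-aligning sequences fills the remainder of the
library, so a locus designed at 100 RPM really sits near 100 RPM after
quantification.  With the background weight fixed at 1e6 minus the summed
WT locus RPM, WT expected RPM equals the design value exactly; KO values
shift only by the small compositional renormalisation that real
fixed-depth libraries also exhibit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .reference import NcRNARecord, ReferenceCatalog

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_PARENT_LENGTH = {
    "miRNA": 22,
    "tRNA": 75,
    "yRNA": 100,
    "rRNA": 1500,   # capped well below the real 45S; length never enters per-read math
    "snRNA": 150,
    "snoRNA": 120,
    "other": 200,
}

#: Class-typical KO fold changes: miRNAs depend on the knocked-out
#: machinery (depleted), fragment classes rise compositionally (enriched).
DEFAULT_KO_FOLD_CHANGES = {
    "miRNA": 0.2,
    "tRNA": 2.0,
    "yRNA": 2.0,
    "rRNA": 2.0,
    "snoRNA": 2.0,
    "snRNA": 2.0,
    "other": 1.0,
}


@dataclass(slots=True)
class SimDesign:
    """Design of a synthetic knockout experiment.

    Defaults give 200 fragment/miRNA loci over four classes, WT expected
    RPM log-normal with median 100 (sigma 1 on the natural-log scale),
    one KO condition with miRNA ×0.2 and fragment classes ×2, a 10%
    unchanged fraction per class, 3 replicate libraries per condition at
    2 million reads, and error-free reads.
    """

    n_parents: dict[str, int] = field(
        default_factory=lambda: {"miRNA": 50, "tRNA": 50, "yRNA": 50, "rRNA": 50}
    )
    parent_length: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PARENT_LENGTH)
    )
    loci_per_parent: int = 1
    fragment_len_min: int = 16
    fragment_len_max: int = 32
    wt_rpm_median: float = 100.0
    wt_rpm_sigma: float = 1.0
    ko_conditions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"KO": dict(DEFAULT_KO_FOLD_CHANGES)}
    )
    unchanged_fraction: float = 0.1
    depth: int = 2_000_000
    n_replicates: int = 3
    error_rate: float = 0.0
    start_jitter: int = 0
    duplicate_parents: int = 0
    wt_name: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (16 <= self.fragment_len_min <= self.fragment_len_max <= 32):
            raise ValueError("fragment lengths must lie in [16, 32]")
        if self.depth <= 0 or self.n_replicates <= 0:
            raise ValueError("depth and n_replicates must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.unchanged_fraction <= 1:
            raise ValueError("unchanged_fraction must be in [0, 1]")
        if self.start_jitter < 0:
            raise ValueError("start_jitter must be >= 0")
        for ko, fcs in self.ko_conditions.items():
            for label, fc in fcs.items():
                if fc <= 0:
                    raise ValueError(f"fold change for {label} in {ko} must be > 0")

    @property
    def conditions(self) -> list[str]:
        return [self.wt_name, *self.ko_conditions]


@dataclass(frozen=True, slots=True)
class TrueLocus:
    """Ground-truth fragment window with designed expression."""

    parent_id: str
    class_label: str
    start: int
    end: int
    wt_rpm: float
    fold_changes: tuple[tuple[str, float], ...]  # (ko_name, fc), hashable

    @property
    def locus_id(self) -> str:
        return f"{self.parent_id}:{self.start}-{self.end}"

    def fold_change(self, condition: str, wt_name: str = "WT") -> float:
        if condition == wt_name:
            return 1.0
        return dict(self.fold_changes)[condition]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def simulate_parents(design: SimDesign, rng: np.random.Generator) -> ReferenceCatalog:
    """Random parent ncRNAs per class, pairwise distinct.

    ``duplicate_parents`` appends that many exact-copy parents (distinct
    ids, ``*_dup`` suffix) of the first fragment-class parents, to exercise
    multi-mapping; they share their template's loci downstream.
    """
    records: list[NcRNARecord] = []
    seen: set[str] = set()
    for label, n in design.n_parents.items():
        length = design.parent_length.get(label, DEFAULT_PARENT_LENGTH["other"])
        for i in range(n):
            seq = _random_seq(rng, length)
            while seq in seen:  # pragma: no cover - astronomically rare
                seq = _random_seq(rng, length)
            seen.add(seq)
            records.append(
                NcRNARecord(
                    id=f"{label}_{i:04d}", class_label=label,
                    sequence=seq, source="simulated",
                )
            )
    if design.duplicate_parents:
        templates = [r for r in records if r.class_label != "miRNA"]
        if not templates:
            templates = records
        for j, rec in enumerate(templates[: design.duplicate_parents]):
            records.append(
                NcRNARecord(
                    id=f"{rec.id}_dup", class_label=rec.class_label,
                    sequence=rec.sequence, source="simulated-duplicate",
                )
            )
    return ReferenceCatalog(records=records)


def design_loci(
    design: SimDesign, catalog: ReferenceCatalog, rng: np.random.Generator
) -> list[TrueLocus]:
    """Place ground-truth fragment windows and draw their expression.

    miRNA parents are whole-parent features; fragment-class parents get
    ``loci_per_parent`` non-overlapping windows (uniform length in the
    designed range, separated by at least 5 nt so locus calling can resolve
    them).  WT RPM is log-normal (median ``wt_rpm_median``); a
    ``unchanged_fraction`` of loci per class keeps fold change 1 in every KO.
    Duplicate parents (``*_dup``) host copies of their template's windows.
    """
    loci: list[TrueLocus] = []
    by_class: dict[str, list[TrueLocus]] = {}
    template_windows: dict[str, list[tuple[int, int]]] = {}
    for rec in catalog.records:
        if rec.id.endswith("_dup") and rec.source == "simulated-duplicate":
            windows = template_windows.get(rec.id[: -len("_dup")], [])
        elif rec.class_label == "miRNA":
            windows = [(0, len(rec))]
        else:
            windows = []
            gap = 5
            attempts = 0
            while len(windows) < design.loci_per_parent and attempts < 200:
                attempts += 1
                frag_len = int(
                    rng.integers(design.fragment_len_min, design.fragment_len_max + 1)
                )
                if frag_len > len(rec):
                    continue
                start = int(rng.integers(0, len(rec) - frag_len + 1))
                end = start + frag_len
                if all(end + gap <= s or start >= e + gap for s, e in windows):
                    windows.append((start, end))
            windows.sort()
            template_windows[rec.id] = windows
        for start, end in windows:
            wt_rpm = float(
                design.wt_rpm_median * np.exp(design.wt_rpm_sigma * rng.normal())
            )
            locus = TrueLocus(
                parent_id=rec.id,
                class_label=rec.class_label,
                start=start,
                end=end,
                wt_rpm=wt_rpm,
                fold_changes=tuple(
                    (ko, fcs.get(rec.class_label, 1.0))
                    for ko, fcs in design.ko_conditions.items()
                ),
            )
            loci.append(locus)
            by_class.setdefault(rec.class_label, []).append(locus)

    # mark an unchanged fraction per class (fold change 1 in every KO)
    if design.unchanged_fraction > 0:
        unchanged_ids: set[str] = set()
        for label, group in by_class.items():
            k = int(round(design.unchanged_fraction * len(group)))
            if k:
                picks = rng.choice(len(group), size=k, replace=False)
                unchanged_ids.update(group[i].locus_id for i in picks)
        loci = [
            TrueLocus(
                parent_id=l.parent_id, class_label=l.class_label,
                start=l.start, end=l.end, wt_rpm=l.wt_rpm,
                fold_changes=tuple((ko, 1.0) for ko, _ in l.fold_changes),
            )
            if l.locus_id in unchanged_ids
            else l
            for l in loci
        ]

    total_wt = sum(l.wt_rpm for l in loci)
    if total_wt > 1e6:
        logger.warning(
            "designed WT RPM sums to %.0f > 1e6; library proportions will be "
            "renormalised and realized RPM will undershoot the design", total_wt,
        )
    return loci


def _mutate_reads(
    reads: list[str], error_rate: float, rng: np.random.Generator
) -> list[str]:
    """Independent per-base substitutions at ``error_rate``; never to the same base."""
    if error_rate <= 0 or not reads:
        return reads
    lengths = np.fromiter((len(r) for r in reads), dtype=np.int64, count=len(reads))
    n_err = rng.binomial(lengths, error_rate)
    hit = np.nonzero(n_err)[0]
    for i in hit:
        seq = bytearray(reads[i], "ascii")
        pos = rng.choice(lengths[i], size=n_err[i], replace=False)
        for p in pos:
            old = seq[p]
            choices = [b for b in b"ACGT" if b != old]
            seq[p] = choices[rng.integers(0, 3)]
        reads[i] = seq.decode()
    return reads


def simulate_library(
    design: SimDesign,
    catalog: ReferenceCatalog,
    loci: Sequence[TrueLocus],
    condition: str,
    replicate: int,
    out_fastq: str | Path,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Write one FASTQ library; return realized read counts per locus.

    Read counts per locus are multinomial at the designed depth with
    probability proportional to WT RPM × condition fold change; the
    background pool (key ``"background"`` in the returned counts) carries
    constant weight 1e6 − Σ WT RPM.  Each locus read is the exact window
    sequence, optionally start-jittered by ±``start_jitter`` nt, then hit by
    per-base substitutions at ``error_rate``.  Quality is a constant 'I';
    read ids encode library, locus and serial number.  Deterministic given
    (design, seed, condition, replicate).
    """
    if rng is None:
        cond_idx = design.conditions.index(condition)
        rng = np.random.default_rng([design.seed, 2, cond_idx, replicate])
    weights = np.array(
        [l.wt_rpm * l.fold_change(condition, design.wt_name) for l in loci]
    )
    background = max(0.0, 1e6 - sum(l.wt_rpm for l in loci))
    weights = np.append(weights, background)
    counts = rng.multinomial(design.depth, weights / weights.sum())
    lib_id = f"{condition}_rep{replicate}"

    realized: dict[str, int] = {}
    qual = {n: "I" * n for n in range(design.fragment_len_min, 33)}
    path = Path(out_fastq)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as out:
        buf: list[str] = []

        def emit(read_id: str, seq: str) -> None:
            buf.append(f"@{read_id}\n{seq}\n+\n{qual[len(seq)]}\n")
            if len(buf) >= 100_000:
                out.write("".join(buf))
                buf.clear()

        for locus, n in zip(loci, counts[:-1]):
            realized[locus.locus_id] = int(n)
            if n == 0:
                continue
            parent = catalog[locus.parent_id].sequence
            frag_len = locus.end - locus.start
            if design.start_jitter:
                j = design.start_jitter
                shifts = rng.integers(-j, j + 1, size=n)
                starts = np.clip(shifts + locus.start, 0, len(parent) - frag_len)
                uniq, per = np.unique(starts, return_counts=True)
                reads = []
                for s, m in zip(uniq, per):
                    reads += [parent[s : s + frag_len]] * int(m)
            else:
                reads = [parent[locus.start : locus.end]] * int(n)
            reads = _mutate_reads(reads, design.error_rate, rng)
            lid = locus.locus_id
            for serial, seq in enumerate(reads):
                emit(f"{lib_id}|{lid}|{serial}", seq)

        n_bg = int(counts[-1])
        realized["background"] = n_bg
        if n_bg:
            lens = rng.integers(
                design.fragment_len_min, design.fragment_len_max + 1, size=n_bg
            )
            chars = _BASES[rng.integers(0, 4, size=(n_bg, design.fragment_len_max))]
            blob = chars.tobytes()
            w = design.fragment_len_max
            for serial in range(n_bg):
                seq = blob[serial * w : serial * w + lens[serial]].decode()
                emit(f"{lib_id}|bg|{serial}", seq)
        out.write("".join(buf))
    logger.info("simulated %s: %d reads -> %s", lib_id, design.depth, path)
    return realized


def write_truth(
    design: SimDesign, loci: Sequence[TrueLocus], path: str | Path
) -> pd.DataFrame:
    """Ground-truth table: one row per locus × condition.

    ``expected_rpm`` is the design expectation (WT RPM × fold change); in WT
    it equals the expected realized RPM exactly, in KO up to the small
    compositional renormalisation of fixed-depth libraries.
    """
    rows = []
    for cond in design.conditions:
        for l in loci:
            fc = l.fold_change(cond, design.wt_name)
            rows.append(
                (
                    l.locus_id, l.parent_id, l.class_label, l.start, l.end,
                    cond, l.wt_rpm, fc, l.wt_rpm * fc,
                )
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "locus_id", "parent_id", "class_label", "start", "end",
            "condition", "wt_rpm", "fold_change", "expected_rpm",
        ],
    )
    truth.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return truth


def simulate_experiment(
    design: SimDesign, outdir: str | Path
) -> dict[str, object]:
    """Simulate the full experiment into a directory.

    Writes one reference FASTA per class, per-library FASTQ files, the
    ground-truth locus table, per-library realized counts, the design echo
    and a ready-to-run pipeline config.  Returns the catalog, true loci,
    library table and file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = simulate_parents(design, np.random.default_rng([design.seed, 0]))
    loci = design_loci(design, catalog, np.random.default_rng([design.seed, 1]))

    ref_paths: dict[str, Path] = {}
    for label, ids in catalog.class_index.items():
        p = outdir / f"ref_{label}.fasta"
        with open(p, "w") as out:
            for rid in ids:
                out.write(f">{rid}\n{catalog[rid].sequence}\n")
        ref_paths[label] = p

    lib_rows = []
    realized_cols: dict[str, dict[str, int]] = {}
    libraries: dict[str, list[str]] = {}
    for cond in design.conditions:
        libraries[cond] = []
        for rep in range(1, design.n_replicates + 1):
            lib_id = f"{cond}_rep{rep}"
            fq = outdir / f"{lib_id}.fastq"
            realized = simulate_library(design, catalog, loci, cond, rep, fq)
            realized_cols[lib_id] = realized
            libraries[cond].append(str(fq))
            lib_rows.append(
                (
                    lib_id, cond, rep, design.seed, design.depth,
                    realized["background"],
                )
            )

    truth = write_truth(design, loci, outdir / "truth_loci.tsv")
    lib_table = pd.DataFrame(
        lib_rows,
        columns=["library_id", "condition", "replicate", "seed",
                 "reads", "background_reads"],
    )
    lib_table.to_csv(outdir / "truth_libraries.tsv", sep="\t", index=False)
    counts = pd.DataFrame(realized_cols).fillna(0).astype(int)
    counts.index.name = "locus_id"
    counts.to_csv(outdir / "truth_counts.tsv", sep="\t")

    config = {
        "reference": {label: str(p) for label, p in ref_paths.items()},
        "libraries": libraries,
        "wt_condition": design.wt_name,
        "seed": design.seed,
    }
    with open(outdir / "config.yaml", "w") as out:
        yaml.safe_dump(config, out, sort_keys=True)
    with open(outdir / "design.yaml", "w") as out:
        yaml.safe_dump(design_to_dict(design), out, sort_keys=True)

    return {
        "catalog": catalog,
        "loci": loci,
        "truth": truth,
        "libraries": libraries,
        "library_table": lib_table,
        "realized_counts": counts,
        "config_path": outdir / "config.yaml",
        "ref_paths": ref_paths,
    }


def design_to_dict(design: SimDesign) -> dict:
    return {
        "n_parents": dict(design.n_parents),
        "parent_length": dict(design.parent_length),
        "loci_per_parent": design.loci_per_parent,
        "fragment_len_min": design.fragment_len_min,
        "fragment_len_max": design.fragment_len_max,
        "wt_rpm_median": design.wt_rpm_median,
        "wt_rpm_sigma": design.wt_rpm_sigma,
        "ko_conditions": {k: dict(v) for k, v in design.ko_conditions.items()},
        "unchanged_fraction": design.unchanged_fraction,
        "depth": design.depth,
        "n_replicates": design.n_replicates,
        "error_rate": design.error_rate,
        "start_jitter": design.start_jitter,
        "duplicate_parents": design.duplicate_parents,
        "wt_name": design.wt_name,
        "seed": design.seed,
    }


def design_from_dict(data: Mapping) -> SimDesign:
    return SimDesign(**dict(data))
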