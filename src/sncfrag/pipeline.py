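"""End-to-end orchestration: reference → align → quantify → compare → report.

A run is driven by one YAML config file::

    reference:             # class label -> FASTA path (one class per file)
      miRNA: ref_miRNA.fasta
      tRNA:  ref_tRNA.fasta
    libraries:             # condition -> list of FASTQ/FASTA files
      WT:  [WT_rep1.fastq, WT_rep2.fastq]
      KO:  [KO_rep1.fastq, KO_rep2.fastq]
    wt_condition: WT
    expression_threshold_rpm: 20    # all remaining keys are flat AnalysisConfig
    up_ratio: 1.5                   # fields and optional, defaulting to the
    down_ratio: 0.5                 # study values
    ...

All stage outputs are TSV/BED text; the manifest records the config
snapshot, input checksums, package version and per-stage tallies, and
carries no timestamps so an identical rerun reproduces it byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .diffexp import AnalysisConfig, compare_conditions, summarize_classes
from .matcher import align_library, build_index, write_alignments_tsv
from .quant import call_loci, pooled_coverage, quantify, write_loci_bed
from .reference import load_catalog
from .report import render_summary

logger = logging.getLogger(__name__)

_CONFIG_ONLY_KEYS = {"reference", "libraries", "wt_condition", "collapse_duplicates",
                     "blast_provenance"}


class PipelineConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise PipelineConfigError(f"config {path} is not a mapping")
    return data


def parse_config(data: Mapping) -> tuple[dict[str, str], dict[str, list[str]], str, AnalysisConfig, bool]:
    """Validate the config mapping before any compute."""
    reference = data.get("reference")
    libraries = data.get("libraries")
    if not isinstance(reference, Mapping) or not reference:
        raise PipelineConfigError("config needs a non-empty 'reference' mapping")
    if not isinstance(libraries, Mapping) or not libraries:
        raise PipelineConfigError("config needs a non-empty 'libraries' mapping")
    wt = data.get("wt_condition", "WT")
    if wt not in libraries:
        raise PipelineConfigError(f"wt_condition {wt!r} not among libraries")
    if len(libraries) < 2:
        raise PipelineConfigError("need the WT condition plus at least one KO")
    analysis_keys = {f.name for f in dataclasses.fields(AnalysisConfig)}
    extra = set(data) - _CONFIG_ONLY_KEYS - analysis_keys
    if extra:
        raise PipelineConfigError(f"unknown config keys: {sorted(extra)}")
    try:
        config = AnalysisConfig(
            **{k: data[k] for k in analysis_keys if k in data}
        )
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(f"invalid analysis settings: {exc}") from exc
    for cond, files in libraries.items():
        if not files:
            raise PipelineConfigError(f"condition {cond!r} has no libraries")
        for f in files:
            if not Path(f).exists():
                raise PipelineConfigError(f"missing input for {cond!r}: {f}")
    for label, f in reference.items():
        if not Path(f).exists():
            raise PipelineConfigError(f"missing reference FASTA for {label!r}: {f}")
    libraries = {c: [str(f) for f in files] for c, files in libraries.items()}
    return (
        {str(k): str(v) for k, v in reference.items()},
        libraries,
        str(wt),
        config,
        bool(data.get("collapse_duplicates", False)),
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config_path: str | Path, outdir: str | Path) -> dict:
    """Run every stage and write the manifest; returns the manifest dict.

    Stage order: reference catalog, per-library alignment, pooled locus
    calling, quantification, one comparison per KO, class summaries and the
    stacked-bar report.  The config is validated fully before any compute;
    a failing stage aborts with the stage named.
    """
    config_path = Path(config_path)
    outdir = Path(outdir)
    data = load_config(config_path)
    reference, libraries, wt, config, collapse = parse_config(data)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "sncfrag",
        "version": __version__,
        "config": {k: data[k] for k in sorted(data)},
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    for label, f in reference.items():
        manifest["inputs"][f] = _sha256(f)
    for files in libraries.values():
        for f in files:
            manifest["inputs"][f] = _sha256(f)

    stage = "reference"
    try:
        catalog = load_catalog(
            sorted(reference.items()), collapse_duplicates=collapse
        )
        catalog.write_tsv(outdir / "catalog.tsv")
        catalog.write_fasta(outdir / "catalog.fasta")
        manifest["stages"][stage] = {
            "n_records": len(catalog),
            "classes": {c: len(ids) for c, ids in sorted(catalog.class_index.items())},
        }
        manifest["outputs"]["catalog_tsv"] = str(outdir / "catalog.tsv")

        stage = "align"
        index = build_index(catalog)
        aln_dir = outdir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        summaries = []
        conditions: dict[str, str] = {}
        groups: dict[str, list[str]] = {}
        align_stats = {}
        antisense = config.strand_policy == "both"
        for cond, files in libraries.items():
            groups[cond] = []
            for f in files:
                lib_id = Path(f).stem
                if lib_id in conditions:
                    raise ValueError(f"duplicate library id {lib_id!r}")
                s = align_library(
                    f, index, library_id=lib_id, antisense=antisense,
                    len_min=config.read_len_min, len_max=config.read_len_max,
                )
                write_alignments_tsv(s, catalog, aln_dir / f"{lib_id}.tsv")
                summaries.append(s)
                conditions[lib_id] = cond
                groups[cond].append(lib_id)
                align_stats[lib_id] = {
                    "total_reads": s.total_reads,
                    "length_filtered_reads": s.length_filtered_reads,
                    "aligned_reads": s.aligned_reads,
                    "alignments": len(s.alignments),
                }
        manifest["stages"][stage] = align_stats

        stage = "call_loci"
        profiles = pooled_coverage(summaries, catalog)
        loci = call_loci(
            profiles, catalog, delta=config.loci_delta, min_reads=config.min_reads
        )
        if not loci:
            raise ValueError("no fragment loci called (no reads aligned?)")
        write_loci_bed(loci, outdir / "loci.bed")
        manifest["stages"][stage] = {"n_loci": len(loci)}
        manifest["outputs"]["loci_bed"] = str(outdir / "loci.bed")

        stage = "quantify"
        matrix = quantify(
            summaries, loci,
            delta=config.loci_delta,
            policy=config.multimap_policy,
            denominator=config.rpm_denominator,
            conditions=conditions,
        )
        matrix.write(outdir)
        manifest["stages"][stage] = {
            "n_features": len(matrix.features),
            "assigned_reads": {
                lib: int(n) for lib, n in matrix.assigned_reads.items()
            },
        }
        manifest["outputs"]["rpm_tsv"] = str(outdir / "expression_rpm.tsv")

        stage = "compare"
        all_summaries = []
        compare_stats = {}
        for ko in libraries:
            if ko == wt:
                continue
            comp = compare_conditions(matrix, groups, wt, ko, config)
            comp.to_csv(outdir / f"comparison_{ko}.tsv", sep="\t",
                        float_format="%.6g")
            summary = summarize_classes(comp, ko)
            all_summaries.append(summary)
            compare_stats[ko] = {
                "n_expressed": int(comp["expressed"].sum()),
                "n_features": len(comp),
            }
        class_summary = pd.concat(all_summaries, ignore_index=True)
        manifest["stages"][stage] = compare_stats

        stage = "report"
        render_summary(
            class_summary,
            tsv_path=outdir / "class_summary.tsv",
            figure_path=outdir / "class_summary.png",
        )
        manifest["stages"][stage] = {"n_rows": int(len(class_summary))}
        manifest["outputs"]["class_summary_tsv"] = str(outdir / "class_summary.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
        out.write("\n")
    return manifest
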