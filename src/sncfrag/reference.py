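"""Class-labelled ncRNA reference catalogs.

A reference catalog holds full-length parent ncRNAs (mature miRNAs plus the
tRNAs, rRNAs, yRNAs, snoRNAs and snRNAs from which small-RNA fragments are
excised), one class label per record.  Class membership is taken from the
input file assignment — one class per FASTA file — never parsed out of
headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: Recognised parent ncRNA classes.  "other" is a catch-all for user catalogs.
NCRNA_CLASSES = ("miRNA", "tRNA", "rRNA", "yRNA", "snoRNA", "snRNA", "other")

#: Shortest parent that can host an accepted (16 nt) alignment.
MIN_PARENT_LENGTH = 16

_VALID_BASES = frozenset("ACGT")


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


@dataclass(frozen=True, slots=True)
class NcRNARecord:
    """One parent ncRNA with its class label.

    The sequence is stored normalised: uppercase DNA alphabet with U→T.
    """

    id: str
    class_label: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.class_label not in NCRNA_CLASSES:
            raise ReferenceError(
                f"unknown class label {self.class_label!r} for record {self.id!r}"
            )
        if len(self.sequence) < MIN_PARENT_LENGTH:
            raise ReferenceError(
                f"record {self.id!r} is {len(self.sequence)} nt, below the "
                f"{MIN_PARENT_LENGTH} nt floor"
            )
        if not _VALID_BASES.issuperset(self.sequence):
            raise ReferenceError(f"record {self.id!r} contains non-ACGT characters")

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to the DNA alphabet (T)."""
    return seq.upper().replace("U", "T")


def load_reference(
    fasta_path: str | Path, class_label: str, *, source: str | None = None
) -> list[NcRNARecord]:
    """Load one class-worth of parent ncRNAs from a FASTA file.

    Sequences are uppercased and U→T normalised.  Records shorter than 16 nt
    or containing IUPAC ambiguity codes (N, R, Y, ...) are dropped with a
    logged warning; exact matching against ambiguity codes is undefined.

    Raises
    ------
    ReferenceError
        On a missing/empty/malformed file or a duplicated record id; the
        message names the offending header.
    """
    path = Path(fasta_path)
    if class_label not in NCRNA_CLASSES:
        raise ReferenceError(f"unknown class label {class_label!r}")
    if not path.exists():
        raise ReferenceError(f"reference FASTA not found: {path}")
    src = source if source is not None else path.name

    records: list[NcRNARecord] = []
    seen: set[str] = set()
    n_parsed = 0
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            raise ReferenceError(f"empty reference FASTA: {path}")
        if first != ">":
            raise ReferenceError(
                f"malformed FASTA {path}: does not start with '>' header"
            )
        handle.seek(0)
        for header, raw_seq in SimpleFastaParser(handle):
            n_parsed += 1
            rec_id = header.split()[0] if header.split() else ""
            if not rec_id:
                raise ReferenceError(f"malformed FASTA {path}: empty header")
            if rec_id in seen:
                raise ReferenceError(f"duplicate record id {rec_id!r} in {path}")
            seen.add(rec_id)
            seq = normalize_sequence(raw_seq)
            if not seq:
                raise ReferenceError(
                    f"malformed FASTA {path}: record {rec_id!r} has no sequence"
                )
            if len(seq) < MIN_PARENT_LENGTH:
                logger.warning(
                    "dropping %s (%s): %d nt is below the %d nt floor",
                    rec_id, class_label, len(seq), MIN_PARENT_LENGTH,
                )
                continue
            if not _VALID_BASES.issuperset(seq):
                bad = sorted(set(seq) - _VALID_BASES)
                logger.warning(
                    "dropping %s (%s): ambiguity characters %s",
                    rec_id, class_label, "".join(bad),
                )
                continue
            records.append(
                NcRNARecord(id=rec_id, class_label=class_label, sequence=seq, source=src)
            )
    if n_parsed == 0:
        raise ReferenceError(f"empty reference FASTA: {path}")
    logger.info(
        "%s: loaded %d/%d %s records (dropped %d)",
        path.name, len(records), n_parsed, class_label, n_parsed - len(records),
    )
    return records


@dataclass(slots=True)
class ReferenceCatalog:
    """Merged, class-indexed collection of parent ncRNAs.

    Records keep their input order; ``class_index`` maps every class label to
    the ids it contributes, and every record sits in exactly one bucket.
    """

    records: list[NcRNARecord]
    class_index: dict[str, list[str]] = field(default_factory=dict)
    _by_id: dict[str, NcRNARecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ReferenceError("empty reference")
        self._by_id = {}
        index: dict[str, list[str]] = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise ReferenceError(f"duplicate record id {rec.id!r} in catalog")
            self._by_id[rec.id] = rec
            index.setdefault(rec.class_label, []).append(rec.id)
        self.class_index = index

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._by_id

    def __getitem__(self, rec_id: str) -> NcRNARecord:
        return self._by_id[rec_id]

    def get(self, rec_id: str) -> NcRNARecord | None:
        return self._by_id.get(rec_id)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def class_of(self, rec_id: str) -> str:
        return self._by_id[rec_id].class_label

    def collapse_duplicates(self) -> "ReferenceCatalog":
        """Keep the first record of every identical sequence (per class).

        Off by default throughout the pipeline: identical sequences under
        different ids (tRNA isodecoders, miRNA paralogues) stay separate
        records, mirroring how miRBase/Ensembl entries are catalogued.
        """
        kept: list[NcRNARecord] = []
        seen: dict[tuple[str, str], str] = {}
        for rec in self.records:
            key = (rec.class_label, rec.sequence)
            if key in seen:
                logger.warning(
                    "collapsing %s into %s (identical %s sequence)",
                    rec.id, seen[key], rec.class_label,
                )
                continue
            seen[key] = rec.id
            kept.append(rec)
        return ReferenceCatalog(records=kept)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as out:
            for rec in self.records:
                out.write(f">{rec.id}\n{rec.sequence}\n")

    def write_tsv(self, path: str | Path) -> None:
        """Catalog export: id, class_label, length, source."""
        with open(path, "w") as out:
            out.write("id\tclass_label\tlength\tsource\n")
            for rec in self.records:
                out.write(f"{rec.id}\t{rec.class_label}\t{len(rec)}\t{rec.source}\n")


def merge_catalog(
    parts: Sequence[Iterable[NcRNARecord]] | Mapping[str, Iterable[NcRNARecord]],
    *,
    collapse_duplicates: bool = False,
) -> ReferenceCatalog:
    """Merge per-class record collections into one catalog.

    Ids colliding across parts are disambiguated by prefixing with the class
    label (``tRNA:id``); a collision that survives prefixing is an error.
    Record order follows input order; the same parts in the same order always
    give the same catalog.
    """
    if isinstance(parts, Mapping):
        part_list = [list(p) for p in parts.values()]
    else:
        part_list = [list(p) for p in parts]
    flat = [rec for part in part_list for rec in part]
    if not flat:
        raise ReferenceError("empty reference")

    counts: dict[str, int] = {}
    for rec in flat:
        counts[rec.id] = counts.get(rec.id, 0) + 1
    resolved: list[NcRNARecord] = []
    seen: set[str] = set()
    for rec in flat:
        rec_id = rec.id
        if counts[rec_id] > 1:
            rec_id = f"{rec.class_label}:{rec.id}"
            logger.warning("prefixing colliding id %r as %r", rec.id, rec_id)
        if rec_id in seen:
            raise ReferenceError(
                f"id collision not resolvable by class prefixing: {rec_id!r}"
            )
        seen.add(rec_id)
        resolved.append(
            NcRNARecord(
                id=rec_id,
                class_label=rec.class_label,
                sequence=rec.sequence,
                source=rec.source,
            )
        )
    catalog = ReferenceCatalog(records=resolved)
    return catalog.collapse_duplicates() if collapse_duplicates else catalog


def load_catalog(
    class_fastas: Mapping[str, str | Path] | Sequence[tuple[str, str | Path]],
    *,
    collapse_duplicates: bool = False,
) -> ReferenceCatalog:
    """Load several (class_label, fasta) pairs and merge them."""
    items = class_fastas.items() if isinstance(class_fastas, Mapping) else class_fastas
    parts = [load_reference(path, label) for label, path in items]
    return merge_catalog(parts, collapse_duplicates=collapse_duplicates)
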