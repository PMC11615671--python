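import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from conftest import brute_force_match, random_seq
from sncfrag.matcher import (
    align_library,
    build_index,
    match_read,
    reverse_complement,
    write_alignments_sam,
    write_alignments_tsv,
)
from sncfrag.reference import NcRNARecord, ReferenceCatalog


class TestIndex:
    def test_locate_finds_every_occurrence(self, tiny_catalog):
        idx = build_index(tiny_catalog, k=16)
        assert sorted(idx.locate("ACGTACGTACGTACGT")) == [("t1", 0), ("t1", 4)]

    def test_locate_absent_seed_empty(self, tiny_catalog):
        idx = build_index(tiny_catalog, k=16)
        assert idx.locate("G" * 16) == []

    def test_seed_longer_than_min_read_rejected(self, tiny_catalog):
        with pytest.raises(ValueError, match="minimum accepted read length"):
            build_index(tiny_catalog, k=17)

    def test_index_exhaustive_vs_scan(self, random_catalog):
        idx = build_index(random_catalog, k=16)
        rec = random_catalog.records[0]
        for off in range(0, len(rec.sequence) - 16 + 1, 7):
            seed_kmer = rec.sequence[off:off + 16]
            assert (rec.id, off) in idx.locate(seed_kmer)


class TestMatchRead:
    def test_full_read_identity(self, tiny_catalog):
        idx = build_index(tiny_catalog)
        (aln,) = match_read("ACGTACGTACGTACGTACGT", idx)
        assert (aln.parent_id, aln.start, aln.end, aln.strand) == ("t1", 0, 20, "sense")

    def test_single_substitution_rejected(self, tiny_catalog):
        idx = build_index(tiny_catalog)
        assert match_read("ACGTACGTACGTACGTACGA", idx) == []

    @pytest.mark.parametrize("length", [14, 15, 33, 40])
    def test_out_of_window_lengths_rejected(self, tiny_catalog, length):
        idx = build_index(tiny_catalog)
        read = ("ACGT" * 12)[:length]
        assert match_read(read, idx) == []

    def test_n_containing_read_never_matches(self, tiny_catalog):
        idx = build_index(tiny_catalog)
        assert match_read("NCGTACGTACGTACGTACGT", idx) == []

    def test_u_reads_normalised(self, tiny_catalog):
        idx = build_index(tiny_catalog)
        assert len(match_read("ACGUACGUACGUACGUACGU", idx)) == 1

    def test_antisense_iff_revcomp_matches_sense(self, tiny_catalog):
        idx = build_index(tiny_catalog)
        read = reverse_complement("TTTTCCCCGGGGAAAATTTT")  # t2[0:20] antisense
        assert match_read(read, idx) == []
        hits = match_read(read, idx, antisense=True)
        assert [(a.parent_id, a.start, a.end, a.strand) for a in hits] == [
            ("t2", 0, 20, "antisense")
        ]

    def test_multimapping_duplicate_parents(self):
        seq = "AACCGGTTAACCGGTTAACC"
        cat = ReferenceCatalog(records=[
            NcRNARecord("iso1", "tRNA", seq), NcRNARecord("iso2", "tRNA", seq),
        ])
        hits = match_read(seq, build_index(cat))
        assert sorted(a.parent_id for a in hits) == ["iso1", "iso2"]


def test_matcher_agrees_with_brute_force_oracle(random_catalog, rng):
    """500 random/planted/near-miss reads: index equals all-offsets scan."""
    idx = build_index(random_catalog)
    reads = []
    for _ in range(250):
        reads.append(random_seq(rng, int(rng.integers(14, 35))))
    for _ in range(200):  # planted exact matches, some length-mutated
        rec = random_catalog.records[rng.integers(len(random_catalog.records))]
        n = int(rng.integers(16, 33))
        start = int(rng.integers(0, len(rec.sequence) - n + 1))
        reads.append(rec.sequence[start:start + n])
    for _ in range(50):  # 1-substitution near-misses
        rec = random_catalog.records[rng.integers(len(random_catalog.records))]
        n = int(rng.integers(16, 33))
        start = int(rng.integers(0, len(rec.sequence) - n + 1))
        read = list(rec.sequence[start:start + n])
        pos = int(rng.integers(n))
        read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        reads.append("".join(read))
    for read in reads:
        got = {(a.parent_id, a.start) for a in match_read(read, idx)}
        assert got == brute_force_match(read, random_catalog)


@seed(20240917)
@settings(max_examples=60, deadline=None)
@given(data=st.data())
def test_substring_closure_property(data):
    """A read matching at (P, i) matches there again wherever it recurs."""
    alphabet = st.sampled_from("ACGT")
    parent = data.draw(st.text(alphabet, min_size=30, max_size=120), label="parent")
    cat = ReferenceCatalog(records=[NcRNARecord("p", "tRNA", parent)])
    idx = build_index(cat)
    n = data.draw(st.integers(16, min(32, len(parent))), label="len")
    start = data.draw(st.integers(0, len(parent) - n), label="start")
    read = parent[start:start + n]
    hits = {(a.parent_id, a.start) for a in match_read(read, idx)}
    assert ("p", start) in hits
    assert hits == brute_force_match(read, cat)
    # every copy of the read reports the identical placement set
    assert hits == {(a.parent_id, a.start) for a in match_read(read, idx)}


class TestAlignLibrary:
    def write_fastq(self, path, reads):
        with open(path, "w") as out:
            for i, seq in enumerate(reads):
                out.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        return path

    def test_counts(self, tmp_path, tiny_catalog):
        idx = build_index(tiny_catalog)
        reads = [
            "ACGTACGTACGTACGTACGT",     # matches t1
            "TGAGGTAGTAGGTTGTATAGTT",   # matches m1
            "TTTTCCCCGGGGAAAA",         # matches t2
            "GGGGGGGGGGGGGGGGGGGG",     # no match
        ]
        s = align_library(self.write_fastq(tmp_path / "l.fastq", reads), idx)
        assert (s.total_reads, s.length_filtered_reads, s.aligned_reads) == (4, 4, 3)

    def test_length_filter_and_non_acgt_tally(self, tmp_path, tiny_catalog):
        idx = build_index(tiny_catalog)
        reads = ["ACGT" * 3,                     # 12 nt: filtered out
                 "A" * 33,                       # 33 nt: filtered out
                 "ACGTNCGTACGTACGTACGT",         # valid length, N
                 "ACGTACGTACGTACGTACGT"]
        s = align_library(self.write_fastq(tmp_path / "l.fastq", reads), idx)
        assert s.total_reads == 4
        assert s.length_filtered_reads == 2   # N read stays in the denominator
        assert s.non_acgt_reads == 1
        assert s.aligned_reads == 1

    def test_empty_library_zeros_with_warning(self, tmp_path, tiny_catalog, caplog):
        p = tmp_path / "empty.fastq"
        p.write_text("")
        with caplog.at_level("WARNING"):
            s = align_library(p, build_index(tiny_catalog))
        assert (s.total_reads, s.aligned_reads) == (0, 0)
        assert "empty" in caplog.text

    def test_fasta_input_and_malformed_error(self, tmp_path, tiny_catalog):
        idx = build_index(tiny_catalog)
        fa = tmp_path / "l.fasta"
        fa.write_text(">r0\nACGTACGTACGTACGTACGT\n")
        assert align_library(fa, idx).aligned_reads == 1
        bad = tmp_path / "bad.txt"
        bad.write_text("ACGTACGT\n")
        with pytest.raises(ValueError, match="unrecognised"):
            align_library(bad, idx)

    def test_alignment_tsv_deterministic(self, tmp_path, tiny_catalog):
        idx = build_index(tiny_catalog)
        reads = ["ACGTACGTACGTACGTACGT", "TTTTCCCCGGGGAAAA"] * 3
        fq = self.write_fastq(tmp_path / "l.fastq", reads)
        outs = []
        for i in range(2):
            s = align_library(fq, idx)
            out = tmp_path / f"aln{i}.tsv"
            write_alignments_tsv(s, tiny_catalog, out)
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]
        header = outs[0].decode().splitlines()[0]
        assert header == "read_id\tparent_id\tclass_label\tstart\tend\tstrand"

    def test_sam_export_readable_by_pysam(self, tmp_path, tiny_catalog):
        pysam = pytest.importorskip("pysam")
        idx = build_index(tiny_catalog)
        fq = self.write_fastq(tmp_path / "l.fastq", ["ACGTACGTACGTACGTACGT"])
        s = align_library(fq, idx)
        sam = tmp_path / "l.sam"
        write_alignments_sam(s, tiny_catalog, sam)
        with pysam.AlignmentFile(str(sam), "r") as fh:
            recs = list(fh)
        # the full 20-mer fits the 20 nt parent only at 0-based position 0
        assert [(r.reference_name, r.reference_start) for r in recs] == [("t1", 0)]
        assert all(r.cigarstring == "20M" and r.flag == 0 for r in recs)
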