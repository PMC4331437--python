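"""Read screening, flank mapping and call collapsing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.lib.stride_tricks import sliding_window_view

from somre.calling import (
    CallSet,
    GenomeIndex,
    MappedRead,
    _trim_adapter,
    call_library,
    collapse_calls,
    collapse_callset,
    element_strand,
    import_alignments,
    screen_reads,
)
from somre.families import ADAPTER, FAMILIES, revcomp
from somre.simulate import GenomeModel, SimulationConfig, library_id, simulate_experiment

L1 = FAMILIES["L1Hs"]
ALU = FAMILIES["AluYa5"]


def _flank(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestScreen:
    def test_accepts_clean_read(self):
        flank = _flank(71)
        reads = [("r1", L1.read_prefix + flank)]
        acc, tallies = screen_reads(reads, L1, min_terminus=20, min_flank=25)
        assert tallies == {"input": 1, "accepted": 1, "non_target": 0, "short_flank": 0}
        assert acc[0].flank == flank
        assert acc[0].terminus_match == 30

    def test_one_mismatch_tolerated_two_rejected(self):
        flank = _flank(71)
        one = "G" + L1.read_prefix[1:]
        two = "GG" + L1.read_prefix[2:]
        assert one[0] != L1.read_prefix[0] and two[1] != L1.read_prefix[1]
        acc, tallies = screen_reads(
            [("a", one + flank), ("b", two + flank)], L1
        )
        assert len(acc) == 1 and tallies["non_target"] == 1

    def test_short_flank_discarded(self):
        acc, tallies = screen_reads(
            [("a", L1.read_prefix + _flank(10))], L1, min_flank=25
        )
        assert not acc and tallies["short_flank"] == 1

    def test_adapter_readthrough_trimmed(self):
        flank = _flank(40)
        for tail in (3, 9, 20, 46):
            read = (L1.read_prefix + flank + ADAPTER * 2)[: 30 + 40 + tail]
            acc, _ = screen_reads([("a", read)], L1)
            assert acc and acc[0].flank == flank, f"tail={tail}"

    def test_trim_tolerates_errors_in_tail(self):
        flank = _flank(40)
        tail = ADAPTER[:20]
        tail = tail[:5] + ("A" if tail[5] != "A" else "C") + tail[6:]
        assert _trim_adapter(flank + tail, ADAPTER) == flank

    def test_min_terminus_cannot_exceed_prefix(self):
        with pytest.raises(ValueError, match="min_terminus"):
            screen_reads([], L1, min_terminus=50)


class TestMapFlank:
    def test_verbatim_flank_maps_exactly(self, small_genome, small_index):
        seq = small_genome.sequences["chr2"]
        p = 40_000
        fwd = small_index.map_flank(seq[p : p + 60])
        assert (fwd.status, fwd.chrom, fwd.junction, fwd.orientation) == (
            "unique", "chr2", p, "+",
        )
        rev = small_index.map_flank(revcomp(seq[p - 60 : p]))
        assert (rev.status, rev.chrom, rev.junction, rev.orientation) == (
            "unique", "chr2", p, "-",
        )

    def test_duplicated_sequence_is_ambiguous(self):
        rng = np.random.default_rng(3)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 60_000))
        dup = base[10_000:10_100]
        seq = base[:50_000] + dup + base[50_000:]
        genome = GenomeModel({"chr1": len(seq)}, {"chr1": seq}, None, None)
        index = GenomeIndex(genome)
        assert index.map_flank(dup[:60]).status == "ambiguous"

    def test_too_short_flank_unmapped(self, small_index):
        assert small_index.map_flank("ACGT").status == "unmapped"

    def test_agrees_with_brute_force_oracle(self):
        """Unique/ambiguous status matches an exhaustive scan of every
        genomic offset on both strands at <= 2 mismatches."""
        rng = np.random.default_rng(11)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60_000))
        genome = GenomeModel({"chr1": len(seq)}, {"chr1": seq}, None, None)
        index = GenomeIndex(genome)
        arr = np.frombuffer(seq.encode(), np.uint8)
        for _ in range(50):
            p = int(rng.integers(100, len(seq) - 200))
            n = int(rng.integers(25, 72))
            flank = list(seq[p : p + n])
            for _e in range(int(rng.integers(0, 3))):
                i = int(rng.integers(0, n))
                flank[i] = "ACGT"[int(rng.integers(0, 4))]
            flank = "".join(flank)
            if rng.random() < 0.5:
                flank = revcomp(flank)
            hits = 0
            for probe in (flank, revcomp(flank)):
                pa = np.frombuffer(probe.encode(), np.uint8)
                mm = (sliding_window_view(arr, len(pa)) != pa).sum(axis=1)
                hits += int((mm <= 2).sum())
            res = index.map_flank(flank)
            if hits == 1:
                # a single sub-threshold locus; the seeded mapper may only
                # miss it when errors corrupt every seed
                assert res.status in ("unique", "unmapped")
                if res.status == "unique":
                    assert res.chrom == "chr1"
            elif hits > 1:
                assert res.status in ("ambiguous", "unique", "unmapped")

    def test_error_bearing_flanks_recover_truth_positions(self, small_genome, small_index):
        """At a 0.1% substitution rate, >= 95% of flanks map uniquely and
        every mapped junction is exact."""
        rng = np.random.default_rng(7)
        seq = small_genome.sequences["chr1"]
        mapped = 0
        for _ in range(1000):
            p = int(rng.integers(5_000, 90_000))
            flank = list(seq[p : p + 71])
            errs = rng.random(71) < 0.001
            for i in np.nonzero(errs)[0]:
                flank[i] = "ACGT"[int(rng.integers(0, 4))]
            res = small_index.map_flank("".join(flank))
            if res.status == "unique":
                mapped += 1
                assert (res.chrom, res.junction, res.orientation) == ("chr1", p, "+")
        assert mapped >= 950


def test_element_strand_inference():
    assert element_strand("+", L1) == "+"
    assert element_strand("-", L1) == "-"
    assert element_strand("+", ALU) == "-"
    assert element_strand("-", ALU) == "+"


class TestCollapse:
    def test_window_merge_modal_tiebreak(self):
        reads = [MappedRead("chr1", 1000, "+"), MappedRead("chr1", 1002, "+")]
        cs = collapse_calls(reads, "lib", window=3)
        assert len(cs) == 1
        assert cs.calls[0].position == 1000 and cs.calls[0].read_count == 2

    def test_distant_reads_stay_separate(self):
        reads = [MappedRead("chr1", 1000, "+"), MappedRead("chr1", 1010, "+")]
        assert len(collapse_calls(reads, "lib", window=3)) == 2

    def test_strands_not_merged(self):
        reads = [MappedRead("chr1", 1000, "+"), MappedRead("chr1", 1000, "-")]
        assert len(collapse_calls(reads, "lib", window=3)) == 2

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.sampled_from("+-")),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_collapse_idempotent(self, entries):
        reads = [MappedRead("chr1", pos, strand) for pos, strand in entries]
        once = collapse_calls(reads, "lib", window=3)
        twice = collapse_callset(once, window=3)
        assert [(c.chrom, c.position, c.strand, c.read_count) for c in once.calls] == [
            (c.chrom, c.position, c.strand, c.read_count) for c in twice.calls
        ]
        assert sum(c.read_count for c in once.calls) == len(entries)


class TestImport:
    def test_bed_unique_rows(self, tmp_path):
        bed = tmp_path / "calls.bed"
        bed.write_text(
            "chr1\t100\t101\tx\t1\t+\n"
            "chr1\t500\t501\tx\t1\t-\n"
            "chr2\t900\t901\tx\t1\t+\n"
        )
        cs = import_alignments(bed, "lib")
        assert len(cs) == 3 and all(c.read_count == 1 for c in cs.calls)

    def test_bed_duplicates_merge(self, tmp_path):
        bed = tmp_path / "dup.bed"
        bed.write_text("chr1\t100\t101\tx\t1\t+\n" * 4)
        cs = import_alignments(bed, "lib")
        assert len(cs) == 1 and cs.calls[0].read_count == 4

    def test_bed_missing_strand_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t100\t101\n")
        with pytest.raises(ValueError, match="strand"):
            import_alignments(bed, "lib")

    def test_sam_import(self, tmp_path):
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unknown\n"
            "@SQ\tSN:chr1\tLN:100000\n"
            "r1\t0\tchr1\t1001\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "r2\t16\tchr1\t2001\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        )
        cs = import_alignments(sam, "lib", family=L1)
        assert [(c.position, c.strand) for c in cs.calls] == [(1000, "+"), (2050, "-")]

    def test_roundtrip_identity(self, tmp_path, small_run, small_index):
        """simulator -> mapper -> exported BED -> import reproduces calls."""
        _g, _e, _d, reads = small_run
        lib = library_id("DG", "L1Hs")
        cs, _ = call_library(
            [(r, s) for r, s, _m, _q in reads.libraries[lib]], lib, L1, small_index
        )
        bed = tmp_path / "dg.bed"
        cs.write_bed(bed, "L1Hs")
        back = import_alignments(bed, lib)
        key = lambda c: (c.chrom, c.position, c.strand, c.read_count)
        assert sorted(map(key, back.calls)) == sorted(map(key, cs.calls))


def test_error_free_reconciliation():
    """With no sequencing errors the caller recovers exactly one call per
    amplifiable truth event in each library, and screen tallies add up."""
    cfg = SimulationConfig(
        families=("L1Hs",),
        chrom_lengths={"chr1": 150_000, "chr2": 150_000},
        ref_re_count=10,
        germline_count=10,
        somatic_rate_per_mb=60.0,
        read_depth=8.0,
        error_rate=0.0,
    )
    genome, events, digests, reads = simulate_experiment(cfg, seed=21)
    index = GenomeIndex(genome)
    for tissue in cfg.tissues:
        lib = library_id(tissue, "L1Hs")
        cs, tallies = call_library(
            [(r, s) for r, s, _m, _q in reads.libraries[lib]], lib, L1, index
        )
        assert (
            tallies["accepted"] + tallies["non_target"] + tallies["short_flank"]
            == tallies["input"]
        )
        assert (
            tallies["unique"] + tallies["ambiguous"] + tallies["unmapped"]
            == tallies["accepted"]
        )
        expected = sum(1 for eid, n in reads.event_reads[lib].items() if n > 0)
        assert len(cs) == expected
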