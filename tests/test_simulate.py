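"""Simulator: genome construction, planting, digestion and read emission."""

import re
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from somre.families import ALUI, FAMILIES, HAEIII, RSAI, revcomp
from somre.simulate import (
    GenomeModel,
    InsertionEvent,
    SimulationConfig,
    _nearest_cut_left,
    _nearest_cut_right,
    build_genome,
    digest_and_amplify,
    emit_reads,
    plant_insertions,
    re_junction,
    simulate_experiment,
)


class TestBuildGenome:
    def test_gene_fraction_hits_target(self, medium_genome):
        lengths = medium_genome.genes["end"] - medium_genome.genes["start"]
        target = 0.45 * medium_genome.total_length
        assert abs(lengths.sum() - target) <= lengths.max()

    def test_genes_disjoint_and_in_bounds(self, medium_genome):
        for chrom, sub in medium_genome.genes.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"] >= 0).all()
            assert (sub["end"] <= medium_genome.chrom_lengths[chrom]).all()
            assert (sub["start"].values[1:] >= sub["end"].values[:-1]).all()

    def test_reference_res_planted_in_sequence(self, medium_genome):
        for _, row in medium_genome.reference_res.head(20).iterrows():
            fam = FAMILIES[row["name"]]
            seq = medium_genome.sequences[row["chrom"]][row["start"] : row["end"]]
            expected = (
                fam.element_sequence
                if row["strand"] == "+"
                else revcomp(fam.element_sequence)
            )
            assert seq == expected

    def test_deterministic_fasta(self, tmp_path):
        cfg = SimulationConfig(
            chrom_lengths={"chr1": 60_000}, ref_re_count=3, germline_count=3
        )
        for name in ("a", "b"):
            build_genome(cfg, seed=3).write_fasta(tmp_path / f"{name}.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_zero_gene_fraction(self):
        genome = build_genome(
            SimulationConfig(
                chrom_lengths={"chr1": 60_000}, gene_fraction=0.0, ref_re_count=3
            ),
            1,
        )
        assert len(genome.genes) == 0

    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="50 kb"):
            SimulationConfig(chrom_lengths={"chr1": 10_000})


class TestPlantInsertions:
    def test_zero_somatic_rate_gives_full_tissue_sets(self):
        cfg = SimulationConfig(
            families=("L1Hs",),
            chrom_lengths={"chr1": 100_000},
            somatic_rate_per_mb=0.0,
            ref_re_count=5,
            germline_count=5,
        )
        events = plant_insertions(build_genome(cfg, 1), cfg, 2)
        assert all(e.origin in ("reference", "germline") for e in events)
        assert all(e.tissues == cfg.tissues for e in events)

    def test_somatic_events_single_tissue_and_spacing(self, small_run):
        _genome, events, _d, _r = small_run
        positions = {}
        for e in events:
            if e.origin == "somatic":
                assert len(e.tissues) == 1
            positions.setdefault(e.chrom, []).append(e.position)
        for chrom, pos in positions.items():
            pos = sorted(pos)
            novel = np.diff(pos)
            assert (novel >= 1).all()

    def test_co_orientation_probability_recovered(self):
        """Binomial sampling oracle: with co-orientation probability 0.41
        the genic co-oriented fraction lands within 3 SE."""
        cfg = SimulationConfig(
            families=("L1Hs",),
            tissues=("t1",),
            somatic_rate_per_mb=3500.0,
            germline_count=0,
            ref_re_count=0,
            co_orientation_p={"L1Hs": 0.41},
        )
        genome = build_genome(cfg, 4)
        events = plant_insertions(genome, cfg, 5)
        genes = {
            (r.chrom, r.start, r.end): r.strand
            for r in genome.genes.itertuples()
        }
        co = tot = 0
        for e in events:
            for (chrom, s, en), strand in genes.items():
                if chrom == e.chrom and s <= e.position < en:
                    tot += 1
                    co += e.strand == strand
                    break
        assert tot > 2000
        se = np.sqrt(0.41 * 0.59 / tot)
        assert abs(co / tot - 0.41) < 3 * se

    def test_unit_genic_multiplier_is_uniform(self):
        """Uniform-sampling oracle: multiplier 1 gives a genic event
        fraction matching the genic genome fraction within 3 SE."""
        cfg = SimulationConfig(
            families=("L1Hs",),
            tissues=("t1",),
            somatic_rate_per_mb=2000.0,
            germline_count=0,
            ref_re_count=0,
            genic_multiplier={"L1Hs": 1.0},
        )
        genome = build_genome(cfg, 6)
        events = plant_insertions(genome, cfg, 7)
        intervals = [
            (r.chrom, r.start, r.end) for r in genome.genes.itertuples()
        ]
        genic = sum(
            any(c == e.chrom and s <= e.position < en for c, s, en in intervals)
            for e in events
        )
        f = genome.genic_fraction()
        n = len(events)
        se = np.sqrt(f * (1 - f) / n)
        assert abs(genic / n - f) < 3 * se


class TestDigest:
    def test_cut_site_scan_example(self):
        # one AluI site at 80 and one RsaI site at 150; blunt mid-site cuts
        seq = "T" * 80 + "AGCT" + "T" * 66 + "GTAC" + "T" * 46
        assert len(seq) == 200
        enzymes = (ALUI, RSAI)
        assert _nearest_cut_left(seq, 100, enzymes, 3000) == 82
        assert _nearest_cut_right(seq, 100, enzymes, 3000) == 152

    def test_short_flank_dropped(self):
        fam = FAMILIES["L1Hs"]
        # '+' L1: flank right of junction; place an AluI site 10 bp after it
        flank = "T" * 10 + "AGCT" + "T" * 600
        left = "C" * 3500 + "GGCC" + "C" * 200
        seq = left + flank + "C" * 3300
        genome = GenomeModel({"chr1": len(seq)}, {"chr1": seq}, _empty(), _empty())
        ev = InsertionEvent("e0", "chr1", len(left), "+", "L1Hs", "somatic", ("t1",))
        cfg = SimulationConfig(families=("L1Hs",), tissues=("t1",))
        res = digest_and_amplify(genome, [ev], fam, cfg)
        assert res.tallies["short_flank"] == 1
        assert not res.fragments[0].amplifiable

    def test_suppression_loss_without_cut_sites(self):
        # no recognition sites anywhere within the 3 kb cap
        seq = "T" * 8000
        genome = GenomeModel({"chr1": 8000}, {"chr1": seq}, _empty(), _empty())
        ev = InsertionEvent("e0", "chr1", 4000, "+", "AluYa5", "somatic", ("t1",))
        cfg = SimulationConfig(families=("AluYa5",), tissues=("t1",))
        res = digest_and_amplify(genome, [ev], FAMILIES["AluYa5"], cfg)
        assert res.tallies["suppression_loss"] == 1

    def test_fragment_boundaries_match_brute_force(self, small_run, small_config):
        """Digest oracle: for 100 random events the fragment equals the
        one delimited by a full regex enumeration of every cut site."""
        genome, events, digests, _reads = small_run
        fam = FAMILIES["L1Hs"]
        enzymes = small_config.enzymes_for("L1Hs")
        frags = [f for f in digests["L1Hs"].fragments if f.amplifiable]
        rng = np.random.default_rng(0)
        w = small_config.max_fragment + 300
        for frag in list(rng.choice(len(frags), size=100, replace=True)):
            f = frags[int(frag)]
            ev = f.event
            seq = genome.sequences[ev.chrom]
            elem = (
                fam.element_sequence
                if ev.strand == "+"
                else revcomp(fam.element_sequence)
            )
            flank_right = ev.strand == "+"  # L1 is 3'-flanked
            if ev.origin == "reference":
                local = seq[ev.position - w : ev.position + w]
                j = w
            else:
                local = seq[ev.position - w : ev.position] + elem + seq[ev.position :][:w]
                j = w + len(elem) if flank_right else w
            cuts = sorted(
                m.start() + e.cut_offset
                for e in enzymes
                for m in re.finditer(f"(?={e.site})", local)
            )
            left = max(c for c in cuts if c <= j)
            right = min(c for c in cuts if c >= j)
            assert f.fragment_seq == local[left:right]
            assert f.flank_len == (right - j if flank_right else j - left)

    def test_conservation_and_tissue_restriction(self, small_run):
        """Every amplifiable fragment maps to one truth event; dropped
        fragments are enumerated; reference fragments feed all tissues."""
        _g, events, digests, reads = small_run
        d = digests["L1Hs"]
        assert d.tallies["events"] == len(events)
        assert (
            d.tallies["amplifiable"]
            + d.tallies["suppression_loss"]
            + d.tallies["short_flank"]
            + d.tallies["no_primer"]
            == d.tallies["events"]
        )
        ids = [f.event.event_id for f in d.fragments]
        assert len(ids) == len(set(ids))
        # somatic events only ever produce reads in their own tissue
        by_event = {}
        for lib, counts in reads.event_reads.items():
            tissue = lib.rsplit("_", 1)[0]
            for eid in counts:
                by_event.setdefault(eid, set()).add(tissue)
        for e in events:
            if e.origin == "somatic" and e.event_id in by_event:
                assert by_event[e.event_id] == set(e.tissues)


class TestEmitReads:
    def test_error_free_read_crosses_junction_verbatim(self):
        cfg = SimulationConfig(
            families=("L1Hs",),
            tissues=("t1",),
            chrom_lengths={"chr1": 100_000},
            somatic_rate_per_mb=40.0,
            germline_count=0,
            ref_re_count=0,
            error_rate=0.0,
            somatic_read_dist={1: 1.0},
        )
        genome, events, digests, reads = simulate_experiment(cfg, seed=9)
        fam = FAMILIES["L1Hs"]
        frags = {f.event.event_id: f for f in digests["L1Hs"].fragments}
        pairs = reads.libraries["t1_L1Hs"]
        assert pairs
        for rid, r1, _r2, _q in pairs:
            eid = rid.split(":")[0]
            f = frags[eid]
            assert r1.startswith(fam.read_prefix)
            assert r1[len(fam.read_prefix) :].startswith(
                f.flank_out[: 101 - len(fam.read_prefix)]
            )

    def test_truth_bed_complete_and_counts(self, small_run):
        _g, events, _d, reads = small_run
        assert len(reads.truth) == len(events)
        classes = set(reads.truth["class"])
        assert classes <= {"reference", "germline", "somatic"}
        som = reads.truth[reads.truth["class"] == "somatic"]
        assert (som["score"] <= 5).all()

    def test_zero_depth_empty_fastq_full_truth(self, small_config):
        cfg = SimulationConfig(
            **{
                **{
                    f: getattr(small_config, f)
                    for f in (
                        "families", "chrom_lengths", "ref_re_count",
                        "germline_count", "somatic_rate_per_mb",
                    )
                },
                "read_depth": 0.0,
            }
        )
        _g, events, _d, reads = simulate_experiment(cfg, seed=5)
        assert all(len(p) == 0 for p in reads.libraries.values())
        assert len(reads.truth) == len(events)

    def test_byte_identical_outputs(self, tmp_path, small_config):
        for name in ("a", "b"):
            simulate_experiment(small_config, seed=5, outdir=tmp_path / name)
        for fn in ("DG_L1Hs_R1.fastq", "truth.bed", "genome.fasta", "genes.bed"):
            assert (tmp_path / "a" / fn).read_bytes() == (
                tmp_path / "b" / fn
            ).read_bytes()


def _empty() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])


def test_re_junction_convention():
    l1, alu = FAMILIES["L1Hs"], FAMILIES["AluYa5"]
    assert re_junction(l1, 100, 300, "+") == 300  # 3' end, plus strand
    assert re_junction(l1, 100, 300, "-") == 100
    assert re_junction(alu, 100, 300, "+") == 100  # 5' end, plus strand
    assert re_junction(alu, 100, 300, "-") == 300
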