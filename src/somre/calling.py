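"""Junction-library read calling.

Turns paired junction reads into per-library insertion calls with
single-base junction coordinates: screen reads for the expected RE
terminus prefix, map the post-junction flank to the reference with a
toy seed-and-extend mapper, and collapse near-identical junctions into
calls with read counts.  Reads whose flank cannot be placed uniquely
are discarded — only a uniquely mapped flank establishes the insertion
coordinate at single-base resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .families import ADAPTER, FAMILIES, REFamilyModel, revcomp
from .simulate import GenomeModel

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class JunctionRead:
    """One accepted read pair: terminus-matched read 1 plus its flank."""

    library: str
    read_id: str
    terminus_match: int
    flank: str
    mate: str | None = None


@dataclass
class Call:
    chrom: str
    position: int
    strand: str
    read_count: int
    flank: str = ""


@dataclass
class CallSet:
    """Deduplicated insertion calls of one library."""

    library: str
    calls: list[Call] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": c.chrom,
                    "position": c.position,
                    "strand": c.strand,
                    "read_count": c.read_count,
                }
                for c in self.calls
            ],
            columns=["chrom", "position", "strand", "read_count"],
        )

    def write_bed(self, path: str | Path, family: str = ".") -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tfamily\n")
            for i, c in enumerate(
                sorted(self.calls, key=lambda c: (c.chrom, c.position, c.strand))
            ):
                fh.write(
                    f"{c.chrom}\t{c.position}\t{c.position + 1}\tcall{i:06d}\t"
                    f"{c.read_count}\t{c.strand}\t{family}\n"
                )


def _trim_adapter(flank: str, adapter: str, min_overlap: int = 3) -> str:
    """Remove adapter read-through from the 3' end of a flank.

    The adapter tail is anchored at the read end, so the earliest suffix
    of length >= ``min_overlap`` that matches the adapter prefix (with a
    mismatch budget of one per 8 bp, tolerating sequencing errors in the
    tail) marks the trim point.
    """
    n = len(flank)
    reference = adapter * (n // len(adapter) + 1)
    for i in range(0, n - min_overlap + 1):
        tail = flank[i:]
        allowed = len(tail) // 8
        mismatches = 0
        for a, b in zip(tail, reference):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return flank[:i]
    return flank


def screen_reads(
    reads: "str | Path | list[tuple[str, str]]",
    family: REFamilyModel,
    min_terminus: int = 20,
    min_flank: int = 25,
    adapter: str = ADAPTER,
) -> tuple[list[JunctionRead], dict[str, int]]:
    """Filter read 1 sequences down to junction-informative reads.

    A read is accepted when its first ``read_terminus_len`` bases match
    the family's expected terminus prefix with at most one mismatch
    (``min_terminus`` must not exceed that fixed prefix length — the
    junction position within the read is set by the PCR design, not by
    the filter).  The remainder is the genomic flank; any adapter
    read-through is trimmed, and flanks shorter than ``min_flank`` are
    discarded and tallied.
    """
    prefix = family.read_prefix
    if min_terminus > len(prefix):
        raise ValueError(
            f"min_terminus={min_terminus} exceeds the fixed terminus prefix "
            f"length {len(prefix)}"
        )
    plen = len(prefix)
    accepted: list[JunctionRead] = []
    tallies = {"input": 0, "accepted": 0, "non_target": 0, "short_flank": 0}
    if isinstance(reads, (str, Path)):
        with open(reads) as fh:
            records = [(title, seq) for title, seq, _q in FastqGeneralIterator(fh)]
    else:
        records = list(reads)
    for title, seq in records:
        tallies["input"] += 1
        head = seq[:plen]
        mismatches = sum(a != b for a, b in zip(head, prefix))
        if len(head) < plen or mismatches > 1:
            tallies["non_target"] += 1
            continue
        flank = _trim_adapter(seq[plen:], adapter)
        if len(flank) < min_flank:
            tallies["short_flank"] += 1
            continue
        accepted.append(
            JunctionRead(
                library="",
                read_id=title.split()[0],
                terminus_match=plen - mismatches,
                flank=flank,
            )
        )
        tallies["accepted"] += 1
    return accepted, tallies


@dataclass
class MapResult:
    status: str  # unique | ambiguous | unmapped
    chrom: str | None = None
    junction: int | None = None
    orientation: str | None = None


class GenomeIndex:
    """Exact-seed flank mapper over a toy genome.

    Indexes every forward-strand k-mer (default k=20) as a sorted array
    of 2-bit-packed integers; a flank is seeded at a few offsets on both
    strands and each candidate locus is verified over the full flank
    allowing up to ``max_mismatches`` substitutions.
    """

    def __init__(self, genome: GenomeModel, k: int = 20, max_mismatches: int = 2):
        if k > 31:
            raise ValueError("k must be <= 31 for 2-bit packing")
        self.k = k
        self.max_mismatches = max_mismatches
        self.chroms = sorted(genome.sequences)
        self.codes = {c: _encode(genome.sequences[c]) for c in self.chroms}
        offsets = {}
        pos = 0
        for c in self.chroms:
            offsets[c] = pos
            pos += len(self.codes[c])
        self.offsets = offsets
        self._bounds = np.array(
            [offsets[c] for c in self.chroms] + [pos], dtype=np.int64
        )
        kmer_arrays, pos_arrays = [], []
        for c in self.chroms:
            codes = self.codes[c].astype(np.uint64)
            n = len(codes)
            if n < k:
                continue
            km = np.zeros(n - k + 1, dtype=np.uint64)
            for j in range(k):
                km = (km << np.uint64(2)) | codes[j : n - k + 1 + j]
            kmer_arrays.append(km)
            pos_arrays.append(np.arange(n - k + 1, dtype=np.int64) + offsets[c])
        kmers = np.concatenate(kmer_arrays)
        positions = np.concatenate(pos_arrays)
        order = np.argsort(kmers, kind="stable")
        self.kmers = kmers[order]
        self.positions = positions[order]

    def _locate(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._bounds, gpos, side="right")) - 1
        chrom = self.chroms[i]
        return chrom, gpos - self.offsets[chrom]

    def _seed_hits(self, codes: np.ndarray, offset: int) -> np.ndarray:
        key = np.uint64(0)
        for v in codes[offset : offset + self.k]:
            key = (key << np.uint64(2)) | np.uint64(v)
        lo = int(np.searchsorted(self.kmers, key, side="left"))
        hi = int(np.searchsorted(self.kmers, key, side="right"))
        return self.positions[lo:hi] - offset

    def _verify(self, codes: np.ndarray, gstart: int) -> bool:
        n = len(codes)
        chrom, off = self._locate(gstart) if gstart >= 0 else (None, -1)
        if chrom is None:
            return False
        ref = self.codes[chrom]
        if off < 0 or off + n > len(ref):
            return False
        return int(np.count_nonzero(ref[off : off + n] != codes)) <= self.max_mismatches

    def map_flank(self, flank: str) -> MapResult:
        """Place a flank; returns the junction coordinate on success.

        The junction is the flank boundary adjacent to the insertion:
        the mapped start for a forward hit, the mapped end for a
        reverse hit.
        """
        n = len(flank)
        if n < self.k:
            return MapResult("unmapped")
        fwd = _encode(flank)
        rev = _encode(revcomp(flank))
        if (fwd > 3).any():
            return MapResult("unmapped")
        seed_offsets = [o for o in (0, 10, 20) if o + self.k <= n]
        hits: set[tuple[int, str]] = set()
        for strand, codes in (("+", fwd), ("-", rev)):
            for off in seed_offsets:
                # reverse-strand seeds index into the reverse-complemented
                # flank, whose genomic start is the candidate start too
                for cand in self._seed_hits(codes, off):
                    hits.add((int(cand), strand))
        passing = [
            (gstart, strand)
            for gstart, strand in sorted(hits)
            if self._verify(fwd if strand == "+" else rev, gstart)
        ]
        if not passing:
            return MapResult("unmapped")
        if len(passing) > 1:
            return MapResult("ambiguous")
        gstart, strand = passing[0]
        chrom, off = self._locate(gstart)
        if strand == "+":
            return MapResult("unique", chrom, off, "+")
        return MapResult("unique", chrom, off + n, "-")


def element_strand(mapped_orientation: str, family: REFamilyModel) -> str:
    """Infer the inserted element's strand from the flank orientation.

    For a 3'-flanked family (L1) the read runs in the element's sense,
    so the element strand equals the flank's mapped orientation; for a
    5'-flanked family (Alu) the read runs antisense and the strand is
    flipped.
    """
    if family.flank_side == "3p":
        return mapped_orientation
    return "-" if mapped_orientation == "+" else "+"


@dataclass
class MappedRead:
    chrom: str
    position: int
    strand: str
    flank: str = ""
    count: int = 1


def _cluster_positions(
    entries: list[tuple[int, int, str]], window: int
) -> list[tuple[int, int, str]]:
    """Single-linkage chain of (position, count, flank) triples.

    Returns one (modal position, total count, flank) per cluster; the
    modal position is the one with the highest read total, ties broken
    toward the smaller coordinate.
    """
    out = []
    cluster: list[tuple[int, int, str]] = []

    def flush():
        if not cluster:
            return
        weights: dict[int, int] = {}
        flanks: dict[int, str] = {}
        for pos, cnt, fl in cluster:
            weights[pos] = weights.get(pos, 0) + cnt
            flanks.setdefault(pos, fl)
        modal = min(weights, key=lambda p: (-weights[p], p))
        out.append((modal, sum(weights.values()), flanks[modal]))

    last = None
    for pos, cnt, fl in sorted(entries):
        if last is not None and pos - last > window:
            flush()
            cluster = []
        cluster.append((pos, cnt, fl))
        last = pos
    flush()
    return out


def collapse_calls(
    mapped: list[MappedRead], library: str, window: int = 3
) -> CallSet:
    """Merge junction coordinates within ``window`` bp into single calls."""
    grouped: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for m in mapped:
        grouped.setdefault((m.chrom, m.strand), []).append(
            (m.position, m.count, m.flank)
        )
    calls = []
    for (chrom, strand), entries in sorted(grouped.items()):
        for pos, total, flank in _cluster_positions(entries, window):
            calls.append(Call(chrom, pos, strand, total, flank))
    calls.sort(key=lambda c: (c.chrom, c.position, c.strand))
    return CallSet(library, calls)


def collapse_callset(callset: CallSet, window: int = 3) -> CallSet:
    """Re-collapse an existing CallSet (idempotent on collapsed input)."""
    entries = [
        MappedRead(c.chrom, c.position, c.strand, c.flank, c.read_count)
        for c in callset.calls
    ]
    return collapse_calls(entries, callset.library, window)


def call_library(
    fastq_r1: "str | Path | list[tuple[str, str]]",
    library: str,
    family: REFamilyModel,
    index: GenomeIndex,
    min_terminus: int = 20,
    min_flank: int = 25,
    window: int = 3,
) -> tuple[CallSet, dict[str, int]]:
    """Screen, map and collapse one library's read 1 file."""
    accepted, tallies = screen_reads(fastq_r1, family, min_terminus, min_flank)
    mapped: list[MappedRead] = []
    tallies.update({"unique": 0, "ambiguous": 0, "unmapped": 0})
    for read in accepted:
        res = index.map_flank(read.flank)
        tallies[res.status] += 1
        if res.status == "unique":
            mapped.append(
                MappedRead(
                    res.chrom,
                    res.junction,
                    element_strand(res.orientation, family),
                    read.flank,
                )
            )
    callset = collapse_calls(mapped, library, window)
    return callset, tallies


def import_alignments(
    path: str | Path,
    library: str,
    family: REFamilyModel | None = None,
    window: int = 3,
) -> CallSet:
    """Build a CallSet from externally produced alignments (BED or SAM).

    BED rows are junction records (start = junction, score = read count,
    strand = element strand; strand is mandatory).  SAM records are
    treated as mapped flanks: the junction is the alignment start for
    forward hits and the alignment end for reverse hits, with the
    element strand inferred through ``family`` when given.
    """
    path = Path(path)
    entries: list[MappedRead] = []
    if path.suffix.lower() in (".sam", ".bam"):
        import pysam

        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped:
                    continue
                orient = "-" if aln.is_reverse else "+"
                junction = aln.reference_end if aln.is_reverse else aln.reference_start
                strand = element_strand(orient, family) if family else orient
                entries.append(MappedRead(aln.reference_name, int(junction), strand))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6 or parts[5] not in ("+", "-"):
                    raise ValueError(
                        f"{path}:{lineno}: BED record lacks a strand field"
                    )
                try:
                    count = max(int(float(parts[4])), 1)
                except ValueError:
                    count = 1
                entries.append(
                    MappedRead(parts[0], int(parts[1]), parts[5], count=count)
                )
    return collapse_calls(entries, library, window)
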