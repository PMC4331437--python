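"""Synthetic junction-library simulator.

Emulates the data-generating process of a suppression-PCR retroelement
profiling experiment at toy scale: a small random reference genome with
gene and reference-RE annotation, planted germline and tissue-specific
somatic insertions, restriction digestion of each (virtual) tissue
genome, and paired-end junction reads for every amplifiable fragment.

The simulation is sequence-level: restriction sites are found on the
actual insertion-bearing sequence (an insertion can create or destroy a
site), a fragment is amplifiable only if it retains the subfamily
primer sites and a mappable flank, and reads carry substitution errors
at a configurable rate.  Target-site duplications, indel errors and PCR
chimeras are not modeled.
"""

from __future__ import annotations

import hashlib
import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .families import ADAPTER, ENZYMES, FAMILIES, REFamilyModel, revcomp

logger = logging.getLogger(__name__)

TISSUES = ("cerebellum", "frontal_cortex", "SVZ", "DG", "myocardium")

#: minimum allowed distance between planted insertion points (bp)
MIN_EVENT_SPACING = 20
#: exclusion zone around reference-RE intervals for novel insertions (bp)
REF_EXCLUSION = 150

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Rates are per Mb per tissue per family; ``tissue_rate_multiplier``
    scales them for individual tissues (keys ``"DG"`` or ``"DG:L1Hs"``).
    ``read_depth`` is the mean read-pair count per germline/reference
    event per library; somatic events instead draw from
    ``somatic_read_dist``, reflecting that an insertion carried by one or
    a few cells is seen by very few molecules.
    """

    tissues: tuple[str, ...] = TISSUES
    families: tuple[str, ...] = ("L1Hs", "AluYa5")
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
    )
    gene_fraction: float = 0.45
    ref_re_count: int = 60
    somatic_rate_per_mb: float = 50.0
    tissue_rate_multiplier: dict[str, float] = field(default_factory=dict)
    germline_count: int = 30
    co_orientation_p: dict[str, float] = field(
        default_factory=lambda: {"L1Hs": 0.41, "AluYa5": 0.49}
    )
    genic_multiplier: dict[str, float] = field(
        default_factory=lambda: {"L1Hs": 1.2, "AluYa5": 1.0}
    )
    read_length: int = 101
    read_depth: float = 30.0
    somatic_read_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.85, 2: 0.08, 3: 0.04, 4: 0.02, 5: 0.01}
    )
    error_rate: float = 0.001
    min_flank: int = 25
    max_fragment: int = 3000
    enzymes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"L1Hs": ("AluI", "HaeIII"), "AluYa5": ("AluI", "RsaI")}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, length in self.chrom_lengths.items():
            if length < 50_000:
                raise ValueError(
                    f"chromosome {name} is {length} bp; chromosomes must be >= 50 kb"
                )
        if not 0.0 <= self.gene_fraction <= 1.0:
            raise ValueError("gene_fraction must be in [0, 1]")
        for fam, p in self.co_orientation_p.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"co_orientation_p[{fam}] must be in [0, 1]")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.somatic_rate_per_mb < 0:
            raise ValueError("somatic_rate_per_mb must be >= 0")
        if abs(sum(self.somatic_read_dist.values()) - 1.0) > 1e-9:
            raise ValueError("somatic_read_dist probabilities must sum to 1")
        for fam in self.families:
            if fam not in FAMILIES:
                raise ValueError(f"unknown family {fam!r}")

    def rate_for(self, tissue: str, family: str) -> float:
        mult = self.tissue_rate_multiplier.get(
            f"{tissue}:{family}", self.tissue_rate_multiplier.get(tissue, 1.0)
        )
        return self.somatic_rate_per_mb * mult

    def enzymes_for(self, family: str) -> tuple:
        return tuple(ENZYMES[n] for n in self.enzymes[family])

    @property
    def margin(self) -> int:
        """Insertions keep this distance from chromosome ends so the
        digestion window never runs off the sequence."""
        return self.max_fragment + 400

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["somatic_read_dist"] = {int(k): float(v) for k, v in self.somatic_read_dist.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class GenomeModel:
    """A toy reference genome with gene and reference-RE annotation.

    ``genes`` and ``reference_res`` are BED6-style frames
    (chrom, start, end, name, score, strand); for reference REs the name
    column is the family.
    """

    chrom_lengths: dict[str, int]
    sequences: dict[str, str]
    genes: pd.DataFrame
    reference_res: pd.DataFrame

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def genic_intervals(self, chrom: str) -> list[tuple[int, int]]:
        sub = self.genes[self.genes["chrom"] == chrom]
        return list(zip(sub["start"], sub["end"]))

    def genic_fraction(self) -> float:
        if len(self.genes) == 0:
            return 0.0
        return float((self.genes["end"] - self.genes["start"]).sum()) / self.total_length

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_annotation(self, gene_bed: str | Path, re_bed: str | Path) -> None:
        write_bed6(self.genes, gene_bed)
        write_bed6(self.reference_res, re_bed)


def genome_from_fasta(
    path: str | Path,
    genes: pd.DataFrame | None = None,
    reference_res: pd.DataFrame | None = None,
) -> GenomeModel:
    """Load a genome (plus optional annotation frames) from FASTA."""
    from Bio import SeqIO

    cols = ["chrom", "start", "end", "name", "score", "strand"]
    empty = pd.DataFrame(columns=cols)
    sequences = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    lengths = {c: len(s) for c, s in sequences.items()}
    return GenomeModel(
        lengths,
        sequences,
        genes if genes is not None else empty.copy(),
        reference_res if reference_res is not None else empty.copy(),
    )


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=range(6),
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    return df


@dataclass
class InsertionEvent:
    """A planted retroelement insertion.

    ``position`` is a 0-based inter-base coordinate: the element sits
    between reference bases ``position - 1`` and ``position``.  Reference
    events appear in every tissue; somatic events in exactly one.
    """

    event_id: str
    chrom: str
    position: int
    strand: str
    family: str
    origin: str  # reference | germline | somatic
    tissues: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.origin not in ("reference", "germline", "somatic"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.origin == "somatic" and len(self.tissues) != 1:
            raise ValueError("somatic events must belong to exactly one tissue")


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def build_genome(config: SimulationConfig, seed: int) -> GenomeModel:
    """Construct a random reference genome with genes and reference REs.

    Genes are placed as non-overlapping intervals whose total length is
    steered to ``gene_fraction`` of each chromosome (achieved to within
    one gene length).  Reference-RE copies are written into the sequence
    at their annotated loci, so digestion and read emission treat them
    exactly like novel insertions.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    gene_rows, re_rows = [], []
    gene_idx = 0
    margin = 1_000
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        seq = _random_sequence(rng, length)
        # --- genes ---
        f = config.gene_fraction
        if f > 0:
            target = f * length
            placed = 0
            pos = margin
            while placed < target:
                glen = int(rng.integers(5_000, 30_000))
                remaining = int(target - placed)
                if remaining < 1_000:
                    break
                glen = min(glen, remaining)  # land on the target, not past it
                if pos + glen > length - margin:
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append(
                    {
                        "chrom": chrom,
                        "start": pos,
                        "end": pos + glen,
                        "name": f"gene{gene_idx:05d}",
                        "score": 0,
                        "strand": strand,
                    }
                )
                gene_idx += 1
                placed += glen
                pos += glen
                # steer the running gene density back to the target
                ideal_next = margin + placed / f - glen * (1 - f) / f * rng.uniform(
                    -0.3, 0.3
                )
                pos = max(pos + 1, int(ideal_next))
        sequences[chrom] = seq
    # --- reference REs (planted after genes so intervals are known) ---
    chrom_names = sorted(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[int]] = {c: [] for c in chrom_names}
    re_idx = 0
    seq_arrays = {c: bytearray(sequences[c], "ascii") for c in chrom_names}
    margin_re = config.margin
    for fam_name in sorted(config.families):
        fam = FAMILIES[fam_name]
        elem = fam.element_sequence
        for _ in range(config.ref_re_count):
            for _attempt in range(1_000):
                chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
                length = config.chrom_lengths[chrom]
                start = int(rng.integers(margin_re, length - margin_re - len(elem)))
                taken = occupied[chrom]
                i = bisect_left(taken, start)
                clear = all(
                    abs(start - taken[j]) > len(elem) + 500
                    for j in range(max(0, i - 1), min(len(taken), i + 1))
                )
                if clear:
                    insort(taken, start)
                    break
            else:  # pragma: no cover - essentially impossible at default density
                raise RuntimeError("could not place reference RE without collision")
            strand = "+" if rng.random() < 0.5 else "-"
            planted = elem if strand == "+" else revcomp(elem)
            seq_arrays[chrom][start : start + len(elem)] = planted.encode()
            re_rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + len(elem),
                    "name": fam_name,
                    "score": 0,
                    "strand": strand,
                }
            )
            re_idx += 1
    sequences = {c: seq_arrays[c].decode() for c in chrom_names}
    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    res = pd.DataFrame(
        re_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return GenomeModel(dict(config.chrom_lengths), sequences, genes, res)


def re_junction(family: REFamilyModel, start: int, end: int, strand: str) -> int:
    """Junction coordinate (recovered-flank boundary) of an annotated RE."""
    if family.flank_side == "3p":
        return end if strand == "+" else start
    return start if strand == "+" else end


class _PositionSampler:
    """Samples insertion points, reweighting genic bp by a multiplier."""

    def __init__(self, genome: GenomeModel, config: SimulationConfig, multiplier: float):
        margin = config.margin
        intervals: list[tuple[str, int, int, bool]] = []
        for chrom in sorted(genome.chrom_lengths):
            length = genome.chrom_lengths[chrom]
            lo, hi = margin, length - margin
            genic = [
                (max(s, lo), min(e, hi))
                for s, e in genome.genic_intervals(chrom)
                if min(e, hi) > max(s, lo)
            ]
            genic.sort()
            pos = lo
            for s, e in genic:
                if s > pos:
                    intervals.append((chrom, pos, s, False))
                intervals.append((chrom, s, e, True))
                pos = e
            if pos < hi:
                intervals.append((chrom, pos, hi, False))
        self.intervals = intervals
        w = np.array(
            [(e - s) * (multiplier if g else 1.0) for _, s, e, g in intervals],
            dtype=float,
        )
        self.prob = w / w.sum()

    def draw(self, rng: np.random.Generator) -> tuple[str, int, bool]:
        i = rng.choice(len(self.intervals), p=self.prob)
        chrom, s, e, genic = self.intervals[i]
        return chrom, int(rng.integers(s, e)), genic

    def draw_many(self, rng: np.random.Generator, n: int) -> list[tuple[str, int, bool]]:
        idx = rng.choice(len(self.intervals), size=n, p=self.prob)
        u = rng.random(n)
        out = []
        for i, frac in zip(idx, u):
            chrom, s, e, genic = self.intervals[i]
            out.append((chrom, s + int(frac * (e - s)), genic))
        return out


def plant_insertions(
    genome: GenomeModel, config: SimulationConfig, seed: int
) -> list[InsertionEvent]:
    """Plant reference, germline and somatic insertion events.

    Somatic counts per tissue are Poisson with mean rate x genome Mb;
    germline events get the full tissue set.  The insertion strand
    follows the configured co-orientation probability relative to an
    overlapped gene (uniform when intergenic).  Points closer than
    20 bp to an existing event (or inside a reference-RE footprint) are
    resampled.
    """
    rng = np.random.default_rng(seed)
    events: list[InsertionEvent] = []
    taken: dict[str, list[int]] = {c: [] for c in genome.chrom_lengths}
    # block the reference-RE footprints so novel junctions stay distinct
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_lengths}
    for _, row in genome.reference_res.iterrows():
        blocked[row["chrom"]].append(
            (row["start"] - REF_EXCLUSION, row["end"] + REF_EXCLUSION)
        )
    for c in blocked:
        blocked[c].sort()

    gene_lookup: dict[str, list[tuple[int, int, str]]] = {}
    for _, row in genome.genes.iterrows():
        gene_lookup.setdefault(row["chrom"], []).append(
            (row["start"], row["end"], row["strand"])
        )
    for c in gene_lookup:
        gene_lookup[c].sort()

    def overlapping_gene(chrom: str, pos: int) -> str | None:
        arr = gene_lookup.get(chrom, [])
        i = bisect_left(arr, (pos + 1,)) - 1
        if i >= 0 and arr[i][0] <= pos < arr[i][1]:
            return arr[i][2]
        return None

    def is_free(chrom: str, pos: int) -> bool:
        arr = taken[chrom]
        i = bisect_left(arr, pos)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(arr[j] - pos) < MIN_EVENT_SPACING:
                return False
        blk = blocked[chrom]
        k = bisect_left(blk, (pos + 1,)) - 1
        if k >= 0 and blk[k][0] <= pos < blk[k][1]:
            return False
        return True

    resampled = 0

    def sample_point(sampler: _PositionSampler) -> tuple[str, int]:
        nonlocal resampled
        for _ in range(10_000):
            chrom, pos, _ = sampler.draw(rng)
            if is_free(chrom, pos):
                insort(taken[chrom], pos)
                return chrom, pos
            resampled += 1
        raise RuntimeError("insertion density too high: could not place event")

    def choose_strand(fam_name: str, chrom: str, pos: int) -> str:
        gstrand = overlapping_gene(chrom, pos)
        if gstrand is None:
            return "+" if rng.random() < 0.5 else "-"
        co = rng.random() < config.co_orientation_p.get(fam_name, 0.5)
        return gstrand if co else ("-" if gstrand == "+" else "+")

    # reference events straight from the annotation
    for i, row in genome.reference_res.reset_index(drop=True).iterrows():
        fam = FAMILIES[row["name"]]
        events.append(
            InsertionEvent(
                event_id=f"ref{i:05d}",
                chrom=row["chrom"],
                position=re_junction(fam, row["start"], row["end"], row["strand"]),
                strand=row["strand"],
                family=row["name"],
                origin="reference",
                tissues=tuple(config.tissues),
            )
        )

    genome_mb = genome.total_length / 1e6
    counter = 0
    for fam_name in sorted(config.families):
        sampler = _PositionSampler(
            genome, config, config.genic_multiplier.get(fam_name, 1.0)
        )
        for _ in range(config.germline_count):
            chrom, pos = sample_point(sampler)
            events.append(
                InsertionEvent(
                    event_id=f"germ{counter:05d}",
                    chrom=chrom,
                    position=pos,
                    strand=choose_strand(fam_name, chrom, pos),
                    family=fam_name,
                    origin="germline",
                    tissues=tuple(config.tissues),
                )
            )
            counter += 1
        for tissue in config.tissues:
            n = rng.poisson(config.rate_for(tissue, fam_name) * genome_mb)
            for _ in range(n):
                chrom, pos = sample_point(sampler)
                events.append(
                    InsertionEvent(
                        event_id=f"som{counter:05d}",
                        chrom=chrom,
                        position=pos,
                        strand=choose_strand(fam_name, chrom, pos),
                        family=fam_name,
                        origin="somatic",
                        tissues=(tissue,),
                    )
                )
                counter += 1
    if resampled:
        logger.warning("resampled %d colliding insertion points", resampled)
    return events


@dataclass
class Fragment:
    """The restriction fragment containing one insertion junction."""

    event: InsertionEvent
    fragment_seq: str
    flank_len: int
    element_len: int
    flank_out: str  # genomic flank read outward from the junction
    mate_seq: str  # fragment sequence entering from the adapter end
    amplifiable: bool
    drop_reason: str | None = None


@dataclass
class DigestResult:
    family: str
    fragments: list[Fragment]
    tallies: dict[str, int]

    @property
    def amplifiable(self) -> list[Fragment]:
        return [f for f in self.fragments if f.amplifiable]


def _nearest_cut_right(seq: str, j: int, enzymes, limit: int) -> int | None:
    best = None
    for enz in enzymes:
        start = max(0, j - len(enz.site) + 1)
        while True:
            i = seq.find(enz.site, start)
            if i == -1:
                break
            cut = i + enz.cut_offset
            if cut >= j:
                if cut - j <= limit and (best is None or cut < best):
                    best = cut
                break
            start = i + 1
    return best


def _nearest_cut_left(seq: str, j: int, enzymes, limit: int) -> int | None:
    best = None
    for enz in enzymes:
        hi = min(len(seq), j + len(enz.site) - 1)
        start = max(0, j - limit - len(enz.site))
        pos = start
        last = None
        while True:
            i = seq.find(enz.site, pos, hi)
            if i == -1:
                break
            cut = i + enz.cut_offset
            if cut <= j:
                last = cut
            pos = i + 1
        if last is not None and j - last <= limit and (best is None or last > best):
            best = last
    return best


def digest_and_amplify(
    genome: GenomeModel,
    events: list[InsertionEvent],
    family: REFamilyModel,
    config: SimulationConfig,
) -> DigestResult:
    """Compute the junction restriction fragment for every event.

    The insertion-bearing local sequence is scanned outward from the
    junction for the nearest cut site of the library's enzymes on each
    side.  A fragment is amplifiable only when it retains all of the
    family's diagnostic primer sites and its genomic flank segment is at
    least ``min_flank`` bp.  Fragments with no cut site within
    ``max_fragment`` bp of the junction are lost to suppression and
    tallied.
    """
    enzymes = config.enzymes_for(family.name)
    rl = config.read_length
    w = config.max_fragment + 300
    fragments: list[Fragment] = []
    tallies = {
        "events": 0,
        "amplifiable": 0,
        "suppression_loss": 0,
        "short_flank": 0,
        "no_primer": 0,
    }
    for ev in events:
        if ev.family != family.name:
            continue
        tallies["events"] += 1
        seq = genome.sequences[ev.chrom]
        p = ev.position
        elem = family.element_sequence if ev.strand == "+" else revcomp(
            family.element_sequence
        )
        flank_right = (family.flank_side == "3p") == (ev.strand == "+")
        if ev.origin == "reference":
            # the element is already in the reference sequence
            local = seq[p - w : p + w]
            j = w
        else:
            local = seq[p - w : p] + elem + seq[p : p + w]
            j = w + len(elem) if flank_right else w
        cut_l = _nearest_cut_left(local, j, enzymes, config.max_fragment)
        cut_r = _nearest_cut_right(local, j, enzymes, config.max_fragment)
        if cut_l is None or cut_r is None:
            fragments.append(Fragment(ev, "", 0, 0, "", "", False, "suppression_loss"))
            tallies["suppression_loss"] += 1
            continue
        frag = local[cut_l:cut_r]
        if flank_right:
            flank_len = cut_r - j
            element_len = j - cut_l
        else:
            flank_len = j - cut_l
            element_len = cut_r - j
        if flank_len < config.min_flank:
            fragments.append(
                Fragment(ev, frag, flank_len, element_len, "", "", False, "short_flank")
            )
            tallies["short_flank"] += 1
            continue
        has_primers = all(
            primer in frag or revcomp(primer) in frag for primer in family.primer_sites
        )
        if not has_primers:
            fragments.append(
                Fragment(ev, frag, flank_len, element_len, "", "", False, "no_primer")
            )
            tallies["no_primer"] += 1
            continue
        take = min(flank_len, rl - family.read_terminus_len)
        if flank_right:
            flank_out = local[j : j + take]
            mate = revcomp(local[cut_r - min(rl, len(frag)) : cut_r])
        else:
            flank_out = revcomp(local[j - take : j])
            mate = local[cut_l : cut_l + min(rl, len(frag))]
        fragments.append(
            Fragment(ev, frag, flank_len, element_len, flank_out, mate, True)
        )
        tallies["amplifiable"] += 1
    return DigestResult(family.name, fragments, tallies)


@dataclass
class ReadPairSet:
    """Emitted read pairs plus per-event provenance tallies."""

    libraries: dict[str, list[tuple[str, str, str, str]]]  # lib -> (rid, r1, r2, qual)
    event_reads: dict[str, dict[str, int]]  # lib -> event_id -> pair count
    truth: pd.DataFrame

    def total_pairs(self, library: str) -> int:
        return len(self.libraries.get(library, []))


def library_id(tissue: str, family: str) -> str:
    return f"{tissue}_{family}"


def _inject_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def emit_reads(
    digests: dict[str, DigestResult],
    config: SimulationConfig,
    seed: int,
    outdir: str | Path | None = None,
) -> ReadPairSet:
    """Emit paired junction reads per library and the truth BED table.

    Read 1 starts inside the RE terminus and crosses the junction into
    the genomic flank (padded with adapter when the fragment is short);
    read 2 enters from the adapter at the opposite fragment end.  Somatic
    events draw their read multiplicity from the configured categorical
    distribution (capped at 5); germline/reference events draw Poisson
    with mean ``read_depth``.
    """
    rng = np.random.default_rng(seed)
    rl = config.read_length
    libraries: dict[str, list[tuple[str, str, str, str]]] = {}
    event_reads: dict[str, dict[str, int]] = {}
    for tissue in config.tissues:
        for fam in sorted(config.families):
            lib = library_id(tissue, fam)
            libraries[lib] = []
            event_reads[lib] = {}
    qual = "I" * rl
    som_counts = np.array(sorted(config.somatic_read_dist), dtype=int)
    som_probs = np.array(
        [config.somatic_read_dist[int(k)] for k in som_counts], dtype=float
    )
    truth_rows = []
    adapter_pad = (ADAPTER * ((rl // len(ADAPTER)) + 2))

    for fam_name in sorted(digests):
        digest = digests[fam_name]
        fam = FAMILIES[fam_name]
        prefix = fam.read_prefix
        for frag in digest.fragments:
            ev = frag.event
            total = 0
            for tissue in config.tissues:
                if tissue not in ev.tissues:
                    continue
                lib = library_id(tissue, fam_name)
                if not frag.amplifiable or config.read_depth == 0:
                    n = 0
                elif ev.origin == "somatic":
                    n = int(som_counts[rng.choice(len(som_counts), p=som_probs)])
                else:
                    n = int(rng.poisson(config.read_depth))
                if n:
                    event_reads[lib][ev.event_id] = n
                base1 = (prefix + frag.flank_out + adapter_pad)[:rl]
                base2 = (frag.mate_seq + adapter_pad)[:rl]
                for c in range(n):
                    rid = f"{ev.event_id}:{tissue}:{c}"
                    r1 = _inject_errors(base1, rng, config.error_rate)
                    r2 = _inject_errors(base2, rng, config.error_rate)
                    libraries[lib].append((rid, r1, r2, qual))
                total += n
            truth_rows.append(
                {
                    "chrom": ev.chrom,
                    "start": ev.position,
                    "end": ev.position + 1,
                    "name": ev.family,
                    "score": total,
                    "strand": ev.strand,
                    "class": ev.origin,
                    "tissue": ",".join(ev.tissues) if ev.origin == "somatic" else "all",
                    "family": ev.family,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "class", "tissue", "family",
        ],
    )
    rps = ReadPairSet(libraries, event_reads, truth)
    if outdir is not None:
        write_outputs(rps, config, Path(outdir))
    return rps


def write_outputs(rps: ReadPairSet, config: SimulationConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for lib in sorted(rps.libraries):
        pairs = rps.libraries[lib]
        with open(outdir / f"{lib}_R1.fastq", "w") as f1, open(
            outdir / f"{lib}_R2.fastq", "w"
        ) as f2:
            for rid, r1, r2, qual in pairs:
                f1.write(f"@{rid}/1\n{r1}\n+\n{qual}\n")
                f2.write(f"@{rid}/2\n{r2}\n+\n{qual}\n")
    with open(outdir / "truth.bed", "w") as fh:
        fh.write("#" + "\t".join(rps.truth.columns) + "\n")
        rps.truth.to_csv(fh, sep="\t", header=False, index=False)
    config.to_yaml(outdir / "config.yaml")


def simulate_experiment(
    config: SimulationConfig, seed: int, outdir: str | Path | None = None
) -> tuple[GenomeModel, list[InsertionEvent], dict[str, DigestResult], ReadPairSet]:
    """Run the full generator: genome, events, digestion, reads."""
    genome = build_genome(config, seed)
    events = plant_insertions(genome, config, seed + 1)
    digests = {
        fam: digest_and_amplify(genome, events, FAMILIES[fam], config)
        for fam in sorted(config.families)
    }
    reads = emit_reads(digests, config, seed + 2, outdir)
    if outdir is not None:
        outdir = Path(outdir)
        genome.write_fasta(outdir / "genome.fasta")
        genome.write_annotation(outdir / "genes.bed", outdir / "reference_res.bed")
    return genome, events, digests, reads
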