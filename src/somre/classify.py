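"""Cross-library classification of insertion calls.

An insertion call is *reference* when it sits at the junction-proximal
end of an annotated same-family RE; among the remaining (non-reference)
calls, one detected in exactly one tissue library is *potentially
somatic*, one detected in every library is *germline* (polymorphic or
novel germline), and one detected in an intermediate number of
libraries is kept apart as *ambiguous_multi_tissue* rather than being
silently folded into either extreme.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import AnnotationIndex, locate
from .calling import CallSet
from .families import FAMILIES
from .simulate import re_junction
from .utils import round_half_up

CLASS_LABELS = ("reference", "germline", "ambiguous_multi_tissue", "somatic")


@dataclass
class ClassifiedInsertion:
    chrom: str
    position: int
    strand: str
    family: str
    label: str
    libraries: dict[str, int] = field(default_factory=dict)  # library -> read count

    @property
    def read_count(self) -> int:
        return sum(self.libraries.values())


def _reference_junctions(
    re_annotation: pd.DataFrame, family: str
) -> dict[str, list[int]]:
    fam = FAMILIES[family]
    out: dict[str, list[int]] = {}
    sub = re_annotation[re_annotation["name"] == family]
    for _, row in sub.iterrows():
        j = re_junction(fam, int(row["start"]), int(row["end"]), row["strand"])
        out.setdefault(row["chrom"], []).append(j)
    for c in out:
        out[c].sort()
    return out


def _near(sorted_positions: list[int], pos: int, tolerance: int) -> bool:
    i = bisect_left(sorted_positions, pos)
    for j in (i - 1, i):
        if 0 <= j < len(sorted_positions) and abs(sorted_positions[j] - pos) <= tolerance:
            return True
    return False


def match_reference(
    callset: CallSet,
    re_annotation: pd.DataFrame,
    family: str,
    tolerance: int = 100,
) -> list[bool]:
    """Flag calls lying within ``tolerance`` bp of an annotated
    same-family RE junction."""
    junctions = _reference_junctions(re_annotation, family)
    return [
        _near(junctions.get(c.chrom, []), c.position, tolerance)
        for c in callset.calls
    ]


def classify(
    callsets: list[CallSet],
    family: str,
    re_annotation: pd.DataFrame,
    reference_tolerance: int = 100,
    merge_tolerance: int = 3,
) -> list[ClassifiedInsertion]:
    """Merge calls across libraries and assign each insertion one class.

    Calls co-located within ``merge_tolerance`` bp on the same
    chromosome and element strand are one insertion.  Classes partition
    the merged set: reference (matches the RE annotation), somatic
    (exactly one carrying library), germline (all libraries),
    ambiguous_multi_tissue (anything in between).
    """
    if len(callsets) < 2:
        raise ValueError("classification needs at least two libraries")
    libs = [cs.library for cs in callsets]
    if len(set(libs)) != len(libs):
        raise ValueError(f"duplicate library ids in {libs}")
    k = len(libs)
    junctions = _reference_junctions(re_annotation, family)

    pooled: dict[tuple[str, str], list[tuple[int, str, int]]] = {}
    for cs in callsets:
        for call in cs.calls:
            pooled.setdefault((call.chrom, call.strand), []).append(
                (call.position, cs.library, call.read_count)
            )

    out: list[ClassifiedInsertion] = []
    for (chrom, strand), entries in sorted(pooled.items()):
        entries.sort()
        cluster: list[tuple[int, str, int]] = []

        def flush() -> None:
            if not cluster:
                return
            weights: dict[int, int] = {}
            by_lib: dict[str, int] = {}
            for pos, lib, cnt in cluster:
                weights[pos] = weights.get(pos, 0) + cnt
                by_lib[lib] = by_lib.get(lib, 0) + cnt
            modal = min(weights, key=lambda p: (-weights[p], p))
            if _near(junctions.get(chrom, []), modal, reference_tolerance):
                label = "reference"
            elif len(by_lib) == 1:
                label = "somatic"
            elif len(by_lib) == k:
                label = "germline"
            else:
                label = "ambiguous_multi_tissue"
            out.append(
                ClassifiedInsertion(chrom, modal, strand, family, label, by_lib)
            )

        last = None
        for pos, lib, cnt in entries:
            if last is not None and pos - last > merge_tolerance:
                flush()
                cluster = []
            cluster.append((pos, lib, cnt))
            last = pos
        flush()
    out.sort(key=lambda c: (c.chrom, c.position, c.strand))
    return out


def classified_frame(classified: list[ClassifiedInsertion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.position,
                "end": c.position + 1,
                "name": c.label,
                "score": c.read_count,
                "strand": c.strand,
                "class": c.label,
                "family": c.family,
                "libraries": ",".join(sorted(c.libraries)),
                "library_counts": ",".join(
                    f"{lib}:{n}" for lib, n in sorted(c.libraries.items())
                ),
            }
            for c in classified
        ],
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "class", "family", "libraries", "library_counts",
        ],
    )


def summarize(
    classified: list[ClassifiedInsertion],
    total_reads: dict[str, int],
    index: AnnotationIndex | None = None,
) -> pd.DataFrame:
    """Per-library summary of somatic burden and genomic distribution.

    ``total_reads`` maps library id to its high-quality read count (the
    normalization denominator).  The normalized rate is
    100 x somatic reads / total reads, rounded half-up to four decimals;
    genic and promoter fractions are percentages of somatic insertions,
    rounded to two decimals.  A zero-read library reports a missing
    (NaN) rate rather than zero.
    """
    rows = []
    for lib in sorted(total_reads):
        somatic = [c for c in classified if c.label == "somatic" and lib in c.libraries]
        somatic_reads = sum(c.libraries[lib] for c in somatic)
        n_som = len(somatic)
        total = total_reads[lib]
        rate = (
            round_half_up(100.0 * somatic_reads / total, 4) if total > 0 else np.nan
        )
        row = {
            "library": lib,
            "total_reads": total,
            "somatic_reads": somatic_reads,
            "somatic_insertions": n_som,
            "rate_pct": rate,
        }
        if index is not None:
            _, tallies = locate(somatic, index)
            genic, promoter = tallies["genic"], tallies["promoter"]
            row.update(
                {
                    "genic_n": genic,
                    "genic_pct": (
                        round_half_up(100.0 * genic / n_som, 2) if n_som else np.nan
                    ),
                    "promoter_n": promoter,
                    "promoter_pct": (
                        round_half_up(100.0 * promoter / n_som, 2) if n_som else np.nan
                    ),
                    "genic_co": tallies["genic_co"],
                    "genic_counter": tallies["genic_counter"],
                    "promoter_co": tallies["promoter_co"],
                    "promoter_counter": tallies["promoter_counter"],
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
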