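"""Packaged fixture of the published per-tissue count tables.

These TSVs transcribe the printed summary tables of the source study
(per-library read totals, somatic-insertion counts, genic/promoter
tallies and orientation counts for five tissues x two RE families, plus
the reference-RE detection fractions).  Every derived quantity — rates,
percentages, sums, means and the whole statistical battery — is
recomputed from the raw counts by :func:`somre.report.paper_check`.

The loaders verify a SHA-256 checksum so silent fixture edits fail
loudly.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

_CHECKSUMS = {
    "table1.tsv": "7e582af09522aaf67cd63da20f5d9b066ea6b4568ae2a652959f75f5b3ae979a",
    "table2.tsv": "1bf78ee3c10fe4f07fd1265e58d4778635f6a77aa3752d3d4ac3bfa6896a16ea",
    "reference_detection.tsv": "ee73ebe59c4c1f57ef13c5220ecb018cbbd39fac0a6bc5155ce1d6bbbf5d58f3",
}

TISSUES = ("cerebellum", "frontal_cortex", "SVZ", "DG", "myocardium")


def _load(name: str) -> pd.DataFrame:
    data = resources.files("somre.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name} checksum mismatch ({digest}); the packaged "
            "count tables must not be edited"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(data), sep="\t", na_values=["NA"])


def load_table1() -> pd.DataFrame:
    """Per-library counts: reads, somatic insertions, genic/promoter tallies."""
    return _load("table1.tsv")


def load_table2() -> pd.DataFrame:
    """Orientation counts per family x compartment x tissue."""
    return _load("table2.tsv")


def load_reference_detection() -> pd.DataFrame:
    """Detected / annotated reference-RE copies per family."""
    return _load("reference_detection.tsv")


def library_counts(family: str) -> dict[str, tuple[int, int]]:
    """(somatic reads, total reads) per tissue for one family."""
    t1 = load_table1()
    sub = t1[t1["family"] == family]
    return {
        row["tissue"]: (int(row["somatic_reads"]), int(row["total_reads"]))
        for _, row in sub.iterrows()
    }
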