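"""Retroelement family models for junction-library work.

A suppression-PCR junction library recovers, for every insertion of a
target subfamily, one end of the element ("the terminus") together with
the adjacent unique genomic sequence ("the flank").  Which end is
recovered is a property of the wet-lab design: L1 libraries are built
from the L1 3'-terminus (LINEs are frequently 5'-truncated, so only the
3' end is reliably present), while Alu libraries recover the 5'-flank
(avoiding the 3' polyA tract).

The consensus sequences below are synthetic stand-ins: short, fixed
sequences that embed the subfamily-diagnostic PCR primer sites verbatim
and deliberately contain no recognition site of the library's own
restriction enzymes, so that the junction fragment always retains the
primer sites.  They are not the biological L1Hs/AluYa5 consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A blunt cutter that cleaves in the middle of its recognition site."""

    name: str
    site: str

    @property
    def cut_offset(self) -> int:
        return len(self.site) // 2


ALUI = RestrictionEnzyme("AluI", "AGCT")
HAEIII = RestrictionEnzyme("HaeIII", "GGCC")
RSAI = RestrictionEnzyme("RsaI", "GTAC")

ENZYMES = {e.name: e for e in (ALUI, HAEIII, RSAI)}

# Subfamily-diagnostic primers (5'->3', element sense).
PRIMER_3_L1HS = "GAGATATACCTAATGCTAGATGACAC"
PRIMER_3_END_L1 = "GCACATGTACCCTAAAACTTAGAGTA"
PRIMER_AY107 = "TCACCGTTTTAGCCGGGA"
PRIMER_AY24 = "AGGCGTGAGCCACCGCGC"
PRIMER_AY18 = "GAGCCACCGCGCCCGGC"

# Suppression adapter (ligated to every restriction fragment end).
ADAPTER = "TGTAGCGTGAAGACGACAGAAAGGGCGTGGTGCGGAGGGCGGT"


@dataclass(frozen=True)
class REFamilyModel:
    """One target retroelement subfamily and its library chemistry.

    ``terminus`` is the junction-proximal consensus segment, written in
    element sense; for a ``flank_side == "3p"`` family the junction is at
    its right end, for ``"5p"`` at its left end.  ``body`` is the
    element-internal sequence continuing away from the junction (it
    carries the element-side restriction site that bounds the fragment).
    ``read_terminus_len`` is the fixed number of terminus bases the
    sequencer reads before crossing the junction; it is set by the nested
    PCR primer position and therefore identical for all reads of a
    library.
    """

    name: str
    terminus: str
    body: str
    primer_sites: tuple[str, ...]
    flank_side: str  # "3p": flank follows the element 3' end; "5p": precedes the 5' end
    enzymes: tuple[RestrictionEnzyme, ...]
    read_terminus_len: int = 30

    def __post_init__(self) -> None:
        if self.flank_side not in ("3p", "5p"):
            raise ValueError(f"flank_side must be '3p' or '5p', got {self.flank_side!r}")
        if len(self.terminus) < 60:
            raise ValueError("consensus terminus must be at least 60 bp")
        for primer in self.primer_sites:
            if primer not in self.terminus:
                raise ValueError(f"primer {primer} is not a substring of the terminus")

    @property
    def element_sequence(self) -> str:
        """Full synthetic element in element sense (5'->3')."""
        if self.flank_side == "3p":
            return self.body + self.terminus
        return self.terminus + self.body

    @property
    def read_prefix(self) -> str:
        """The exact element-derived prefix of read 1 (junction at its end).

        Read 1 is primed inside the element and reads outward across the
        junction, so for a 3'-flanked family it reads the element plus
        strand and for a 5'-flanked family the minus strand.
        """
        n = self.read_terminus_len
        if self.flank_side == "3p":
            return self.terminus[-n:]
        return revcomp(self.terminus[:n])


# Synthetic L1Hs 3'-terminus: fillers + diagnostic primers + a fixed 30 bp
# junction-proximal tail.  Contains no AluI (AGCT) or HaeIII (GGCC) site.
_L1_TERMINUS = (
    "CATTCCATTC"
    + PRIMER_3_L1HS
    + "ATTCCATC"
    + PRIMER_3_END_L1
    + "ACCCATTCACTTCCATTCAACCATCCCAAA"
)
# Element body 5' of the terminus with one deliberate AluI site 22 bp in,
# bounding the element side of the junction fragment.
_L1_BODY = (
    "CCATTCCATTCCATTCCATT" + "AGCT"
    + "CATTCCATTCCATTCCATTCCATTCCATTCCATTCCATTCCATTCCATTCCATTC"
)

L1HS = REFamilyModel(
    name="L1Hs",
    terminus=_L1_TERMINUS,
    body=_L1_BODY,
    primer_sites=(PRIMER_3_L1HS, PRIMER_3_END_L1),
    flank_side="3p",
    enzymes=(ALUI, HAEIII),
)

# Synthetic AluYa5 5'-terminus: 30 bp junction-proximal head, then the
# diagnostic primers (AY24 followed by CCGGC also spells out AY18).
# Contains no AluI (AGCT) or RsaI (GTAC) site.
_ALU_TERMINUS = (
    "GGCCTCAATTTCCTCATTTGCAAAATGGGA"
    + "CCTTGG"
    + PRIMER_AY107
    + "CTTT"
    + PRIMER_AY24
    + "CCGGC"
)
_ALU_BODY = (
    "CCTTCCTTCCTTCCTTCCTT" + "GTAC"
    + "CCTTCCTTCCTTCCTTCCTTCCTTCCTTCCTT"
)

ALUYA5 = REFamilyModel(
    name="AluYa5",
    terminus=_ALU_TERMINUS,
    body=_ALU_BODY,
    primer_sites=(PRIMER_AY107, PRIMER_AY24, PRIMER_AY18),
    flank_side="5p",
    enzymes=(ALUI, RSAI),
)

FAMILIES: dict[str, REFamilyModel] = {f.name: f for f in (L1HS, ALUYA5)}
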