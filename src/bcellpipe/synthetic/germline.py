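"""Deterministic synthetic germline V/J reference for the kappa light chain.

Sequences are generated reproducibly from the gene name alone, so that the
same reference can be rebuilt anywhere without shipping sequence files.
Each V gene encodes amino acids 1-96 of the mature chain; the last eight
residues (numbered 89-96) form the V-encoded part of CDR3 and carry the
gene- and strain-specific motif used for cross-strain comparisons.  J genes
encode residues 98-107; residue 97 sits at the V-J joint and is supplied by
the junction codon of each rearrangement.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

# One fixed codon per amino acid keeps the generated references deterministic.
# L->CTG and S->AGC are relied on by the junction-variant machinery.
CODON_FOR = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
]

#: first residue of CDR3 in the report numbering
CDR3_START = 89
#: V-J joint residue of the dominant rearrangement
JOINT_POSITION = 97
#: number of CDR3 residues encoded by the V gene (positions 89..96)
V_CDR3_LEN = 8
#: amino-acid spans (1-based, inclusive) used for mutation bookkeeping
V_REGIONS = {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 96)}

V_FRAMEWORK_AA = 88   # residues 1..88
J_AA = 10             # residues 98..107

# Strain-specific CDR3 motifs (residues 89..96).  Positions 91 (Q) and 92 (Y)
# are conserved across strains; charge-altering differences sit at 90/93/94
# for Vk4-74 and 93/95 for Vk4-57.
CDR3_MOTIFS = {
    "NOD": {"Vk4-74": "QQQYDSSP", "Vk4-57": "QQQYHPDP"},
    "B6": {"Vk4-74": "QHQYHRSP", "Vk4-57": "QQQYSPYP"},
}
DEFAULT_CDR3_MOTIF = "QQGYSSTP"

DEFAULT_V_GENES = [
    "Vk4-74", "Vk4-57", "Vk4-56", "Vk4-91", "Vk1-110", "Vk3-1",
    "Vk14-111", "Vk16-104", "Vk17-127", "Vk19-93", "Vk3-7",
]
DEFAULT_J_GENES = ["Jk1", "Jk2", "Jk4", "Jk5"]

#: id of the single fixed heavy chain carried by every simulated cell
HEAVY_CHAIN_ID = "VH-fixed"


def _gene_rng(name: str) -> np.random.Generator:
    return np.random.default_rng(zlib.crc32(name.encode("ascii")))


def _random_codons(rng: np.random.Generator, n_aa: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_aa)
    return "".join(SENSE_CODONS[i] for i in idx)


def encode_aa(aa: str) -> str:
    """Encode an amino-acid string with the fixed codon table."""
    return "".join(CODON_FOR[a] for a in aa)


@dataclass(frozen=True)
class GermlineSegment:
    name: str
    segment_type: str  # "V" or "J"
    seq: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class GermlineReference:
    """Ordered V and J segment collections; order breaks alignment ties."""

    v_segments: list[GermlineSegment] = field(default_factory=list)
    j_segments: list[GermlineSegment] = field(default_factory=list)
    strain: str = "NOD"

    def get(self, name: str) -> GermlineSegment:
        for seg in self.v_segments + self.j_segments:
            if seg.name == name:
                return seg
        raise KeyError(f"unknown germline segment: {name!r}")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.v_segments + self.j_segments]


def make_v_segment(name: str, strain: str = "NOD") -> GermlineSegment:
    rng = _gene_rng(name)
    framework = _random_codons(rng, V_FRAMEWORK_AA)
    motif = CDR3_MOTIFS.get(strain, {}).get(name, DEFAULT_CDR3_MOTIF)
    if len(motif) != V_CDR3_LEN:
        raise ValueError(f"CDR3 motif for {name} must be {V_CDR3_LEN} aa")
    return GermlineSegment(name, "V", framework + encode_aa(motif))


def make_j_segment(name: str) -> GermlineSegment:
    rng = _gene_rng(name)
    return GermlineSegment(name, "J", _random_codons(rng, J_AA))


def make_heavy_chain() -> GermlineSegment:
    rng = _gene_rng(HEAVY_CHAIN_ID)
    return GermlineSegment(HEAVY_CHAIN_ID, "V", _random_codons(rng, 110))


def default_reference(strain: str = "NOD") -> GermlineReference:
    """Build the default kappa V/J reference for one strain."""
    if strain not in ("NOD", "B6"):
        raise ValueError(f"unknown strain {strain!r}; expected 'NOD' or 'B6'")
    return GermlineReference(
        v_segments=[make_v_segment(n, strain) for n in DEFAULT_V_GENES],
        j_segments=[make_j_segment(n) for n in DEFAULT_J_GENES],
        strain=strain,
    )
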