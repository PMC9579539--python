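"""CDR3 translation and numbering, residue charge classes, and cross-strain
polymorphism comparison.

Numbering is anchored at the CDR3 start: positions run consecutively from
89, which places the V-J joint residue of the dominant rearrangement at 97.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from ..synthetic.germline import CDR3_START
from .align import SegmentCall

NEGATIVE = "negative"
NEUTRAL = "neutral"
POSITIVE = "positive"

_CHARGE = {**{a: NEUTRAL for a in "ACFGILMNPQSTVWY"},
           "D": NEGATIVE, "E": NEGATIVE,
           "H": POSITIVE, "K": POSITIVE, "R": POSITIVE}


def charge_class(residue: str) -> str:
    """Classify a one-letter amino acid as negative / neutral / positive."""
    try:
        return _CHARGE[residue.upper()]
    except (KeyError, AttributeError):
        raise ValueError(f"invalid amino-acid letter: {residue!r}") from None


@dataclass
class NumberedCdr3:
    aa: str                    # empty when frameshifted
    positions: list[int] = field(default_factory=list)
    frameshift: bool = False
    nonproductive: bool = False  # in-frame stop codon

    def residue_at(self, position: int) -> str:
        if position not in self.positions:
            raise KeyError(f"position {position} not in CDR3 numbering")
        return self.aa[self.positions.index(position)]


def extract_cdr3(contig_nt: str, call: SegmentCall) -> NumberedCdr3:
    """Translate the junction span and number residues from 89 upward."""
    start, end = call.junction_span
    if not (0 <= start <= end <= len(contig_nt)):
        raise ValueError("junction span outside contig bounds")
    nt = contig_nt[start:end]
    if len(nt) % 3 != 0:
        return NumberedCdr3(aa="", frameshift=True)
    aa = str(Seq(nt).translate())
    if "*" in aa:
        return NumberedCdr3(
            aa=aa, positions=list(range(CDR3_START, CDR3_START + len(aa))),
            nonproductive=True,
        )
    return NumberedCdr3(aa=aa, positions=list(range(CDR3_START, CDR3_START + len(aa))))


@dataclass
class PolymorphismReport:
    """Per-position consensus comparison between two strains' CDR3 sets."""

    positions: pd.DataFrame  # position, residue_a, residue_b, identical,
                             # charge_a, charge_b, charge_altering
    length_mismatch: bool = False

    @property
    def charge_altering_positions(self) -> list[int]:
        if self.length_mismatch:
            return []
        flagged = self.positions[self.positions["charge_altering"]]
        return list(flagged["position"])

    @property
    def conserved_positions(self) -> list[int]:
        if self.length_mismatch:
            return []
        return list(self.positions[self.positions["identical"]]["position"])


def _consensus(cdr3s: list[str]) -> str:
    lengths = {len(s) for s in cdr3s}
    if len(lengths) != 1:
        raise ValueError("inconsistent CDR3 lengths within a strain set")
    length = lengths.pop()
    out = []
    for i in range(length):
        column = [s[i] for s in cdr3s]
        out.append(max(set(column), key=column.count))
    return "".join(out)


def compare_strains(cdr3s_a: list[str], cdr3s_b: list[str]) -> PolymorphismReport:
    """Compare per-position consensus residues of two strains' CDR3 sets.

    Identical positions are never flagged; positions whose residues fall in
    different charge classes are marked charge-altering.  Sets whose
    consensus lengths differ yield a length-mismatch report with no
    positional table.
    """
    if not cdr3s_a or not cdr3s_b:
        raise ValueError("both strain CDR3 sets must be non-empty")
    cons_a, cons_b = _consensus(cdr3s_a), _consensus(cdr3s_b)
    if len(cons_a) != len(cons_b):
        return PolymorphismReport(positions=pd.DataFrame(), length_mismatch=True)

    rows = []
    for i, (ra, rb) in enumerate(zip(cons_a, cons_b)):
        ca, cb = charge_class(ra), charge_class(rb)
        identical = ra == rb
        rows.append({
            "position": CDR3_START + i,
            "residue_a": ra, "residue_b": rb,
            "identical": identical,
            "charge_a": ca, "charge_b": cb,
            "charge_altering": (not identical) and ca != cb,
        })
    return PolymorphismReport(positions=pd.DataFrame(rows))
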