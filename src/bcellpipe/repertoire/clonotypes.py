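"""Clonotype tables: per-mouse and mean-across-mice V/J frequencies.

A clonotype is the V-gene x J-gene pair.  Pairs whose pooled frequency is
below 0.2% are collected into an "others" bin.  Mean frequencies weight
mice equally, not by cell count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ..datatypes import UNASSIGNED, ContigTable
from ..synthetic.germline import CDR3_START
from .align import SegmentCall
from .cdr3 import extract_cdr3

logger = logging.getLogger(__name__)

OTHERS_LABEL = "others"
OTHERS_THRESHOLD = 0.002  # pooled-frequency cutoff for the rare-pair bin


@dataclass
class ClonotypeTable:
    cells: pd.DataFrame          # barcode, donor, v_gene, j_gene, pair, cdr3_aa
    v_freq: pd.DataFrame         # index: V gene; columns: mouse<i>..., mean
    j_freq: pd.DataFrame
    pair_freq: pd.DataFrame      # rare pairs binned under "others"
    kappa_fraction: float
    n_excluded: int

    def mean_frequency(self, table: str, key: str) -> float:
        freq = {"v": self.v_freq, "j": self.j_freq, "pair": self.pair_freq}[table]
        return float(freq.loc[key, "mean"]) if key in freq.index else 0.0

    @property
    def top_pair(self) -> str:
        real = self.pair_freq.drop(index=OTHERS_LABEL, errors="ignore")
        return str(real["mean"].idxmax())


def _frequency_table(cells: pd.DataFrame, column: str) -> pd.DataFrame:
    donors = sorted(cells["donor"].unique())
    out = {}
    for d in donors:
        sub = cells[cells["donor"] == d]
        out[f"mouse{d}"] = sub[column].value_counts(normalize=True)
    freq = pd.DataFrame(out).fillna(0.0)
    freq["mean"] = freq[[f"mouse{d}" for d in donors]].mean(axis=1)
    return freq.sort_values("mean", ascending=False)


def build_clonotype_table(
    contigs: ContigTable,
    calls: dict[str, SegmentCall],
    assignments: dict[str, int] | None = None,
    others_threshold: float = OTHERS_THRESHOLD,
) -> ClonotypeTable:
    """Aggregate kappa segment calls into per-mouse frequency tables.

    ``calls`` maps kappa contig ids to their germline assignment;
    ``assignments`` maps barcodes to donor indices and overrides the table's
    own donor column (cells without an assigned donor are excluded).
    """
    light = contigs.df[contigs.df["chain"].isin(["IGK", "IGL"])]
    kappa = light[light["chain"] == "IGK"]
    kappa_fraction = float(len(kappa) / len(light)) if len(light) else float("nan")

    rows = []
    n_excluded = 0
    for _, rec in kappa.iterrows():
        donor = rec["donor"]
        if assignments is not None:
            donor = assignments.get(rec["barcode"], UNASSIGNED)
        if donor == UNASSIGNED:
            n_excluded += 1
            continue
        call = calls.get(rec["contig_id"])
        if call is None:
            n_excluded += 1
            continue
        cdr3 = extract_cdr3(contigs.sequences[rec["contig_id"]], call)
        rows.append({
            "barcode": rec["barcode"], "donor": int(donor),
            "v_gene": call.v_gene, "j_gene": call.j_gene,
            "pair": f"{call.v_gene}/{call.j_gene}",
            "cdr3_aa": cdr3.aa,
        })
    if n_excluded:
        logger.info("excluded %d kappa contigs without donor or call", n_excluded)
    if not rows:
        raise ValueError("no assignable kappa contigs")

    cells = pd.DataFrame(rows)
    pooled = cells["pair"].value_counts(normalize=True)
    rare = set(pooled[pooled < others_threshold].index)
    cells["pair_binned"] = cells["pair"].where(~cells["pair"].isin(rare), OTHERS_LABEL)

    return ClonotypeTable(
        cells=cells,
        v_freq=_frequency_table(cells, "v_gene"),
        j_freq=_frequency_table(cells, "j_gene"),
        pair_freq=_frequency_table(cells, "pair_binned"),
        kappa_fraction=kappa_fraction,
        n_excluded=n_excluded,
    )


def position_composition(
    table: ClonotypeTable,
    position: int = 97,
    v_gene: str | None = None,
    j_gene: str | None = None,
) -> pd.Series:
    """Residue frequencies at one numbered CDR3 position, over filtered cells."""
    cells = table.cells
    if v_gene is not None:
        cells = cells[cells["v_gene"] == v_gene]
    if j_gene is not None:
        cells = cells[cells["j_gene"] == j_gene]
    if cells.empty:
        raise ValueError("empty selection for position composition")
    idx = position - CDR3_START
    residues = [aa[idx] for aa in cells["cdr3_aa"] if len(aa) > idx >= 0]
    if not residues:
        raise ValueError(f"position {position} outside every selected CDR3")
    return pd.Series(residues).value_counts(normalize=True)
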