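"""Kappa light-chain repertoire simulator.

Cells are drawn from a multinomial over rearrangement specs (V gene, J gene,
junction variant).  Each cell receives one productive kappa contig built as
germline V + junction codon + germline J, plus a single fixed heavy chain
shared by every cell.  Junction variation is restricted to one alternative
codon at the V-J joint (leucine vs serine at numbered position 97), matching
the dimorphism the default configuration models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..datatypes import UNASSIGNED, ContigTable
from .germline import (
    CODON_FOR,
    GermlineReference,
    default_reference,
    make_heavy_chain,
)


@dataclass(frozen=True)
class ClonotypeSpec:
    """One rearrangement with an optional junction-variant label."""

    v_gene: str
    j_gene: str
    variant: str          # amino acid placed at the V-J joint (position 97)
    probability: float

    @property
    def label(self) -> str:
        return f"{self.v_gene}/{self.j_gene}:{self.variant}"

    @property
    def joint_codon(self) -> str:
        return CODON_FOR[self.variant]


def default_clonotype_table() -> list[ClonotypeSpec]:
    """Default rearrangement probabilities.

    Five dominant rearrangements (the top pair split into L/S junction
    variants) plus rare "others", each below 0.2%, placed so that the V and
    J marginal frequencies come out at 87.9% (Vk4-74) and 72.2% (Jk5).
    """
    specs = [
        ClonotypeSpec("Vk4-74", "Jk5", "L", 0.353),
        ClonotypeSpec("Vk4-74", "Jk5", "S", 0.288),
        ClonotypeSpec("Vk4-74", "Jk2", "L", 0.221),
        ClonotypeSpec("Vk4-57", "Jk5", "L", 0.074),
        ClonotypeSpec("Vk4-57", "Jk2", "L", 0.032),
    ]
    # rare clonotypes: 1.7% more Vk4-74 mass on minor J genes
    for i, j in enumerate(["Jk1", "Jk4"] * 5):
        specs.append(ClonotypeSpec("Vk4-74", j, "L" if i % 2 else "S", 0.0017))
    # 0.7% more Jk5 mass on minor V genes
    for v in ["Vk4-56", "Vk4-91", "Vk1-110", "Vk3-1"]:
        specs.append(ClonotypeSpec(v, "Jk5", "L", 0.00175))
    # fully minor V/J combinations
    for v, j in [
        ("Vk14-111", "Jk1"), ("Vk16-104", "Jk4"), ("Vk17-127", "Jk1"),
        ("Vk19-93", "Jk4"), ("Vk3-7", "Jk1"),
    ]:
        specs.append(ClonotypeSpec(v, j, "L", 0.0016))
    return specs


@dataclass
class RepertoireConfig:
    cells_per_mouse: tuple[int, ...] = (2081, 1947, 63)
    clonotypes: list[ClonotypeSpec] = field(default_factory=default_clonotype_table)
    mutation_rate: float = 0.0
    unassigned_fraction: float = 0.0012
    strain: str = "NOD"

    def __post_init__(self) -> None:
        total_p = sum(c.probability for c in self.clonotypes)
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError(f"clonotype probabilities sum to {total_p}, not 1")
        if any(n < 0 for n in self.cells_per_mouse):
            raise ValueError("cell counts must be non-negative")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")
        if not 0.0 <= self.unassigned_fraction < 1.0:
            raise ValueError("unassigned fraction must lie in [0, 1)")

    @property
    def n_assigned(self) -> int:
        return int(sum(self.cells_per_mouse))

    @property
    def n_unassigned(self) -> int:
        return int(round(self.unassigned_fraction * self.n_assigned))


def _draw_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(bases, size=16)) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        alphabet = "ACGT"
        for i in np.flatnonzero(hit):
            choices = [b for b in alphabet if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_repertoire(
    config: RepertoireConfig, seed: int, reference: GermlineReference | None = None
) -> tuple[ContigTable, pd.DataFrame]:
    """Simulate per-cell contigs and return them with the ground-truth table.

    Returns a :class:`ContigTable` (one kappa and one heavy contig per cell)
    and a truth DataFrame with columns ``barcode, donor, v_gene, j_gene,
    variant, clonotype``.  Donor 0 marks the configured unassigned fraction.
    """
    if reference is None:
        reference = default_reference(config.strain)
    for spec in config.clonotypes:
        reference.get(spec.v_gene)  # raises KeyError on unknown germline id
        reference.get(spec.j_gene)

    rng = np.random.default_rng(seed)
    donors = np.concatenate(
        [np.full(n, i + 1) for i, n in enumerate(config.cells_per_mouse)]
        + [np.full(config.n_unassigned, UNASSIGNED)]
    ).astype(int)
    n_cells = donors.size
    barcodes = _draw_barcodes(rng, n_cells)

    probs = np.array([c.probability for c in config.clonotypes])
    clono_idx = rng.choice(len(config.clonotypes), size=n_cells, p=probs)

    heavy = make_heavy_chain()
    rows: list[dict] = []
    seqs: dict[str, str] = {}
    truth_rows: list[dict] = []
    for bc, donor, ci in zip(barcodes, donors, clono_idx):
        spec = config.clonotypes[ci]
        v = reference.get(spec.v_gene)
        j = reference.get(spec.j_gene)
        contig_nt = _mutate(rng, v.seq + spec.joint_codon + j.seq, config.mutation_rate)
        cdr3_nt = contig_nt[len(v.seq) - 24: len(v.seq) + 3]
        cdr3_aa = _translate(cdr3_nt)

        kappa_id = f"{bc}_contig_1"
        heavy_id = f"{bc}_contig_2"
        rows.append({
            "barcode": bc, "donor": int(donor), "chain": "IGK",
            "v_gene": spec.v_gene, "j_gene": spec.j_gene,
            "cdr3_nt": cdr3_nt, "cdr3_aa": cdr3_aa, "contig_id": kappa_id,
        })
        rows.append({
            "barcode": bc, "donor": int(donor), "chain": "IGH",
            "v_gene": heavy.name, "j_gene": heavy.name,
            "cdr3_nt": "", "cdr3_aa": "", "contig_id": heavy_id,
        })
        seqs[kappa_id] = contig_nt
        seqs[heavy_id] = heavy.seq
        truth_rows.append({
            "barcode": bc, "donor": int(donor), "v_gene": spec.v_gene,
            "j_gene": spec.j_gene, "variant": spec.variant,
            "clonotype": f"{spec.v_gene}/{spec.j_gene}",
        })

    table = ContigTable(pd.DataFrame(rows), seqs)
    truth = pd.DataFrame(truth_rows)
    return table, truth


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    if len(nt) % 3 != 0:
        return ""
    return str(Seq(nt).translate())
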