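"""Shared tabular and kinetic data containers used across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns every contig annotation table must carry
CONTIG_COLUMNS = ["barcode", "donor", "chain", "v_gene", "j_gene", "cdr3_nt", "cdr3_aa", "contig_id"]

#: chain values accepted by the readers
VALID_CHAINS = {"IGH", "IGK", "IGL"}

#: donor code meaning "no hashtag truth / unassigned"
UNASSIGNED = 0


@dataclass
class ContigTable:
    """Per-cell contig annotations plus the contig nucleotide sequences.

    ``df`` has one row per contig with :data:`CONTIG_COLUMNS`; ``donor`` is a
    1-based hashtag index with 0 meaning unassigned.  ``sequences`` maps
    ``contig_id`` to the full contig nucleotide sequence.
    """

    df: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CONTIG_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"contig table missing required columns: {missing}")

    @property
    def barcodes(self) -> list[str]:
        return list(self.df["barcode"].unique())

    def chain(self, chain: str) -> pd.DataFrame:
        return self.df[self.df["chain"] == chain]

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SensorgramSet:
    """Per-concentration SPR traces.

    ``df`` columns: ``time_s`` (s), ``ru`` (RU), ``conc_M`` (M) and ``phase``
    in ``{"baseline", "assoc", "dissoc"}``.  Time is strictly increasing
    within each concentration trace and phases are contiguous.
    """

    df: pd.DataFrame
    association_s: float
    dissociation_s: float

    def __post_init__(self) -> None:
        required = {"time_s", "ru", "conc_M", "phase"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"sensorgram table missing columns: {sorted(missing)}")
        for conc, grp in self.df.groupby("conc_M"):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"time not strictly increasing for C={conc}")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.df["conc_M"].unique())

    def trace(self, conc: float) -> pd.DataFrame:
        return self.df[self.df["conc_M"] == conc]


@dataclass
class KineticParameters:
    """1:1 Langmuir kinetic constants with fit diagnostics.

    ka in 1/(M*s), kd in 1/s, Rmax in RU.  ``kD`` is always kd/ka (M).
    """

    ka: float
    kd: float
    rmax: float
    ka_se: float = float("nan")
    kd_se: float = float("nan")
    rmax_se: float = float("nan")
    residual_rms: float = float("nan")

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValueError("ka, kd and Rmax must all be positive")

    @property
    def kD(self) -> float:
        return self.kd / self.ka

    def as_dict(self) -> dict[str, float]:
        return {
            "ka": self.ka, "kd": self.kd, "KD": self.kD, "rmax": self.rmax,
            "ka_se": self.ka_se, "kd_se": self.kd_se, "rmax_se": self.rmax_se,
            "residual_rms": self.residual_rms,
        }


@dataclass
class ElisaCurve:
    """One ELISA titration: dilution folds (increasing) and OD450 values."""

    dilution: np.ndarray
    od450: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.dilution = np.asarray(self.dilution, dtype=float)
        self.od450 = np.asarray(self.od450, dtype=float)
        if self.dilution.size < 2:
            raise ValueError("ELISA curve needs at least 2 points")
        if self.dilution.size != self.od450.size:
            raise ValueError("dilution and OD vectors differ in length")
        if np.any(np.diff(self.dilution) <= 0):
            raise ValueError("dilution series must be strictly increasing")
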