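"""Donor assignment from hashtag UMI counts.

Counts are CLR-normalized per cell and each hashtag gets a detection
threshold estimated from its background population (cells whose strongest
hashtag is a different one), as mean + k*SD of those background CLR values.
A cell is a singlet of its top hashtag when that hashtag is above threshold
and clears every other above-threshold hashtag by the configured margin; a
second above-threshold hashtag within the margin makes a multiplet, and a
cell with nothing above threshold is unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STATE_SINGLET = "singlet"
STATE_MULTIPLET = "multiplet"
STATE_UNASSIGNED = "unassigned"


@dataclass
class DemuxParams:
    k: float = 2.0            # SD multiplier for the background threshold
    margin: float = 1.0       # CLR gap required over the runner-up
    thresholds: np.ndarray | None = None  # explicit per-hashtag overrides

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be non-negative")


@dataclass
class DonorAssignment:
    """Per-cell demultiplexing call with the normalized score matrix."""

    table: pd.DataFrame       # columns: cell, state, donor (1-based, 0 if n/a)
    clr: pd.DataFrame         # cells x hashtags CLR values
    thresholds: np.ndarray

    @property
    def donors(self) -> np.ndarray:
        return self.table["donor"].to_numpy()

    def counts_by_donor(self) -> pd.Series:
        singlets = self.table[self.table["state"] == STATE_SINGLET]
        return singlets["donor"].value_counts().sort_index()


def clr_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio per cell with pseudocount 1.

    Each cell's counts are mapped to log(x+1) minus the cell's mean log, so
    a cell with identical counts on every hashtag scores 0 everywhere.
    """
    if matrix.size == 0:
        raise ValueError("empty hashtag matrix")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("hashtag counts must be non-negative")
    logged = np.log(matrix.to_numpy(dtype=float) + 1.0)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)


def _background_thresholds(clr: np.ndarray, k: float) -> np.ndarray:
    """Per-hashtag threshold = mean + k*SD over cells topping another hashtag."""
    top = clr.argmax(axis=1)
    n_hashtags = clr.shape[1]
    thresholds = np.empty(n_hashtags)
    for h in range(n_hashtags):
        bg = clr[top != h, h]
        if bg.size < 2:  # degenerate panel: fall back to the global spread
            bg = clr[:, h]
        thresholds[h] = bg.mean() + k * bg.std(ddof=1 if bg.size > 1 else 0)
    return thresholds


def demultiplex(matrix: pd.DataFrame, params: DemuxParams | None = None) -> DonorAssignment:
    """Assign each cell to a hashtag, a multiplet, or unassigned."""
    if params is None:
        params = DemuxParams()
    if matrix.shape[1] < 2:
        raise ValueError("demultiplexing needs at least 2 hashtags")

    clr_df = clr_normalize(matrix)
    clr = clr_df.to_numpy()
    if params.thresholds is not None:
        thresholds = np.asarray(params.thresholds, dtype=float)
        if thresholds.size != clr.shape[1]:
            raise ValueError("threshold vector length must match hashtag count")
    else:
        thresholds = _background_thresholds(clr, params.k)

    n_cells = clr.shape[0]
    above = clr > thresholds[None, :]
    top = clr.argmax(axis=1)
    top_val = clr[np.arange(n_cells), top]
    # strongest competitor among the *other* above-threshold hashtags
    masked = np.where(above, clr, -np.inf)
    masked[np.arange(n_cells), top] = -np.inf
    competitor = masked.max(axis=1)

    top_above = above[np.arange(n_cells), top]
    states = np.full(n_cells, STATE_UNASSIGNED, dtype=object)
    donors = np.zeros(n_cells, dtype=int)
    is_multi = top_above & (top_val - competitor < params.margin) & np.isfinite(competitor)
    is_singlet = top_above & ~is_multi
    states[is_multi] = STATE_MULTIPLET
    states[is_singlet] = STATE_SINGLET
    donors[is_singlet] = top[is_singlet] + 1

    table = pd.DataFrame({
        "cell": list(matrix.index),
        "state": states,
        "donor": donors,
    })
    return DonorAssignment(table=table, clr=clr_df, thresholds=thresholds)
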