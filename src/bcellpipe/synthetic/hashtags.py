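"""Hashtag UMI-count simulator (negative-binomial signal over background)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datatypes import UNASSIGNED


@dataclass
class HashtagConfig:
    n_hashtags: int = 3
    signal_mean: float = 300.0
    signal_dispersion: float = 10.0
    background_mean: float = 3.0
    background_dispersion: float = 2.0
    multiplet_fraction: float = 0.0
    unlabeled_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.signal_mean <= self.background_mean:
            raise ValueError("signal mean must exceed background mean")
        for name in ("multiplet_fraction", "unlabeled_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_hashtags < 1:
            raise ValueError("need at least one hashtag")


def _nb(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (size) theta.

    Variance is mean + mean^2/theta; mean 0 degenerates to all-zero counts.
    """
    if mean == 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_hashtags(
    config: HashtagConfig,
    donor_truth: np.ndarray,
    seed: int,
    cell_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cells x hashtags UMI count matrix from donor ground truth.

    ``donor_truth`` holds 1-based hashtag indices (0 = unlabeled cell).
    Returns ``(counts, truth)`` where counts is a DataFrame indexed by cell
    with columns ``hashtag1..N`` and truth records the per-cell state
    (``singlet``/``multiplet``/``unlabeled``) plus the signal hashtags.
    """
    donor_truth = np.asarray(donor_truth, dtype=int)
    if donor_truth.ndim != 1:
        raise ValueError("donor truth must be a 1-D vector of hashtag indices")
    if donor_truth.max(initial=0) > config.n_hashtags:
        raise ValueError("donor index outside the hashtag panel")

    rng = np.random.default_rng(seed)
    n = donor_truth.size
    counts = _nb(rng, config.background_mean, config.background_dispersion,
                 (n, config.n_hashtags))

    is_multiplet = (donor_truth != UNASSIGNED) & (
        rng.random(n) < config.multiplet_fraction
    )
    states = []
    signal_cols: list[tuple[int, ...]] = []
    for i in range(n):
        d = donor_truth[i]
        if d == UNASSIGNED:
            states.append("unlabeled")
            signal_cols.append(())
            continue
        own = d - 1
        if is_multiplet[i] and config.n_hashtags >= 2:
            other = int(rng.choice([h for h in range(config.n_hashtags) if h != own]))
            sig = (own, other)
            states.append("multiplet")
        else:
            sig = (own,)
            states.append("singlet")
        for h in sig:
            counts[i, h] += _nb(rng, config.signal_mean, config.signal_dispersion, 1)[0]
        signal_cols.append(sig)

    if cell_ids is None:
        cells = [f"cell{i:05d}" for i in range(n)]
    else:
        if len(cell_ids) != n:
            raise ValueError("cell_ids length must match donor truth")
        cells = list(cell_ids)
    mat = pd.DataFrame(
        counts, index=cells,
        columns=[f"hashtag{h + 1}" for h in range(config.n_hashtags)],
    )
    truth = pd.DataFrame({
        "cell": cells,
        "donor": donor_truth,
        "state": states,
        "signal_hashtags": [";".join(str(h + 1) for h in s) for s in signal_cols],
    })
    return mat, truth
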