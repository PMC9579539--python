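"""Expression-count simulator with planted clusters, and a reference atlas
builder whose populations carry elevated marker genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_POPULATIONS = ["MZ", "FO", "Mem", "T1", "T3", "GC"]

#: planted cluster -> source atlas population for the default fixture
DEFAULT_CLUSTER_SOURCES = {1: "MZ", 2: "FO", 3: "Mem"}


def default_marker_sets() -> dict[int, list[str]]:
    """52 marker genes split over the three default clusters (17/17/18)."""
    return {
        1: [f"mz_g{i:02d}" for i in range(1, 18)],
        2: [f"fo_g{i:02d}" for i in range(1, 18)],
        3: [f"mem_g{i:02d}" for i in range(1, 19)],
    }


@dataclass
class ExpressionConfig:
    cluster_proportions: tuple[float, ...] = (0.4, 0.35, 0.25)
    marker_sets: dict[int, list[str]] = field(default_factory=default_marker_sets)
    effect_lfc: float = 2.0
    n_genes: int = 300
    baseline_mean: float = 2.0
    dispersion: float = 2.0
    n_cells: int = 900

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        seen: set[str] = set()
        for genes in self.marker_sets.values():
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"marker sets overlap on {sorted(overlap)}")
            seen |= set(genes)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_proportions)

    def gene_names(self) -> list[str]:
        markers = [g for c in sorted(self.marker_sets) for g in self.marker_sets[c]]
        n_filler = self.n_genes - len(markers)
        if n_filler < 0:
            raise ValueError("n_genes smaller than the marker panel")
        return markers + [f"bg_g{i:04d}" for i in range(1, n_filler + 1)]


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_expression(
    config: ExpressionConfig, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a cells x genes NB count matrix with planted marker shifts.

    Returns the count DataFrame and 1-based true cluster labels.  Marker
    genes have their mean multiplied by ``2**effect_lfc`` inside their
    cluster; ``effect_lfc = 0`` yields structureless counts.
    """
    rng = np.random.default_rng(seed)
    genes = config.gene_names()
    labels = rng.choice(
        np.arange(1, config.n_clusters + 1),
        size=config.n_cells,
        p=np.asarray(config.cluster_proportions),
    )
    base = rng.gamma(shape=2.0, scale=config.baseline_mean / 2.0, size=len(genes))
    base = np.maximum(base, 0.05)

    mean = np.tile(base, (config.n_cells, 1))
    gene_idx = {g: i for i, g in enumerate(genes)}
    fold = 2.0 ** config.effect_lfc
    for cluster, markers in config.marker_sets.items():
        rows = labels == cluster
        for g in markers:
            if g in gene_idx:
                mean[rows, gene_idx[g]] *= fold

    counts = _nb(rng, mean, config.dispersion)
    cells = [f"cell{i:05d}" for i in range(config.n_cells)]
    return pd.DataFrame(counts, index=cells, columns=genes), labels


def make_reference_atlas(
    populations: list[str],
    genes: list[str],
    seed: int,
    marker_home: dict[str, str] | None = None,
    n_withheld: int = 2,
    elevation: float = 8.0,
) -> pd.DataFrame:
    """Build a populations x genes table of positive reference expression.

    Genes named in ``marker_home`` are elevated in their home population.
    The last ``n_withheld`` genes of the panel are left out of the atlas to
    exercise unmapped-gene reporting downstream.
    """
    if len(set(populations)) != len(populations):
        raise ValueError("duplicate population names in atlas")
    if marker_home is None:
        marker_home = default_marker_home()
    kept = genes[: len(genes) - n_withheld] if n_withheld else list(genes)
    rng = np.random.default_rng(seed)
    values = rng.gamma(shape=2.0, scale=5.0, size=(len(populations), len(kept)))
    values = np.maximum(values, 0.1)
    atlas = pd.DataFrame(values, index=list(populations), columns=kept)
    for g, home in marker_home.items():
        if g in atlas.columns and home in atlas.index:
            atlas.loc[home, g] *= elevation
    return atlas


def default_marker_home() -> dict[str, str]:
    home: dict[str, str] = {}
    for cluster, genes in default_marker_sets().items():
        pop = DEFAULT_CLUSTER_SOURCES[cluster]
        for g in genes:
            home[g] = pop
    return home


def default_atlas(seed: int = 0, n_withheld: int = 2) -> pd.DataFrame:
    """Atlas matching the default expression fixture's marker panel."""
    panel = [g for c in sorted(default_marker_sets()) for g in default_marker_sets()[c]]
    return make_reference_atlas(DEFAULT_POPULATIONS, panel, seed, n_withheld=n_withheld)
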