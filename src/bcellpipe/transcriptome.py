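"""Clustering, marker detection and z-score projection onto a reference atlas.

The projection follows the gene-wise rule: for gene g and population p,
z_gp = (m_gp - mu_g) / sigma_g where m_gp is the population's (median)
expression of g and mu_g/sigma_g are the mean and SD of g across all atlas
populations.  Each cell cluster is then assigned the population with the
highest mean z over the cluster's up-regulated marker genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def normalize_counts(counts: pd.DataFrame, target_sum: float = 1e4) -> pd.DataFrame:
    """Depth-normalize each cell to ``target_sum`` then log1p.

    All-zero cells are flagged and excluded from the result.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    depth = counts.sum(axis=1)
    zero = depth == 0
    if zero.any():
        logger.warning("excluding %d all-zero cells", int(zero.sum()))
        counts = counts.loc[~zero]
        depth = depth[~zero]
    scaled = counts.div(depth, axis=0) * target_sum
    return np.log1p(scaled)


@dataclass
class ClusterParams:
    k_range: tuple[int, int] = (2, 6)
    n_components: int = 20
    silhouette_floor: float = 0.10  # below this the data count as one cluster
    n_init: int = 10


@dataclass
class ClusterResult:
    labels: np.ndarray          # 1-based, aligned with the matrix rows
    n_clusters: int
    silhouettes: dict[int, float] = field(default_factory=dict)

    @property
    def counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


def cluster_cells(
    normalized: pd.DataFrame, params: ClusterParams | None = None, seed: int = 0
) -> ClusterResult:
    """PCA + k-means with silhouette-selected k.

    k is chosen in ``k_range`` by maximum mean silhouette; if even the best
    silhouette is under the floor the data are treated as a single cluster.
    """
    if params is None:
        params = ClusterParams()
    n_cells = normalized.shape[0]
    if n_cells < 2:
        raise ValueError("clustering needs at least 2 cells")
    if n_cells < params.k_range[1]:
        raise ValueError("fewer cells than the maximum requested k")

    x = normalized.to_numpy(dtype=float)
    n_comp = min(params.n_components, n_cells - 1, x.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(x)

    silhouettes: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in range(max(2, params.k_range[0]), params.k_range[1] + 1):
        km = KMeans(n_clusters=k, n_init=params.n_init, random_state=seed)
        lab = km.fit_predict(pcs)
        silhouettes[k] = float(silhouette_score(pcs, lab))
        labelings[k] = lab

    best_k = max(silhouettes, key=silhouettes.get)
    if silhouettes[best_k] < params.silhouette_floor:
        return ClusterResult(np.ones(n_cells, dtype=int), 1, silhouettes)
    return ClusterResult(labelings[best_k] + 1, best_k, silhouettes)


@dataclass
class MarkerSet:
    """Full per-gene one-vs-rest statistics plus the significant subset."""

    stats: pd.DataFrame  # cluster, gene, log2fc, statistic, pvalue, padj, direction
    p_threshold: float = 0.05
    lfc_floor: float = 0.25

    @property
    def significant(self) -> pd.DataFrame:
        s = self.stats
        keep = (s["pvalue"] < self.p_threshold) & (s["log2fc"].abs() >= self.lfc_floor)
        return s[keep]

    def up_genes(self, cluster: int) -> list[str]:
        sig = self.significant
        sel = sig[(sig["cluster"] == cluster) & (sig["direction"] == "up")]
        return list(sel.sort_values("pvalue")["gene"])


def find_markers(
    normalized: pd.DataFrame,
    labels: np.ndarray,
    p_threshold: float = 0.05,
    lfc_floor: float = 0.25,
    min_cells: int = 3,
) -> MarkerSet:
    """One-vs-rest rank-sum test per gene per cluster with BH adjustment."""
    labels = np.asarray(labels)
    clusters = sorted(np.unique(labels))
    if len(clusters) < 2:
        raise ValueError("marker detection needs at least 2 clusters")

    x = normalized.to_numpy(dtype=float)
    genes = list(normalized.columns)
    frames = []
    for c in clusters:
        mask = labels == c
        if mask.sum() < min_cells:
            logger.warning("cluster %s has < %d cells; skipped", c, min_cells)
            continue
        inside, outside = x[mask], x[~mask]
        res = stats.ranksums(inside, outside, axis=0)
        log2fc = np.log2(inside.mean(axis=0) + 1e-9) - np.log2(outside.mean(axis=0) + 1e-9)
        frames.append(pd.DataFrame({
            "cluster": c,
            "gene": genes,
            "log2fc": log2fc,
            "statistic": res.statistic,
            "pvalue": res.pvalue,
            "direction": np.where(log2fc >= 0, "up", "down"),
        }))
    table = pd.concat(frames, ignore_index=True)
    table["padj"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    return MarkerSet(stats=table, p_threshold=p_threshold, lfc_floor=lfc_floor)


def map_genes(
    marker_genes: list[str], atlas: pd.DataFrame, case_insensitive: bool = False
) -> tuple[list[str], list[str]]:
    """Match marker genes to atlas columns; report (mapped, unmapped)."""
    if not marker_genes:
        raise ValueError("empty marker gene list")
    if case_insensitive:
        lookup = {c.lower(): c for c in atlas.columns}
        mapped = [lookup[g.lower()] for g in marker_genes if g.lower() in lookup]
        unmapped = [g for g in marker_genes if g.lower() not in lookup]
    else:
        cols = set(atlas.columns)
        mapped = [g for g in marker_genes if g in cols]
        unmapped = [g for g in marker_genes if g not in cols]
    return mapped, unmapped


@dataclass
class SignatureMatrix:
    """Gene-wise z-scores (genes x populations) and cluster enrichment."""

    z: pd.DataFrame               # genes x populations
    enrichment: pd.DataFrame      # clusters x populations (mean z of up-genes)
    assignment: dict[int, str]    # cluster -> best population
    flagged_genes: list[str] = field(default_factory=list)  # sigma_g == 0


def signature_zscores(atlas: pd.DataFrame, genes: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """z_gp across atlas populations for each gene; zero-variance genes get 0."""
    sub = atlas[genes]  # populations x genes
    mu = sub.mean(axis=0)
    sigma = sub.std(axis=0, ddof=0)
    flagged = list(sigma.index[sigma == 0])
    if flagged:
        logger.warning("zero variance across populations for %s; z set to 0", flagged)
    safe = sigma.replace(0, 1.0)
    z = (sub - mu) / safe
    z.loc[:, flagged] = 0.0
    return z.T, flagged  # genes x populations


def project_to_atlas(
    markers: MarkerSet | dict[int, list[str]],
    atlas: pd.DataFrame,
    case_insensitive: bool = False,
) -> SignatureMatrix:
    """Project per-cluster up-regulated marker genes onto the atlas."""
    if isinstance(markers, MarkerSet):
        per_cluster = {
            int(c): markers.up_genes(int(c))
            for c in sorted(markers.stats["cluster"].unique())
        }
    else:
        per_cluster = {int(c): list(g) for c, g in markers.items()}

    all_genes = sorted({g for gs in per_cluster.values() for g in gs})
    mapped, unmapped = map_genes(all_genes, atlas, case_insensitive)
    if unmapped:
        logger.info("%d marker genes not in atlas: %s", len(unmapped), unmapped)
    if not mapped:
        raise ValueError("no marker genes mapped to the atlas")

    z, flagged = signature_zscores(atlas, mapped)
    mapped_set = set(mapped)
    enr_rows = {}
    assignment = {}
    for cluster, genes in per_cluster.items():
        usable = [g for g in genes if g in mapped_set]
        if not usable:
            continue
        score = z.loc[usable].mean(axis=0)
        enr_rows[cluster] = score
        assignment[cluster] = str(score.idxmax())
    enrichment = pd.DataFrame(enr_rows).T
    enrichment.index.name = "cluster"
    return SignatureMatrix(z=z, enrichment=enrichment, assignment=assignment,
                           flagged_genes=flagged)
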