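"""Component selection rules and gene retain-masks.

After the mixture decomposition, whole components are declared informative
or not.  Two adaptive rules are provided:

* ``top3``  — keep the three components with the largest means (read as
  high-, medium- and low-level expressed genes); with K <= 3 this
  degenerates to no filtering.
* ``kmeans2`` — cluster the K parameter triples (mean, SD, weight) into two
  groups by the k-means criterion and drop every component in the cluster
  whose centroid sits lower along the mean coordinate; with K = 1 this
  degenerates to no filtering.

Fixed-proportion threshold filters (remove the lowest-signal P percent of
genes) are provided for comparison with the adaptive rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .gmm import GMMFit
from .signals import FilterSignal

SelectionRule = Literal["top3", "kmeans2", "all"]
FilterRule = Literal["top3", "kmeans2", "fixed_P", "none"]


@dataclass
class ComponentSelection:
    """Set of retained component indices (canonical mean-ascending order)."""

    retained: np.ndarray
    rule: SelectionRule
    nf_equivalent: bool = False
    cluster_centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.retained = np.asarray(sorted(set(int(i) for i in np.atleast_1d(self.retained))))
        if self.retained.size == 0:
            raise ValueError("a component selection must retain at least one component")


@dataclass
class GeneFilter:
    """Boolean retain-mask over all genes plus provenance."""

    retain_mask: np.ndarray
    method: str  # NF, S, V or LV
    rule: FilterRule
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.retain_mask = np.asarray(self.retain_mask, dtype=bool)
        if self.retain_mask.ndim != 1:
            raise ValueError("retain_mask must be 1-D")

    @property
    def removed_fraction(self) -> float:
        return 1.0 - float(self.retain_mask.mean())

    @property
    def n_retained(self) -> int:
        return int(self.retain_mask.sum())


def no_filter(n_genes: int, gene_ids: np.ndarray | None = None) -> GeneFilter:
    """The NF baseline: every gene retained."""
    return GeneFilter(np.ones(n_genes, dtype=bool), "NF", "none", gene_ids)


def select_top3(fit: GMMFit) -> ComponentSelection:
    """Retain the three largest-mean components; K <= 3 degenerates to NF."""
    if fit.K >= 4:
        return ComponentSelection(np.arange(fit.K - 3, fit.K), "top3")
    return ComponentSelection(np.arange(fit.K), "top3", nf_equivalent=True)


def _exact_two_means(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact optimum of the 2-cluster k-means objective by bipartition search.

    For K <= 15 components every nontrivial bipartition can be scored, which
    removes any dependence on initialization.  Returns (labels, centroids)
    with labels in {0, 1}.
    """
    K = points.shape[0]
    best_cost = np.inf
    best_mask = None
    # enumerate subsets containing point 0 (each bipartition scored once)
    for size in range(1, K):
        for idx in combinations(range(1, K), size - 1):
            members = (0,) + idx
            mask = np.zeros(K, dtype=bool)
            mask[list(members)] = True
            c0 = points[mask].mean(axis=0)
            c1 = points[~mask].mean(axis=0)
            cost = ((points[mask] - c0) ** 2).sum() + ((points[~mask] - c1) ** 2).sum()
            if cost < best_cost - 1e-15:
                best_cost = cost
                best_mask = mask
    labels = (~best_mask).astype(int)
    centroids = np.vstack([points[best_mask].mean(axis=0), points[~best_mask].mean(axis=0)])
    return labels, centroids


def select_kmeans2(
    fit: GMMFit,
    seed: int | None = None,
    standardize_coords: bool = False,
) -> ComponentSelection:
    """Two-cluster k-means over component (mean, SD, weight) triples.

    The cluster whose centroid has the smaller mean coordinate is declared
    non-informative and its components are dropped.  The optimum of the
    k-means objective is found exactly (bipartition search), so ``seed`` is
    accepted for interface compatibility but has no effect.  With K = 1 the
    rule degenerates to NF.
    """
    if fit.K == 1:
        return ComponentSelection(np.array([0]), "kmeans2", nf_equivalent=True)
    pts = np.column_stack([fit.means, fit.sds, fit.weights]).astype(float)
    if standardize_coords:
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd
    labels, centroids_std = _exact_two_means(pts)
    # centroid location is judged on the raw mean coordinate
    mu0 = fit.means[labels == 0].mean()
    mu1 = fit.means[labels == 1].mean()
    low = 0 if mu0 <= mu1 else 1
    retained = np.flatnonzero(labels != low)
    raw_centroids = np.vstack(
        [
            np.column_stack([fit.means, fit.sds, fit.weights])[labels == c].mean(axis=0)
            for c in (low, 1 - low)
        ]
    )
    return ComponentSelection(retained, "kmeans2", cluster_centroids=raw_centroids)


def component_filter_mask(
    assignments: np.ndarray,
    selection: ComponentSelection,
    method: str,
    gene_ids: np.ndarray | None = None,
) -> GeneFilter:
    """Retain exactly the genes whose MAP component is in the selection."""
    assignments = np.asarray(assignments, dtype=int)
    if assignments.size == 0:
        raise ValueError("empty assignment vector")
    if assignments.min() < 0 or selection.retained.min() < 0:
        raise ValueError("component indices must be non-negative")
    mask = np.isin(assignments, selection.retained)
    return GeneFilter(mask, method, selection.rule, gene_ids)


def fixed_proportion_filter(
    signal: FilterSignal,
    P: float,
    method: str | None = None,
) -> GeneFilter:
    """Remove the floor(N * P / 100) genes with the smallest signal.

    Ties at the cut boundary are broken by stable gene order.
    """
    if not 0 <= P < 100:
        raise ValueError("P must be in [0, 100)")
    x = signal.x
    n_remove = int(np.floor(x.size * P / 100.0))
    order = np.argsort(x, kind="stable")
    mask = np.ones(x.size, dtype=bool)
    mask[order[:n_remove]] = False
    return GeneFilter(mask, method or signal.method, "fixed_P", signal.gene_ids)


# ---------------------------------------------------------------------------
# mask I/O
# ---------------------------------------------------------------------------

def write_mask(f: GeneFilter, path) -> None:
    """Write a two-column TSV (gene_id, retained 0/1)."""
    ids = f.gene_ids if f.gene_ids is not None else np.arange(f.retain_mask.size)
    pd.DataFrame({"gene_id": ids, "retained": f.retain_mask.astype(int)}).to_csv(
        path, sep="\t", index=False
    )


def read_mask(path, method: str = "NF", rule: FilterRule = "none") -> GeneFilter:
    df = pd.read_csv(path, sep="\t")
    return GeneFilter(df["retained"].to_numpy(dtype=bool), method, rule,
                      df["gene_id"].to_numpy())
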