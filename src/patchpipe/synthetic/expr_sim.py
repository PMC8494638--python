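"""Negative-binomial count-matrix generator: discrete clusters plus an
optional depth-correlated expression gradient in one cluster.

Gene means are specified in count units at a reference library size of 5e5
and scaled per cell by a log-normal library size (mu = log 5e5, sigma = 0.3);
counts are NB with shared dispersion theta (var = mu + mu^2/theta).

Marker genes are on/off genes: their off-state mean is low (around
``marker_off_mean`` counts, so they are detected in only a minority of
cells) and their mean in their own cluster is multiplied by
``2**marker_log2_fc``.  Alternatively ``marker_p_on`` / ``marker_p_off``
plant exact expressing proportions: the NB zero-probability is inverted to
get the off/on means (``mu = theta * ((1-p)^(-1/theta) - 1)``), which pins
the fraction of cells with a non-zero count.  ``marker_log2_fc = 0`` yields
a pure null design with no cluster structure.

Gradient genes (in the designated cluster only) get a log2-mean term linear
in each cell's true scaled depth.  All ground truth is recorded in the
metadata tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..transcriptomics import ExpressionMatrix

__all__ = ["ExpressionDesign", "simulate_expression"]

REFERENCE_LIBRARY = 5e5


@dataclass(frozen=True)
class ExpressionDesign:
    n_clusters: int = 5
    cells_per_cluster: int = 60
    n_genes: int = 2000
    n_markers_per_cluster: int = 50
    marker_log2_fc: float = 2.0
    marker_p_on: float | None = None  # plant exact expressing proportions
    marker_p_off: float | None = None
    marker_off_mean: float = 0.5  # counts at the reference library size
    base_mean: float = 8.0
    base_sigma: float = 1.2
    gradient_cluster: int | None = None
    gradient_genes: int = 0
    gradient_slope: float = 0.0  # log2-expression per unit scaled depth
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clusters", "cells_per_cluster", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        needed = self.n_clusters * self.n_markers_per_cluster + self.gradient_genes
        if needed > self.n_genes:
            raise ValueError("not enough genes for the requested markers/gradient")
        if self.gradient_cluster is not None and not (
            0 <= self.gradient_cluster < self.n_clusters
        ):
            raise ValueError("gradient_cluster out of range")
        if (self.marker_p_on is None) != (self.marker_p_off is None):
            raise ValueError("set both marker_p_on and marker_p_off, or neither")


def _mean_for_detection_probability(p: float, theta: float) -> float:
    """NB mean whose probability of a non-zero count equals ``p``."""
    if not (0 < p < 1):
        raise ValueError("planted proportions must lie in (0, 1)")
    return theta * ((1.0 - p) ** (-1.0 / theta) - 1.0)


def simulate_expression(
    design: ExpressionDesign,
    platform: str = "reference",
    n_donors: int = 2,
) -> ExpressionMatrix:
    """Generate a gene x cell count matrix with full ground-truth metadata."""
    d = design
    rng = np.random.default_rng(d.seed)
    theta = d.nb_dispersion
    n_cells = d.n_clusters * d.cells_per_cluster
    genes = pd.Index([f"G{i:05d}" for i in range(d.n_genes)], name="gene")
    cells = pd.Index([f"C{i:05d}" for i in range(n_cells)], name="cell")

    clusters = np.repeat(np.arange(d.n_clusters), d.cells_per_cluster)
    depths = rng.uniform(-1.0, 0.0, size=n_cells)

    marker_of = np.full(d.n_genes, -1, dtype=int)
    cursor = 0
    for c in range(d.n_clusters):
        marker_of[cursor : cursor + d.n_markers_per_cluster] = c
        cursor += d.n_markers_per_cluster
    gradient_mask = np.zeros(d.n_genes, dtype=bool)
    gradient_mask[cursor : cursor + d.gradient_genes] = True

    # baseline means (count units at the reference library size)
    base = rng.lognormal(mean=np.log(d.base_mean), sigma=d.base_sigma, size=d.n_genes)
    is_marker = marker_of >= 0
    if d.marker_log2_fc != 0 and is_marker.any():
        if d.marker_p_on is not None:
            off = _mean_for_detection_probability(d.marker_p_off, theta)
            on = _mean_for_detection_probability(d.marker_p_on, theta)
        else:
            off = None
            on = None
        base[is_marker] = (
            off
            if off is not None
            else rng.lognormal(
                np.log(d.marker_off_mean), 0.3, size=int(is_marker.sum())
            )
        )
    base[gradient_mask] = rng.lognormal(
        np.log(d.base_mean), 0.5, size=int(gradient_mask.sum())
    )

    log2_mu = np.log2(base)[:, None] * np.ones((1, n_cells))
    if d.marker_log2_fc != 0:
        for c in range(d.n_clusters):
            cols = clusters == c
            rows = marker_of == c
            if d.marker_p_on is not None:
                log2_mu[np.ix_(rows, cols)] = np.log2(on)
            else:
                log2_mu[np.ix_(rows, cols)] += d.marker_log2_fc
    if d.gradient_cluster is not None and d.gradient_genes:
        cols = clusters == d.gradient_cluster
        centred = depths[cols] - depths[cols].mean()
        log2_mu[np.ix_(gradient_mask, cols)] += d.gradient_slope * centred[None, :]

    lib = rng.lognormal(mean=np.log(REFERENCE_LIBRARY), sigma=0.3, size=n_cells)
    mu = 2.0**log2_mu * (lib / REFERENCE_LIBRARY)[None, :]
    counts = rng.negative_binomial(theta, theta / (theta + mu))

    # gene annotations: special categories only on non-marker, non-gradient genes
    plain = np.flatnonzero(~is_marker & ~gradient_mask)
    chromosome = np.array([f"chr{1 + i % 22}" for i in range(d.n_genes)], dtype=object)
    is_mito = np.zeros(d.n_genes, dtype=bool)
    cls_max = np.full(d.n_genes, "neuronal", dtype=object)
    n_special = min(len(plain), max(6, d.n_genes // 20))
    special = (
        rng.choice(plain, size=n_special, replace=False)
        if n_special
        else np.array([], dtype=int)
    )
    third = max(1, n_special // 3) if n_special else 0
    chromosome[special[:third]] = "chrX"
    chromosome[special[third : 2 * third]] = "chrY"
    mito = special[2 * third :]
    chromosome[mito] = "chrM"
    is_mito[mito] = True
    rest = np.setdiff1d(plain, special)
    if len(rest) and third:
        nn = rng.choice(rest, size=min(third, len(rest)), replace=False)
        cls_max[nn] = "non-neuronal"

    gene_meta = pd.DataFrame(
        {
            "chromosome": chromosome,
            "is_mito": is_mito,
            "class_of_max_expression": cls_max,
            "true_marker_cluster": marker_of,
            "true_gradient_gene": gradient_mask,
        },
        index=genes,
    )
    cell_meta = pd.DataFrame(
        {
            "donor": [f"D{i % n_donors}" for i in range(n_cells)],
            "platform": platform,
            "cluster": [f"cluster_{c}" for c in clusters],
            "scaled_depth": depths,
        },
        index=cells,
    )
    return ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=cells), gene_meta, cell_meta
    )
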