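"""Expression normalization, marker scoring, gene filtering, reference
mapping, and cluster-structure statistics.

Conventions: expression matrices are genes x cells pandas DataFrames of
non-negative counts.  "Expressing" a gene means log2(CPM + 1) > 1 (i.e.
CPM > 1); the threshold is exposed where relevant.  All sampling is seeded
and all tie-breaks are lexicographic, so every operation is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "ClusterReference",
    "cpm_log",
    "beta_score",
    "select_binary_genes",
    "filter_genes",
    "nms_score",
    "build_cluster_reference",
    "map_cells",
    "cluster_heterogeneity",
    "cluster_discreteness",
    "deep_marker_selection",
]

EXPRESSION_THRESHOLD_LOG2CPM = 1.0  # "expressed" means log2(CPM+1) above this


@dataclass
class ExpressionMatrix:
    """Gene x cell counts with gene and cell metadata tables.

    ``gene_meta`` is indexed by gene symbol with columns ``chromosome``,
    ``is_mito`` and ``class_of_max_expression``; ``cell_meta`` is indexed by
    cell id with columns ``donor``, ``platform`` and optionally ``cluster``
    and ``scaled_depth``.
    """

    counts: pd.DataFrame
    gene_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene symbols")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("counts must be finite and non-negative")
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=self.counts.index)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.counts.loc[genes], self.gene_meta.loc[genes], self.cell_meta
        )

    def to_dir(self, outdir) -> None:
        """Write as MTX (genes x cells) plus two TSV metadata tables."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "counts.mtx"), sparse.csr_matrix(self.counts.to_numpy()))
        self.gene_meta.to_csv(outdir / "genes.tsv", sep="\t", index_label="gene")
        self.cell_meta.to_csv(outdir / "cells.tsv", sep="\t", index_label="cell")

    @classmethod
    def from_dir(cls, indir) -> "ExpressionMatrix":
        import pathlib

        indir = pathlib.Path(indir)
        gene_meta = pd.read_csv(indir / "genes.tsv", sep="\t", index_col="gene")
        cell_meta = pd.read_csv(indir / "cells.tsv", sep="\t", index_col="cell")
        counts = pd.DataFrame(
            np.asarray(mmread(str(indir / "counts.mtx")).todense()),
            index=gene_meta.index,
            columns=cell_meta.index,
        )
        return cls(counts, gene_meta, cell_meta)


@dataclass
class ClusterReference:
    """Per-cluster centroids and proportion-expressed over a marker panel."""

    clusters: list[str]
    centroids: pd.DataFrame  # genes x clusters, median log2(CPM+1)
    proportions: pd.DataFrame  # genes x clusters, fraction expressing
    marker_panel: pd.Index

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("proportions must lie in [0, 1]")


def cpm_log(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(counts-per-million + 1) normalization, per cell (column)."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"cells with zero total count: {bad[:5]}")
    return np.log2(1e6 * counts / totals + 1.0)


def beta_score(proportions: pd.DataFrame, eps: float = 1e-6) -> pd.Series:
    """Marker binariness score from per-cluster expressing proportions.

    beta = sum_{i<j} (p_i - p_j)^2 / (sum_{i<j} |p_i - p_j| + eps), computed
    per gene (row); lies in [0, 1] with 1 for a perfectly binary marker.
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if p.shape[1] < 2:
        raise ValueError("need at least 2 clusters")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")
    i, j = np.triu_indices(p.shape[1], k=1)
    d = p[:, i] - p[:, j]
    score = (d**2).sum(axis=1) / (np.abs(d).sum(axis=1) + eps)
    if isinstance(proportions, pd.DataFrame):
        return pd.Series(score, index=proportions.index)
    return pd.Series(score)


def _proportions_by_cluster(
    logcpm: pd.DataFrame, labels: pd.Series, threshold: float = EXPRESSION_THRESHOLD_LOG2CPM
) -> pd.DataFrame:
    expressed = logcpm > threshold
    return expressed.T.groupby(labels.loc[logcpm.columns].to_numpy()).mean().T


def select_binary_genes(
    ref: ExpressionMatrix, n: int = 2000, eps: float = 1e-6
) -> list[str]:
    """Top-n genes by beta score; ties broken by gene symbol."""
    if "cluster" not in ref.cell_meta.columns:
        raise ValueError("reference cell_meta must carry cluster labels")
    logcpm = cpm_log(ref.counts)
    props = _proportions_by_cluster(logcpm, ref.cell_meta["cluster"])
    beta = beta_score(props, eps=eps)
    if n > len(beta):
        warnings.warn(f"requested {n} genes but only {len(beta)} available")
        n = len(beta)
    order = pd.DataFrame(
        {"beta": beta.to_numpy(), "gene": beta.index.to_numpy()}
    ).sort_values(["beta", "gene"], ascending=[False, True])
    return list(order["gene"].iloc[:n])


def filter_genes(
    ref: ExpressionMatrix,
    patchseq: ExpressionMatrix,
    platform_log2_threshold: float = 2.0,
) -> tuple[list[str], dict[str, int]]:
    """Remove technically suspect genes; returns (retained, removals per rule).

    Rules (independent predicates, applied to the shared gene set):
    sex-chromosome genes; mitochondrial genes; genes maximally expressed in a
    non-neuronal class; genes with >= 4-fold platform difference in mean
    expression (|log2(mean+1e-2) difference| >= 2, either direction).
    """
    shared = ref.genes.intersection(patchseq.genes)
    removed: dict[str, set] = {}
    gm = ref.gene_meta.loc[shared]

    if "chromosome" in gm.columns:
        removed["sex_chromosome"] = set(
            shared[gm["chromosome"].astype(str).isin(["chrX", "chrY", "X", "Y"])]
        )
    else:
        warnings.warn("no chromosome annotation; sex-chromosome rule skipped")
        removed["sex_chromosome"] = set()

    if "is_mito" in gm.columns:
        removed["mitochondrial"] = set(shared[gm["is_mito"].astype(bool)])
    else:
        warnings.warn("no mitochondrial annotation; rule skipped")
        removed["mitochondrial"] = set()

    if "class_of_max_expression" in gm.columns:
        removed["non_neuronal_max"] = set(
            shared[
                gm["class_of_max_expression"].notna()
                & (gm["class_of_max_expression"] != "neuronal")
            ]
        )
    else:
        warnings.warn("no class-of-max-expression annotation; rule skipped")
        removed["non_neuronal_max"] = set()

    def _mean_cpm(m: ExpressionMatrix) -> pd.Series:
        cpm = 1e6 * m.counts / m.counts.sum(axis=0)
        return cpm.loc[shared].mean(axis=1)

    diff = np.abs(np.log2(_mean_cpm(ref) + 1e-2) - np.log2(_mean_cpm(patchseq) + 1e-2))
    removed["platform_dependent"] = set(shared[diff >= platform_log2_threshold])

    drop = set().union(*removed.values())
    retained = [g for g in shared if g not in drop]
    counts = {rule: len(genes) for rule, genes in removed.items()}
    return retained, counts


def nms_score(
    query: ExpressionMatrix,
    marker_sets: dict[str, list[str]],
    reference: ExpressionMatrix,
    threshold: float = 0.4,
) -> pd.DataFrame:
    """Normalized marker-sum transcriptome quality score per query cell.

    For each class, the cell's summed log2(CPM+1) over that class's "on"
    markers is divided by the median of the same sum over reference cells of
    the class; the best-matching class (highest normalized sum) provides the
    score.  A cell passes iff score > ``threshold`` (strict).
    """
    if not marker_sets or any(len(v) == 0 for v in marker_sets.values()):
        raise ValueError("marker sets must be non-empty")
    if "cluster" not in reference.cell_meta.columns:
        raise ValueError("reference requires cluster labels")
    q_log = cpm_log(query.counts)
    r_log = cpm_log(reference.counts)
    labels = reference.cell_meta["cluster"]
    rows = {}
    for cls, markers in marker_sets.items():
        genes = [g for g in markers if g in q_log.index and g in r_log.index]
        if not genes:
            raise ValueError(f"no marker genes of class {cls!r} found in matrices")
        ref_cells = labels.index[labels == cls]
        if len(ref_cells) == 0:
            raise ValueError(f"empty reference class {cls!r}")
        denom = float(r_log.loc[genes, ref_cells].sum(axis=0).median())
        if denom <= 0:
            raise ValueError(f"reference class {cls!r} has zero marker expression")
        rows[cls] = q_log.loc[genes].sum(axis=0) / denom
    table = pd.DataFrame(rows)
    best = table.idxmax(axis=1)
    score = table.max(axis=1)
    return pd.DataFrame(
        {"nms": score, "best_class": best, "pass": score > threshold}
    )


def build_cluster_reference(
    ref: ExpressionMatrix, marker_panel=None, n_markers: int = 2000
) -> ClusterReference:
    """Median-log2CPM centroids and expressing proportions per cluster."""
    if marker_panel is None:
        marker_panel = select_binary_genes(ref, n=min(n_markers, len(ref.genes)))
    marker_panel = pd.Index(marker_panel)
    logcpm = cpm_log(ref.counts).loc[marker_panel]
    labels = ref.cell_meta["cluster"]
    grouped = logcpm.T.groupby(labels.loc[logcpm.columns].to_numpy())
    centroids = grouped.median().T
    props = _proportions_by_cluster(logcpm, labels)
    clusters = sorted(centroids.columns)
    return ClusterReference(
        clusters=clusters,
        centroids=centroids[clusters],
        proportions=props[clusters],
        marker_panel=marker_panel,
    )


def map_cells(
    query: ExpressionMatrix, reference: ClusterReference
) -> pd.DataFrame:
    """Correlation-based type assignment against cluster centroids.

    Per cell: Pearson correlation between the cell's log2(CPM+1) marker
    vector and each centroid; label = argmax (ties broken by cluster label
    order), confidence = top correlation minus runner-up.  Zero-variance
    cells are left unmapped with a reason.
    """
    panel = reference.marker_panel
    missing = panel.difference(query.genes)
    if len(missing):
        raise ValueError(f"query lacks {len(missing)} marker-panel genes")
    q = cpm_log(query.counts).loc[panel].to_numpy(dtype=float)
    c = reference.centroids.loc[panel].to_numpy(dtype=float)
    qc = q - q.mean(axis=0)
    cc = c - c.mean(axis=0)
    q_sd = np.sqrt((qc**2).sum(axis=0))
    c_sd = np.sqrt((cc**2).sum(axis=0))
    labels, confidences, reasons = [], [], []
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (qc.T @ cc) / np.outer(q_sd, c_sd)
    for i, cell in enumerate(query.cells):
        r = corr[i]
        if q_sd[i] == 0 or not np.isfinite(r).any():
            labels.append(None)
            confidences.append(np.nan)
            reasons.append("zero_variance")
            continue
        order = np.argsort(-r, kind="stable")  # cluster list is sorted already
        best, second = order[0], (order[1] if len(r) > 1 else order[0])
        labels.append(reference.clusters[best])
        confidences.append(float(r[best] - r[second]) if len(r) > 1 else 1.0)
        reasons.append("")
    return pd.DataFrame(
        {"label": labels, "confidence": confidences, "reason": reasons},
        index=query.cells,
    )


def _variable_genes(
    logcpm: pd.DataFrame, n_genes: int, n_mean_bins: int = 20
) -> list[str]:
    """Most variable genes: log-expression variance standardized within
    mean-expression bins (a variance-stabilized dispersion rank)."""
    mean = logcpm.mean(axis=1)
    var = logcpm.var(axis=1)
    ranks = mean.rank(method="first")
    bins = np.ceil(ranks / (len(mean) / n_mean_bins)).astype(int)
    z = pd.Series(index=logcpm.index, dtype=float)
    for b in np.unique(bins):
        sel = bins == b
        v = var[sel]
        sd = v.std()
        z[sel] = (v - v.mean()) / sd if sd > 0 else 0.0
    order = pd.DataFrame(
        {"z": z.to_numpy(), "gene": z.index.to_numpy()}
    ).sort_values(["z", "gene"], ascending=[False, True])
    return list(order["gene"].iloc[:n_genes])


def _pc1_percent_variance(x: np.ndarray, outlier_radius_factor: float = 4.0) -> float:
    """Percent variance on PC1 after one round of outlier-cell removal.

    Outliers: cells whose radius in the first-2-PC plane exceeds
    ``outlier_radius_factor`` times the median radius.
    """
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    pcs = u[:, :2] * s[:2]
    radius = np.sqrt((pcs**2).sum(axis=1))
    med = np.median(radius)
    keep = radius <= outlier_radius_factor * med if med > 0 else np.ones(len(x), bool)
    if keep.sum() >= 3 and keep.sum() < len(x):
        xc = x[keep] - x[keep].mean(axis=0)
        _, s, _ = np.linalg.svd(xc, full_matrices=False)
    total = (s**2).sum()
    return float(100.0 * s[0] ** 2 / total) if total > 0 else 0.0


def cluster_heterogeneity(
    cluster: ExpressionMatrix | pd.DataFrame,
    n_cells: int = 80,
    n_genes: int = 80,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Observed PC1 %variance of a cluster versus a gene-shuffled null.

    Subsamples ``n_cells`` cells, takes the ``n_genes`` most variable genes,
    computes percent variance explained by PC1 (after outlier removal), then
    repeats on ``n_perm`` datasets where each gene's values are shuffled
    independently across cells (preserving every gene's marginal exactly).
    """
    counts = cluster.counts if isinstance(cluster, ExpressionMatrix) else cluster
    if n_genes > len(counts.index):
        raise ValueError("n_genes exceeds available genes")
    rng = np.random.default_rng(seed)
    cells = np.asarray(counts.columns)
    if len(cells) >= n_cells:
        chosen = rng.choice(cells, size=n_cells, replace=False)
    else:
        warnings.warn("cluster smaller than n_cells; sampling with replacement")
        chosen = rng.choice(cells, size=n_cells, replace=True)
    sub = counts.loc[:, chosen]
    sub = sub.loc[:, sub.sum(axis=0) > 0]
    logcpm = cpm_log(sub)
    genes = _variable_genes(logcpm, n_genes)
    x = logcpm.loc[genes].to_numpy().T  # cells x genes
    observed = _pc1_percent_variance(x)
    perms = []
    for _ in range(n_perm):
        xp = x.copy()
        for j in range(xp.shape[1]):
            rng.shuffle(xp[:, j])
        perms.append(_pc1_percent_variance(xp))
    perms = np.asarray(perms)
    return {
        "observed_pc1_pct": observed,
        "permuted_mean": float(perms.mean()) if n_perm else np.nan,
        "permuted_sd": float(perms.std(ddof=1)) if n_perm > 1 else np.nan,
        "permuted": perms,
        "n_cells": int(x.shape[0]),
        "genes": genes,
    }


def _de_count(
    log_t: pd.DataFrame,
    log_o: pd.DataFrame,
    lfc_min: float = 1.0,
    prop_min: float = 0.5,
    prop_ratio_min: float = 0.7,
    threshold: float = EXPRESSION_THRESHOLD_LOG2CPM,
) -> int:
    """Genes up-regulated in the target cluster under the 3-condition rule."""
    lfc = log_t.mean(axis=1) - log_o.mean(axis=1)
    p_t = (log_t > threshold).mean(axis=1)
    p_o = (log_o > threshold).mean(axis=1)
    pmax = np.maximum(p_t, p_o)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(pmax > 0, (p_t - p_o) / pmax, 0.0)
    ok = (lfc >= lfc_min) & (p_t >= prop_min) & (rel >= prop_ratio_min)
    return int(ok.sum())


def cluster_discreteness(
    matrix: ExpressionMatrix,
    target: str,
    others: list[str] | None = None,
    n_sub: int = 80,
    seed: int = 0,
    **de_kwargs,
) -> dict:
    """Mean count of target-upregulated DE genes versus each other cluster,
    after subsampling each cluster to ``n_sub`` cells."""
    labels = matrix.cell_meta["cluster"]
    if others is None:
        others = sorted(set(labels) - {target})
    if not others:
        raise ValueError("need at least one comparison cluster")
    rng = np.random.default_rng(seed)
    logcpm = cpm_log(matrix.counts)

    def subsample(cluster_label):
        cells = np.asarray(labels.index[labels == cluster_label])
        if len(cells) < 2:
            raise ValueError(f"cluster {cluster_label!r} has fewer than 2 cells")
        if len(cells) > n_sub:
            cells = rng.choice(cells, size=n_sub, replace=False)
        return logcpm.loc[:, cells]

    log_t = subsample(target)
    per_pair = {}
    for other in others:
        per_pair[other] = _de_count(log_t, subsample(other), **de_kwargs)
    return {
        "mean_de_genes": float(np.mean(list(per_pair.values()))),
        "per_pair": per_pair,
    }


def deep_marker_selection(
    matrix: ExpressionMatrix,
    quant: float = 0.7,
    min_top2_posterior: float = 0.85,
    min_expressing_fraction: float = 0.3,
) -> list[str]:
    """Genes selective for one or two of exactly three clusters.

    Expression is binarized at each gene's ``quant`` quantile across all
    cells; per-cluster expressing fractions are normalized into a posterior-
    like specificity score.  A gene is retained when the two largest scores
    carry at least ``min_top2_posterior`` of the mass and the gene is
    expressed in at least ``min_expressing_fraction`` of its best cluster.
    """
    labels = matrix.cell_meta["cluster"]
    clusters = sorted(set(labels))
    if len(clusters) != 3:
        raise ValueError(f"expected exactly 3 clusters, got {len(clusters)}")
    logcpm = cpm_log(matrix.counts)
    thresh = logcpm.quantile(quant, axis=1)
    expressed = logcpm.gt(thresh, axis=0)
    fracs = expressed.T.groupby(labels.loc[expressed.columns].to_numpy()).mean().T
    fracs = fracs[clusters]
    total = fracs.sum(axis=1)
    selected = []
    for gene in fracs.index:
        row = fracs.loc[gene]
        if total[gene] <= 0 or row.max() < min_expressing_fraction:
            continue
        s = np.sort((row / total[gene]).to_numpy())[::-1]
        if s[0] + s[1] >= min_top2_posterior:
            selected.append(gene)
    return selected
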