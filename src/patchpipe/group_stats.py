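"""Cross-modal statistics: preprocessing, depth regressions, type-wise ANOVA
with Mann-Whitney post hocs, covariate-adjusted pathology comparisons,
sparse projections and type classifiers.

Robust p-values use a heteroscedasticity-consistent (HC3) covariance in an
OLS framework throughout; multiple testing is controlled per feature batch
with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA, SparsePCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

__all__ = [
    "preprocess",
    "depth_regression",
    "anova_by_type",
    "posthoc_pairs",
    "pathology_comparison",
    "sparse_projection",
    "classify_types",
]


def preprocess(
    features: pd.DataFrame, max_missing: int = 3, k: int = 5
) -> pd.DataFrame:
    """Drop cells with too many missing features, impute, robust-scale.

    Cells missing more than ``max_missing`` features are dropped; remaining
    gaps are filled with the mean of ``k`` nearest neighbours (distances on
    the robust-scaled features); features are centred about the median and
    scaled by IQR (unit scale when IQR is 0).
    """
    if len(features) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells")
    keep = features.isna().sum(axis=1) <= max_missing
    if not keep.any():
        raise ValueError("all cells dropped by the missingness rule")
    x = features.loc[keep]
    med = x.median()
    iqr = x.quantile(0.75) - x.quantile(0.25)
    iqr = iqr.where(iqr > 0, 1.0)
    scaled = (x - med) / iqr
    imputed = KNNImputer(n_neighbors=k).fit_transform(scaled.to_numpy())
    return pd.DataFrame(imputed, index=x.index, columns=x.columns)


def _hc3_pvalue_of_fit(res, restriction) -> float:
    """Robust F-test p-value for a linear restriction under HC3 covariance."""
    test = res.f_test(restriction)
    return float(np.squeeze(test.pvalue))


def depth_regression(features: pd.DataFrame, depth: pd.Series) -> pd.DataFrame:
    """OLS of each feature on scaled depth with an HC3-robust F test.

    Returns a frame with r2, pearson_r, p (HC3) and q (BH-FDR across the
    feature batch); features with fewer than 10 paired observations get NaN.
    """
    depth = depth.loc[features.index]
    if depth.nunique() < 2:
        raise ValueError("zero-variance depth")
    rows = {}
    for col in features.columns:
        y = features[col]
        ok = y.notna() & depth.notna()
        if ok.sum() < 10:
            rows[col] = (np.nan, np.nan, np.nan)
            continue
        yy = y[ok].to_numpy(dtype=float)
        xx = depth[ok].to_numpy(dtype=float)
        X = sm.add_constant(xx)
        res = sm.OLS(yy, X).fit(cov_type="HC3")
        r = float(stats.pearsonr(xx, yy)[0]) if np.std(yy) > 0 else np.nan
        p = _hc3_pvalue_of_fit(res, "x1 = 0")
        rows[col] = (float(res.rsquared), r, p)
    out = pd.DataFrame(rows, index=["r2", "pearson_r", "p"]).T
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def anova_by_type(feature: pd.Series, labels: pd.Series) -> dict:
    """One-way ANOVA by group: eta-squared plus an HC3-robust F p-value."""
    ok = feature.notna() & labels.notna()
    y = feature[ok].to_numpy(dtype=float)
    g = labels[ok].astype(str)
    groups = sorted(g.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = g.value_counts()
    if (sizes < 3).any():
        raise ValueError("each group needs at least 3 cells")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_between = float(
        sum(len(y[(g == grp).to_numpy()]) * (y[(g == grp).to_numpy()].mean() - grand) ** 2 for grp in groups)
    )
    eta_sq = ss_between / ss_total if ss_total > 0 else 0.0
    dummies = pd.get_dummies(g, drop_first=True).astype(float)
    X = sm.add_constant(dummies.to_numpy())
    res = sm.OLS(y, X).fit(cov_type="HC3")
    k = dummies.shape[1]
    restriction = np.hstack([np.zeros((k, 1)), np.eye(k)])
    p = _hc3_pvalue_of_fit(res, restriction)
    return {"eta_sq": eta_sq, "p": p, "n_groups": len(groups)}


def posthoc_pairs(feature: pd.Series, labels: pd.Series, exact_max_n: int = 20) -> pd.DataFrame:
    """All pairwise two-sided Mann-Whitney U tests, BH-corrected.

    Exact U distribution for group sizes <= ``exact_max_n``, normal
    approximation with tie correction otherwise.  Pairs containing a group
    with fewer than 2 distinct values are skipped.
    """
    ok = feature.notna() & labels.notna()
    y = feature[ok]
    g = labels[ok].astype(str)
    groups = sorted(g.unique())
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = y[(g == groups[i]).to_numpy()].to_numpy()
            b = y[(g == groups[j]).to_numpy()].to_numpy()
            if len(np.unique(a)) < 2 and len(np.unique(b)) < 2:
                rows.append((groups[i], groups[j], np.nan, np.nan))
                continue
            method = (
                "exact"
                if max(len(a), len(b)) <= exact_max_n and not _has_ties(a, b)
                else "asymptotic"
            )
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            rows.append((groups[i], groups[j], float(u), float(p)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p"])
    mask = out["p"].notna()
    out["q"] = np.nan
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def _has_ties(a, b) -> bool:
    combined = np.concatenate([a, b])
    return len(np.unique(combined)) < len(combined)


def pathology_comparison(
    features: pd.DataFrame, score_bin: pd.Series, depth: pd.Series
) -> pd.DataFrame:
    """Feature-vs-pathology-bin tests with and without a depth covariate.

    ``score_bin`` holds 'low' / 'high' labels.  Per feature, model 1 regresses
    the feature on the bin indicator and model 2 adds scaled depth; the
    HC3-robust p of the bin coefficient is reported for each, with BH-FDR
    across features within each model.  If the bin indicator and depth are
    perfectly collinear the adjusted model is flagged unstable.
    """
    bins = score_bin.loc[features.index].astype(str)
    if not {"low", "high"} <= set(bins.dropna().unique()) | {"low", "high"}:
        raise ValueError("score_bin must contain 'low'/'high' labels")
    if (bins == "low").sum() == 0 or (bins == "high").sum() == 0:
        raise ValueError("both score bins must be non-empty")
    ind = (bins == "high").astype(float)
    dd = depth.loc[features.index].astype(float)
    rows = {}
    for col in features.columns:
        y = features[col]
        ok = y.notna() & ind.notna() & dd.notna()
        yy = y[ok].to_numpy(dtype=float)
        x1 = ind[ok].to_numpy()
        x2 = dd[ok].to_numpy()
        res1 = sm.OLS(yy, sm.add_constant(x1)).fit(cov_type="HC3")
        p1 = float(res1.pvalues[1])
        unstable = False
        X2 = sm.add_constant(np.column_stack([x1, x2]))
        if np.linalg.matrix_rank(X2) < X2.shape[1]:
            p2 = np.nan
            unstable = True
        else:
            corr = abs(np.corrcoef(x1, x2)[0, 1]) if np.std(x2) > 0 else 1.0
            res2 = sm.OLS(yy, X2).fit(cov_type="HC3")
            p2 = float(res2.pvalues[1])
            if corr > 0.999:
                unstable = True
        rows[col] = (p1, p2, unstable)
    out = pd.DataFrame(rows, index=["p_unadjusted", "p_depth_adjusted", "unstable"]).T
    for col in ("p_unadjusted", "p_depth_adjusted"):
        mask = out[col].notna()
        qcol = col.replace("p_", "q_")
        out[qcol] = np.nan
        if mask.any():
            out.loc[mask, qcol] = multipletests(
                out.loc[mask, col].astype(float), method="fdr_bh"
            )[1]
    return out


def _spca_explained_variance(X: np.ndarray, components: np.ndarray) -> float:
    """Adjusted variance captured by (possibly correlated) sparse components."""
    norms = np.linalg.norm(components, axis=1)
    keep = norms > 0
    if not keep.any():
        return 0.0
    V = (components[keep] / norms[keep, None]).T
    scores = X @ V
    q, r = np.linalg.qr(scores)
    return float(np.sum(np.diag(r) ** 2) / X.shape[0])


def sparse_projection(
    features: pd.DataFrame,
    n_components: int = 2,
    loading_report_threshold: float = 0.05,
    max_nonzero: int = 8,
    min_variance_fraction: float = 0.8,
    alphas=(0.1, 0.3, 1.0, 3.0, 10.0, 30.0),
    seed: int = 0,
) -> dict:
    """L1-penalized 2-component projection with a sparsity/structure trade-off.

    The penalty is increased until each component has at most ``max_nonzero``
    non-zero loadings while retaining at least ``min_variance_fraction`` of
    the unpenalized PCA variance; loadings with |value| above the report
    threshold are returned per component.
    """
    X = features.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if np.linalg.matrix_rank(X) < n_components:
        raise ValueError(f"feature matrix rank below {n_components}")
    pca = PCA(n_components=n_components).fit(X)
    full_var = float(np.sum(pca.explained_variance_))
    chosen = None
    for alpha in sorted(alphas, reverse=True):  # sparsest first
        model = SparsePCA(
            n_components=n_components, alpha=alpha, random_state=seed, max_iter=500
        )
        model.fit(X)
        comps = model.components_
        nnz = np.count_nonzero(comps, axis=1)
        var = _spca_explained_variance(X, comps) * X.shape[0] / max(X.shape[0] - 1, 1)
        if (nnz <= max_nonzero).all() and var >= min_variance_fraction * full_var:
            chosen = (alpha, model, comps, var)
            break
    if chosen is None:  # fall back to the least penalized model
        alpha = min(alphas)
        model = SparsePCA(
            n_components=n_components, alpha=alpha, random_state=seed, max_iter=500
        )
        model.fit(X)
        comps = model.components_
        var = _spca_explained_variance(X, comps) * X.shape[0] / max(X.shape[0] - 1, 1)
        chosen = (alpha, model, comps, var)
        warnings.warn("no penalty met the sparsity/structure criterion")
    alpha, model, comps, var = chosen
    norms = np.linalg.norm(comps, axis=1)
    norms[norms == 0] = 1.0
    comps_n = comps / norms[:, None]
    scores = X @ comps_n.T
    loadings = pd.DataFrame(
        comps_n.T,
        index=features.columns,
        columns=[f"SPC{i}" for i in range(n_components)],
    )
    reported = {
        c: list(loadings.index[loadings[c].abs() > loading_report_threshold])
        for c in loadings.columns
    }
    return {
        "scores": pd.DataFrame(
            scores, index=features.index, columns=loadings.columns
        ),
        "loadings": loadings,
        "reported_features": reported,
        "alpha": alpha,
        "explained_variance": var,
        "pca_variance": full_var,
    }


def classify_types(
    features: pd.DataFrame,
    labels: pd.Series,
    model: str = "logistic",
    n_splits: int = 1000,
    test_size: float = 0.3,
    n_trees: int = 600,
    shuffle_baseline: bool = True,
    seed: int = 0,
) -> dict:
    """Class-balanced accuracy over stratified 70/30 splits plus a
    shuffled-label chance baseline and one representative confusion matrix."""
    y = labels.loc[features.index].astype(str)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if (y.value_counts() < 5).any():
        raise ValueError("each class needs at least 5 cells")
    X = StandardScaler().fit_transform(features.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)

    def run(y_vec: np.ndarray) -> np.ndarray:
        accs = np.empty(n_splits)
        for i in range(n_splits):
            for attempt in range(10):
                rs = int(rng.integers(0, 2**31 - 1))
                X_tr, X_te, y_tr, y_te = train_test_split(
                    X, y_vec, test_size=test_size, stratify=y_vec, random_state=rs
                )
                if set(y_te) == set(y_vec):
                    break
            clf = (
                LogisticRegression(max_iter=2000)
                if model == "logistic"
                else RandomForestClassifier(n_estimators=n_trees, random_state=rs)
            )
            clf.fit(X_tr, y_tr)
            accs[i] = balanced_accuracy_score(y_te, clf.predict(X_te))
        return accs

    accs = run(y.to_numpy())
    out = {
        "balanced_accuracy": float(accs.mean()),
        "balanced_accuracy_sd": float(accs.std(ddof=1)) if n_splits > 1 else np.nan,
        "accuracies": accs,
        "classes": classes,
    }
    # representative confusion matrix from one split
    rs = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y.to_numpy(), test_size=test_size, stratify=y.to_numpy(), random_state=rs
    )
    clf = (
        LogisticRegression(max_iter=2000)
        if model == "logistic"
        else RandomForestClassifier(n_estimators=n_trees, random_state=rs)
    )
    clf.fit(X_tr, y_tr)
    out["confusion_matrix"] = pd.DataFrame(
        confusion_matrix(y_te, clf.predict(X_te), labels=classes),
        index=classes,
        columns=classes,
    )
    if shuffle_baseline:
        y_shuf = y.to_numpy().copy()
        rng.shuffle(y_shuf)
        shuf = run(y_shuf)
        out["shuffled_accuracy"] = float(shuf.mean())
        out["shuffled_accuracy_sd"] = float(shuf.std(ddof=1)) if n_splits > 1 else np.nan
        out["shuffled_accuracies"] = shuf
    return out
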