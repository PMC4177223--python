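"""Morphometric pipeline: concordance filter, PCA, group tests, DFA.

Measurements are z-scored (mean 0, SD 1, SD denominator n-1) before
ordination, so the PCA of the covariance matrix of the standardised data
coincides with a correlation-matrix PCA of the raw data.  The first
component (PCI) is oriented so that overall body-size loadings are
positive: larger animals score higher.  Discriminant classification is a
two-group linear discriminant scored by resubstitution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "observer_concordance",
    "standardize",
    "pca",
    "PCAResult",
    "group_ttest",
    "dfa",
    "DFAResult",
]


def observer_concordance(
    obs1: pd.DataFrame,
    obs2: pd.DataFrame,
    species: pd.Series,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Paired t-test of inter-observer differences, per measurement per species.

    A measurement is dropped only when it differs significantly
    (p < alpha) in *every* species — a disagreement confined to one
    species keeps the measurement.  Species with fewer than 3 pairs for a
    measurement are skipped with a warning.

    Returns the per-measurement-per-species p-value table and the drop list.
    """
    cols = [c for c in obs1.columns if c in obs2.columns
            and pd.api.types.is_numeric_dtype(obs1[c])]
    if not cols:
        raise ValueError("no shared numeric measurement columns")
    species = species.reindex(obs1.index)
    rows, drops = [], []
    for col in cols:
        sig_in: dict[str, bool] = {}
        for sp in pd.unique(species.dropna()):
            idx = species.index[species == sp]
            a = obs1.loc[idx, col].to_numpy(dtype=float)
            b = obs2.loc[idx, col].to_numpy(dtype=float)
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < 3:
                warnings.warn(f"{col}/{sp}: fewer than 3 pairs, skipped")
                continue
            diffs = a[ok] - b[ok]
            if np.allclose(diffs, 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(a[ok], b[ok])
            rows.append({"measurement": col, "species": sp,
                         "t": float(t), "p": float(p)})
            sig_in[sp] = p < alpha
        if sig_in and all(sig_in.values()) and len(sig_in) >= 2:
            drops.append(col)
    return pd.DataFrame(rows), drops


def standardize(m: pd.DataFrame) -> pd.DataFrame:
    """Z-score every numeric column (mean 0, SD 1, ddof=1)."""
    num = m.select_dtypes(include=[np.number])
    sd = num.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    return (num - num.mean()) / sd


@dataclass
class PCAResult:
    scores: pd.DataFrame      # individuals x components (PC1, PC2, ...)
    loadings: pd.DataFrame    # measurements x components
    eigenvalues: np.ndarray   # non-increasing


def pca(z: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the covariance matrix of an (already standardised) matrix.

    PCI's sign is chosen so the mean loading is positive (a body-size
    axis scores larger animals higher); the remaining components are
    oriented so their largest-magnitude loading is positive.
    """
    if len(z) < 3:
        raise ValueError("need at least 3 rows")
    if z.shape[1] > len(z):
        warnings.warn("more measurements than individuals; covariance is rank-deficient")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(z.to_numpy(dtype=float))
    load = model.components_.T  # (features, comps)
    for j in range(load.shape[1]):
        flip = load[:, j].mean() if j == 0 else load[np.abs(load[:, j]).argmax(), j]
        if flip < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(load.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=z.index, columns=names),
        loadings=pd.DataFrame(load, index=z.columns, columns=names),
        eigenvalues=model.explained_variance_,
    )


def group_ttest(values, groups) -> tuple[float, int, float]:
    """Two-sample equal-variance t-test; df = n1 + n2 - 2."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), len(a) + len(b) - 2, float(p)


@dataclass
class DFAResult:
    predictions: pd.Series
    percent_correct: float
    misclassified: list[str]


def dfa(z: pd.DataFrame, groups: pd.Series) -> DFAResult:
    """Two-group linear discriminant with resubstitution scoring.

    With more features than ``n - 2`` the feature space is first reduced
    by PCA (logged via a warning) so the pooled covariance is invertible.
    """
    groups = groups.reindex(z.index)
    labels = pd.unique(groups.dropna())
    if len(labels) != 2 or any((groups == g).sum() < 2 for g in labels):
        raise ValueError("need two groups with at least 2 members each")
    X = z.to_numpy(dtype=float)
    max_feat = len(z) - 2
    if X.shape[1] > max_feat:
        warnings.warn(
            f"{X.shape[1]} features for {len(z)} rows; reducing to "
            f"{max_feat} principal components before the discriminant"
        )
        X = _SkPCA(n_components=max_feat, svd_solver="full").fit_transform(X)
    lda = LinearDiscriminantAnalysis(solver="svd")
    try:
        pred = lda.fit(X, groups.to_numpy()).predict(X)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; using shrinkage discriminant")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        pred = lda.fit(X, groups.to_numpy()).predict(X)
    pred = pd.Series(pred, index=z.index, name="dfa_group")
    correct = pred == groups
    return DFAResult(
        predictions=pred,
        percent_correct=100.0 * float(correct.mean()),
        misclassified=[str(i) for i in z.index[~correct]],
    )
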