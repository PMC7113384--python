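"""PCA of the selected key features with per-feature contribution shares.

The contribution of feature i to component j is r_ij^2 / sum_i r_ij^2,
where r_ij is the Pearson correlation between the feature's raw values and
the component scores.  Because the statistic is built from correlations it
is scale-free and holds under either covariance- or correlation-matrix PCA;
features are standardized before PCA by default since the substitution
features have heterogeneous scales.  With p features and uniform
correlations every contribution equals 1/p, which is the natural reference
line when judging which features dominate a component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .containers import FeatureTable

__all__ = ["PcaResult", "fit_pca", "contributions"]


@dataclass
class PcaResult:
    """Scores, loadings, explained variance and feature-component correlations."""

    component_scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    feature_correlations: np.ndarray
    contributions: np.ndarray
    feature_names: list[str]

    def to_dict(self) -> dict:
        return {
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "loadings": self.loadings.tolist(),
            "feature_correlations": self.feature_correlations.tolist(),
            "contributions": np.where(
                np.isnan(self.contributions), None, self.contributions
            ).tolist(),
            "feature_names": self.feature_names,
        }


def _correlations(X: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r between every raw feature column and every score column.

    Zero-variance features or components give r = 0 (no linear association
    is measurable).
    """
    Xc = X - X.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    x_norm = np.linalg.norm(Xc, axis=0)
    s_norm = np.linalg.norm(Sc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ Sc) / np.outer(x_norm, s_norm)
    return np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)


def contributions(feature_correlations: np.ndarray) -> np.ndarray:
    """Share r_ij^2 / sum_i r_ij^2 of each feature in each component.

    Columns sum to 1.  A component uncorrelated with every feature yields an
    all-NaN column (the share is undefined, not zero).
    """
    r2 = np.asarray(feature_correlations, dtype=float) ** 2
    col_sums = r2.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        result = r2 / col_sums[None, :]
    result[:, col_sums == 0] = np.nan
    return result


def fit_pca(
    table: FeatureTable | np.ndarray,
    standardize: bool = True,
    feature_indices=None,
    n_components: int | None = None,
) -> PcaResult:
    """Fit PCA and derive contributions.

    Components are ordered by decreasing variance; the sign of each
    component is fixed so that its largest-magnitude loading is positive.
    ``n_components`` defaults to the full rank bound min(n_samples - 1,
    n_features), so the explained-variance ratios sum to 1.
    """
    if isinstance(table, FeatureTable):
        X = table.matrix
        names = table.feature_names
    else:
        X = np.asarray(table, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    if feature_indices is not None:
        feature_indices = np.asarray(feature_indices, dtype=int)
        X = X[:, feature_indices]
        names = [names[i] for i in feature_indices]
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    std = X.std(axis=0)
    if (std == 0).all():
        raise ValueError("all features are constant; PCA is undefined")
    Xw = X
    if standardize:
        safe_std = np.where(std == 0, 1.0, std)
        Xw = (X - X.mean(axis=0)) / safe_std

    k = n_components or min(n - 1, p)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Xw)
    loadings = pca.components_.T  # features x components

    # Sign convention: largest-|loading| entry of each component positive.
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip = np.where(flip == 0, 1.0, flip)
    loadings = loadings * flip[None, :]
    scores = scores * flip[None, :]

    r = _correlations(X, scores)
    return PcaResult(
        component_scores=scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        feature_correlations=r,
        contributions=contributions(r),
        feature_names=names,
    )
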