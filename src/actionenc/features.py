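"""Behavioral-rating feature spaces.

Averaged binary ratings of body-part involvement (20 effectors) and action
targets (5 yes/no questions) are reduced by PCA — components are retained
up to a cumulative explained-variance threshold (default 95%) — and the
two component-score matrices are concatenated into the design matrix used
by the encoding models (7 + 5 = 12 columns on the reference data).  PCA is
run on the centered covariance without per-feature rescaling: all ratings
are proportions on a common [0, 1] scale.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .config import DataError

_PLURALS = {"foot": "feet"}


@dataclass
class RatingMatrix:
    """Rater-averaged ratings: videos x features, entries in [0, 1]."""

    values: np.ndarray
    feature_names: list[str]
    video_ids: list[str]
    variant: str = "involvement"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.isnan(v).any():
            raise DataError("rating matrix contains missing entries")
        if v.min() < 0 or v.max() > 1:
            raise DataError("averaged ratings must lie in [0, 1]")
        self.values = v


@dataclass
class FeatureSpace:
    """PCA reduction of a rating matrix.

    loadings: original-features x retained-components; scores: videos x
    retained-components (= centered values @ loadings); explained_variance:
    per-component variance proportions for *all* components, so the sum
    over retained + discarded is <= 1 up to roundoff.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    n_components_retained: int
    variance_threshold: float
    feature_means: np.ndarray
    feature_names: list[str]
    video_ids: list[str]
    name: str = "space"


@dataclass
class DesignMatrix:
    """Concatenated component scores used to model voxel responses."""

    values: np.ndarray
    column_provenance: list[dict]   # {"space": name, "component": idx}
    video_ids: list[str]
    set_id: int | None = None


def _collapse_lateralized(tensor: np.ndarray, names: list[str]
                          ) -> tuple[np.ndarray, list[str]]:
    """Merge left_/right_ features: selected if either side was selected.

    Lateralization is not analyzed: a rating is recorded for "hands" if a
    rater selected the right hand, the left hand, or both.
    """
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for j, name in enumerate(names):
        m = re.match(r"(?:left|right)[ _](.+)", name)
        if m:
            stem = m.group(1)
            key = _PLURALS.get(stem, stem + ("" if stem.endswith("s") else "s"))
        else:
            key = name
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(j)
    if all(len(ix) == 1 for ix in groups.values()):
        return tensor, names
    collapsed = np.stack([tensor[:, groups[k], :].max(axis=1) for k in order],
                         axis=1)
    return collapsed, order


def average_ratings(tensor: np.ndarray, feature_names: list[str],
                    video_ids: list[str], variant: str = "involvement",
                    ) -> RatingMatrix:
    """Average per-rater binary ratings over raters.

    ``tensor`` is videos x features x raters with entries in {0, 1} (NaN
    marks a rater who did not see that video).  Lateralized body parts are
    collapsed before averaging.  A video rated by nobody is an error.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3:
        raise DataError("rating tensor must be videos x features x raters")
    rated = ~np.isnan(tensor)
    if not rated.any(axis=(1, 2)).all():
        raise DataError("every video needs at least one rater")
    tensor, names = _collapse_lateralized(tensor, list(feature_names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(tensor, axis=2)
    values = np.nan_to_num(values, nan=0.0)
    return RatingMatrix(values=values, feature_names=names,
                        video_ids=list(video_ids), variant=variant)


def fit_pca(ratings: RatingMatrix, variance_threshold: float = 0.95,
            name: str | None = None) -> FeatureSpace:
    """PCA of averaged ratings; retain the smallest number of components
    whose cumulative explained variance reaches the threshold."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    X = ratings.values
    if X.shape[0] < 2:
        raise DataError("PCA needs more than one video")
    if np.allclose(X.var(axis=0), 0):
        raise DataError("rating matrix is constant: no variance to reduce")
    pca = PCA(svd_solver="full").fit(X)
    evr = pca.explained_variance_ratio_
    m = int(np.searchsorted(np.cumsum(evr), variance_threshold - 1e-12) + 1)
    m = min(m, len(evr))
    loadings = pca.components_[:m].T
    scores = (X - pca.mean_) @ loadings
    return FeatureSpace(
        loadings=loadings, scores=scores, explained_variance=evr,
        n_components_retained=m, variance_threshold=variance_threshold,
        feature_means=pca.mean_, feature_names=ratings.feature_names,
        video_ids=ratings.video_ids,
        name=name or f"{ratings.variant}_{'x'.join(map(str, X.shape))}")


def project(space: FeatureSpace, values: np.ndarray) -> np.ndarray:
    """Component scores of new rating rows under an existing PCA."""
    return (np.asarray(values) - space.feature_means) @ space.loadings


def combine_spaces(body: FeatureSpace, targets: FeatureSpace,
                   set_id: int | None = None) -> DesignMatrix:
    """Concatenate body-part and action-target component scores."""
    if body.video_ids != targets.video_ids:
        raise DataError("feature spaces cover different videos")
    values = np.hstack([body.scores, targets.scores])
    provenance = (
        [{"space": body.name, "component": j}
         for j in range(body.n_components_retained)]
        + [{"space": targets.name, "component": j}
           for j in range(targets.n_components_retained)])
    return DesignMatrix(values=values, column_provenance=provenance,
                        video_ids=body.video_ids, set_id=set_id)


def backproject(profile: np.ndarray, body: FeatureSpace,
                targets: FeatureSpace) -> np.ndarray:
    """Project a component-weight profile back to the original features.

    Multiplies each space's loading matrix by its slice of the profile and
    concatenates: 20 body parts followed by 5 targets on the default data.
    """
    profile = np.asarray(profile, dtype=float)
    nb, nt = body.n_components_retained, targets.n_components_retained
    if profile.shape[-1] != nb + nt:
        raise DataError(
            f"profile length {profile.shape[-1]} != retained components "
            f"{nb}+{nt}")
    return np.concatenate([body.loadings @ profile[..., :nb],
                           targets.loadings @ profile[..., nb:]], axis=-1)


def feature_correlations(design: DesignMatrix) -> dict:
    """Pairwise Pearson r between body-space and target-space columns.

    Zero-variance columns are flagged and excluded with a warning.
    Returns mean/min/max over cross-space pairs plus the full pair table.
    """
    X = design.values
    spaces = [p["space"] for p in design.column_provenance]
    uniq = list(dict.fromkeys(spaces))
    if len(uniq) != 2:
        raise DataError("design must combine exactly two source spaces")
    if X.shape[0] < 3:
        raise DataError("need at least 3 videos")
    ok = X.std(axis=0) > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} zero-variance design column(s)",
            RuntimeWarning, stacklevel=2)
    a_idx = [j for j, s in enumerate(spaces) if s == uniq[0] and ok[j]]
    b_idx = [j for j, s in enumerate(spaces) if s == uniq[1] and ok[j]]
    if not a_idx or not b_idx:
        raise DataError("a source space has no non-constant columns left")
    C = np.corrcoef(X.T)
    rs = np.array([[C[i, j] for j in b_idx] for i in a_idx])
    return {"mean": float(rs.mean()), "min": float(rs.min()),
            "max": float(rs.max()), "pairs": rs}


def _rdm(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if np.any(features.std(axis=1) == 0):
        raise DataError("constant feature vector: dissimilarity undefined")
    return 1.0 - np.corrcoef(features)


def rdm_correlation(features_a: np.ndarray, features_b: np.ndarray) -> float:
    """Correlation of two condition-dissimilarity matrices.

    Each RDM entry is 1 - Pearson r between two videos' feature vectors;
    the two RDMs are compared by correlating their lower triangles
    (diagonal excluded).
    """
    a, b = np.asarray(features_a), np.asarray(features_b)
    if a.shape[0] != b.shape[0]:
        raise DataError("feature sets cover different videos")
    if a.shape[0] < 4:
        raise DataError("RDM correlation needs at least 4 videos")
    tri = np.tril_indices(a.shape[0], k=-1)
    return float(np.corrcoef(_rdm(a)[tri], _rdm(b)[tri])[0, 1])
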