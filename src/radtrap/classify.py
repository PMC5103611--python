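"""Feature selection, QDA classification and probability-map evaluation.

The detection stage ranks features by greedy minimum-redundancy
maximum-relevance (mRMR, difference criterion) with mutual information
estimated on equal-frequency discretized features, trains a quadratic
discriminant (per-class Gaussian) on the selected panel, predicts a
voxel-wise malignancy posterior, smooths it within the analysis mask, and
evaluates against ground truth with ROC/AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from sklearn.metrics import mutual_info_score, roc_auc_score, roc_curve

from .core import VolumeGrid
from .radiomics import FeatureMatrix

DEFAULT_K = 11  # size of the default selected-feature panel
DEFAULT_MI_BINS = 8
DEFAULT_REGULARIZATION = 1e-3
DEFAULT_SMOOTH_SIGMA_MM = 1.5


class DegenerateLabelError(ValueError):
    """Raised when training labels contain a single class."""


class NumericalConditioningError(ValueError):
    """Raised when a class covariance is singular and unregularized."""


@dataclass
class SelectionResult:
    """Ranked feature names with their greedy mRMR scores."""

    names: List[str]
    scores: List[float]

    def __post_init__(self):
        if len(self.names) != len(self.scores):
            raise ValueError("names/scores length mismatch")
        if not all(np.isfinite(self.scores)):
            raise ValueError("mRMR scores must be finite")


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize into (at most) ``bins`` equal-frequency levels."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")


def mrmr_select(features: FeatureMatrix, k: int = DEFAULT_K,
                bins: int = DEFAULT_MI_BINS) -> SelectionResult:
    """Greedy mRMR ranking (difference criterion).

    The first feature maximizes relevance I(f; label); each subsequent one
    maximizes I(f; label) minus the mean mutual information with the
    already-selected set. Ties break on column order for determinism.
    """
    if features.labels is None:
        raise ValueError("mRMR requires labelled features")
    y = np.asarray(features.labels)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("both classes must be present for selection")
    n_feat = features.values.shape[1]
    if k > n_feat:
        raise ValueError(f"k={k} exceeds the {n_feat} candidate features")
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return SelectionResult([], [])
    disc = np.stack([_equal_frequency_bins(features.values[:, j], bins)
                     for j in range(n_feat)], axis=1)
    relevance = np.array([mutual_info_score(y, disc[:, j]) for j in range(n_feat)])
    selected: List[int] = []
    scores: List[float] = []
    redundancy_sum = np.zeros(n_feat)
    remaining = np.ones(n_feat, dtype=bool)
    for step in range(k):
        if step == 0:
            crit = relevance.copy()
        else:
            crit = relevance - redundancy_sum / len(selected)
        crit[~remaining] = -np.inf
        j = int(np.argmax(crit))
        selected.append(j)
        scores.append(float(crit[j]))
        remaining[j] = False
        if step < k - 1:
            newcol = disc[:, j]
            for m in np.nonzero(remaining)[0]:
                redundancy_sum[m] += mutual_info_score(newcol, disc[:, m])
    return SelectionResult([features.columns[j] for j in selected], scores)


@dataclass
class QDAModel:
    """Two-class Gaussian discriminant with diagonal-shrinkage covariance."""

    feature_names: List[str]
    means: Dict[str, np.ndarray]
    covariances: Dict[str, np.ndarray]
    priors: Dict[str, float]
    regularization: float
    classes: Tuple[str, str] = ("benign", "malignant")

    def __post_init__(self):
        if abs(sum(self.priors.values()) - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        self._chol = {}
        for cls, cov in self.covariances.items():
            cov = np.asarray(cov, dtype=float)
            if not np.allclose(cov, cov.T, atol=1e-9):
                raise ValueError("covariance must be symmetric")
            try:
                self._chol[cls] = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise NumericalConditioningError(
                    f"class {cls!r} covariance is not positive definite") from exc

    def log_likelihood(self, x: np.ndarray, cls: str) -> np.ndarray:
        """Gaussian log density of each row of ``x`` under one class."""
        chol = self._chol[cls]
        diff = np.atleast_2d(x) - self.means[cls]
        sol = np.linalg.solve(chol, diff.T)
        maha = np.sum(sol ** 2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        d = len(self.feature_names)
        return -0.5 * (maha + logdet + d * np.log(2 * np.pi))

    def posterior_malignant(self, x: np.ndarray) -> np.ndarray:
        logp = np.stack([
            self.log_likelihood(x, c) + np.log(self.priors[c]) for c in self.classes
        ])
        logp -= logp.max(axis=0, keepdims=True)
        p = np.exp(logp)
        return p[1] / p.sum(axis=0)

    # -- versioned text serialization --------------------------------------
    def write(self, path) -> None:
        payload = {
            "format": "radtrap-qda-1",
            "feature_names": self.feature_names,
            "regularization": self.regularization,
            "classes": list(self.classes),
            "priors": self.priors,
            "means": {c: m.tolist() for c, m in self.means.items()},
            "covariances": {c: cv.tolist() for c, cv in self.covariances.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read(cls, path) -> "QDAModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "radtrap-qda-1":
            raise ValueError("unrecognized model file format")
        return cls(
            feature_names=payload["feature_names"],
            means={c: np.asarray(m) for c, m in payload["means"].items()},
            covariances={c: np.asarray(cv) for c, cv in payload["covariances"].items()},
            priors=payload["priors"],
            regularization=payload["regularization"],
            classes=tuple(payload["classes"]),
        )


def train_qda(features: FeatureMatrix, selection: Optional[SelectionResult] = None,
              regularization: float = DEFAULT_REGULARIZATION) -> QDAModel:
    """Fit per-class means and covariances on the selected features.

    Covariances are shrunk toward their own diagonal,
    ``(1 - r) S + r diag(S)``: voxel samples are heavily spatially
    correlated and raw covariances can be ill-conditioned.
    """
    if features.labels is None:
        raise ValueError("training requires labelled features")
    if regularization < 0 or regularization > 1:
        raise ValueError("regularization must lie in [0, 1]")
    fm = features.select(selection.names) if selection is not None else features
    y = np.asarray(fm.labels)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("both classes must be present for training")
    d = fm.values.shape[1]
    means, covs, priors = {}, {}, {}
    for cls, member in (("benign", ~y), ("malignant", y)):
        xs = fm.values[member]
        if len(xs) < d + 1 and regularization == 0:
            raise NumericalConditioningError(
                f"class {cls!r} has {len(xs)} samples for {d} features and no regularization")
        means[cls] = xs.mean(axis=0)
        if len(xs) > 1:
            s = np.cov(xs, rowvar=False).reshape(d, d)
        else:
            s = np.zeros((d, d))
        covs[cls] = (1.0 - regularization) * s + regularization * np.diag(np.diag(s))
        if regularization > 0:  # keep strictly PD even for degenerate samples
            floor = max(np.trace(s) / d, 1e-12) * regularization
            covs[cls] = covs[cls] + floor * 1e-6 * np.eye(d)
        priors[cls] = float(member.mean())
    return QDAModel(list(fm.columns), means, covs, priors, regularization)


@dataclass
class ProbabilityMap:
    """Voxel-wise malignancy probabilities defined exactly on a mask."""

    grid: VolumeGrid
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask must match the grid shape")
        if self.grid.modality != "PROB":
            raise ValueError("probability maps must carry the PROB modality")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def masked_values(self) -> np.ndarray:
        return self.grid.values[self.mask]


def predict_probability(model: QDAModel, features: FeatureMatrix,
                        geometry: VolumeGrid) -> ProbabilityMap:
    """Posterior P(malignant | f) at each feature row, on ``geometry``."""
    missing = [n for n in model.feature_names if n not in features.columns]
    if missing:
        raise KeyError(f"feature matrix is missing model columns: {missing[:3]}")
    x = features.select(model.feature_names).values
    post = model.posterior_malignant(x)
    vals = np.zeros(geometry.shape)
    mask = np.zeros(geometry.shape, dtype=bool)
    idx = (features.voxels[:, 0], features.voxels[:, 1], features.voxels[:, 2])
    vals[idx] = post
    mask[idx] = True
    return ProbabilityMap(VolumeGrid(vals, geometry.spacing, geometry.origin, "PROB"), mask)


def smooth_probability_map(pmap: ProbabilityMap, sigma_mm: float = DEFAULT_SMOOTH_SIGMA_MM) -> ProbabilityMap:
    """Mask-normalized Gaussian smoothing in physical units.

    Out-of-mask voxels carry zero weight, so a uniform map stays uniform
    and outputs remain in [0, 1].
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_mm == 0:
        return pmap
    sig_vox = [sigma_mm / s for s in pmap.grid.spacing]
    m = pmap.mask.astype(float)
    num = ndimage.gaussian_filter(pmap.values * m, sig_vox)
    den = ndimage.gaussian_filter(m, sig_vox)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 1e-12)
    out = np.clip(out, 0.0, 1.0)
    out[~pmap.mask] = 0.0
    return ProbabilityMap(pmap.grid.with_values(out), pmap.mask)


class DegenerateTruthError(ValueError):
    """Raised when the truth mask holds a single class in the region."""


def roc_auc(pmap: ProbabilityMap, truth: np.ndarray):
    """ROC curve (fpr, tpr, thresholds) and AUC over the analysis mask.

    AUC equals the normalized Mann-Whitney U statistic with rank-average
    tie handling.
    """
    truth = np.asarray(truth, dtype=bool)
    scores = pmap.masked_values()
    labels = truth[pmap.mask]
    if len(np.unique(labels)) < 2:
        raise DegenerateTruthError("truth must contain both classes within the mask")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return (fpr, tpr, thr), auc
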