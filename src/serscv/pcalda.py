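"""PCA-LDA classifier: centered (unscaled) PCA followed by a two-class
linear discriminant with pooled within-class covariance.

The model is deliberately written from the closed forms so that every piece
(training mean, loadings, discriminant direction, posterior) is inspectable:

* PCA: loadings are the leading right singular vectors of the centered
  training matrix; no variable scaling is applied.
* LDA: discriminant ``w = S_pooled^{-1} (mu_+ - mu_-)``; priors are the
  training class frequencies; posteriors come from the two-Gaussian
  equal-covariance model, so the LD score is the log posterior odds of the
  positive class and the decision threshold sits at score 0
  (posterior 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import SpectraSet


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def fit_pca(train_matrix: np.ndarray, a_max: int):
    """Centered PCA of a (n_samples x n_points) training matrix.

    Returns ``(train_mean, loadings, explained_variance_ratio)`` with
    ``loadings`` of shape (n_points, a): the leading right singular vectors
    of the centered matrix, sign-fixed so each component's largest-magnitude
    weight is positive. If ``a_max`` exceeds the matrix rank the retained
    count is truncated with a warning.
    """
    X = np.asarray(train_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two training spectra")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    a = min(a_max, rank)
    if a < a_max:
        warnings.warn(
            f"requested {a_max} components but rank is {rank}; truncating",
            RuntimeWarning,
            stacklevel=2,
        )
    loadings = Vt[:a].T.copy()
    # deterministic sign: largest-|weight| element positive per component
    for k in range(a):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
    var = s**2
    evr = var[:a] / var.sum() if var.sum() > 0 else np.zeros(a)
    return mean, loadings, evr


@dataclass
class LDAParams:
    """Two-class linear discriminant in PC-score space."""

    classes: tuple  # (negative, positive)
    means: np.ndarray  # 2 x a, row order = classes
    pooled_cov: np.ndarray  # a x a
    priors: np.ndarray  # length 2, sums to 1
    w: np.ndarray  # discriminant direction, length a
    bias: float  # LD score = scores @ w + bias

    @property
    def positive_class(self):
        return self.classes[1]


def fit_lda(scores: np.ndarray, labels, positive_class) -> LDAParams:
    """Fit the pooled-covariance two-class LDA on PC scores."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != len(labels):
        scores = scores.T
    labels = np.asarray(labels)
    classes = [c for c in pd.unique(labels)]
    if len(classes) != 2:
        raise ValueError(f"LDA needs exactly two classes, got {classes}")
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not in {classes}")
    neg = [c for c in classes if c != positive_class][0]
    Xp = scores[labels == positive_class]
    Xn = scores[labels == neg]
    n_p, n_n = len(Xp), len(Xn)
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    a = scores.shape[1]

    def _scatter(X, mu):
        d = X - mu
        return d.T @ d

    dof = n_p + n_n - 2
    pooled = (_scatter(Xp, mu_p) + _scatter(Xn, mu_n)) / max(dof, 1)
    try:
        w = np.linalg.solve(pooled, mu_p - mu_n)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "pooled within-class covariance is singular; retain fewer "
            "principal components"
        ) from err
    priors = np.array([n_n, n_p], dtype=float) / (n_p + n_n)
    # LD score = log posterior odds of the positive class
    bias = float(-0.5 * w @ (mu_p + mu_n) + np.log(priors[1] / priors[0]))
    return LDAParams(
        classes=(neg, positive_class),
        means=np.vstack([mu_n, mu_p]),
        pooled_cov=pooled,
        priors=priors,
        w=np.asarray(w, dtype=float),
        bias=bias,
    )


def lda_scores(params: LDAParams, scores: np.ndarray) -> np.ndarray:
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return scores @ params.w + params.bias


def lda_posterior(params: LDAParams, scores: np.ndarray) -> np.ndarray:
    """Posterior probability of the positive class (logistic of the LD score)."""
    z = lda_scores(params, scores)
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# statsmodels-style model / results pair
# ---------------------------------------------------------------------------

class PCALDA:
    """PCA-LDA classification model for spectra on a shared axis.

    Parameters
    ----------
    X : ndarray (n_samples x n_points)
    y : array-like of class labels (exactly two classes)
    n_components : retained principal components for the discriminant
    positive_class : label treated as the positive class
    axis : optional wavenumber axis, kept for prediction-time checking
    """

    def __init__(self, X, y, n_components: int, positive_class,
                 axis: np.ndarray | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.n_components = int(n_components)
        self.positive_class = positive_class
        self.axis = None if axis is None else np.asarray(axis, dtype=float)

    @classmethod
    def from_spectra(cls, ss: SpectraSet, n_components: int,
                     positive_class="H0T") -> "PCALDA":
        return cls(ss.intensities, ss.labels.to_numpy(), n_components,
                   positive_class, axis=ss.axis)

    def fit(self) -> "PCALDAResults":
        mean, loadings, evr = fit_pca(self.X, self.n_components)
        scores = (self.X - mean) @ loadings
        lda = fit_lda(scores, self.y, self.positive_class)
        return PCALDAResults(self, mean, loadings, evr, lda)


class PCALDAResults:
    """Fitted PCA-LDA model: training mean, loadings, discriminant."""

    def __init__(self, model: PCALDA, train_mean, loadings, explained_variance,
                 lda: LDAParams):
        self.model = model
        self.train_mean = train_mean
        self.loadings = loadings
        self.explained_variance = explained_variance
        self.lda = lda

    @property
    def a(self) -> int:
        return self.loadings.shape[1]

    @property
    def positive_class(self):
        return self.lda.positive_class

    def transform(self, X, axis=None) -> np.ndarray:
        """Project new spectra into the training PC space (training mean is
        used for centering — no information flows back from the new data)."""
        if axis is not None and self.model.axis is not None:
            if len(axis) != len(self.model.axis) or not np.allclose(
                axis, self.model.axis
            ):
                raise ValueError("spectra are not on the model's wavenumber axis")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.train_mean) @ self.loadings

    def predict(self, X, axis=None) -> pd.DataFrame:
        """Per-spectrum predicted class, positive-class posterior, LD score."""
        scores = self.transform(X, axis=axis)
        ld = lda_scores(self.lda, scores)
        post = lda_posterior(self.lda, scores)
        pred = np.where(ld > 0, self.lda.classes[1], self.lda.classes[0])
        return pd.DataFrame(
            {"predicted": pred, "posterior": post, "ld_score": ld}
        )
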