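"""Image-quality features and robust-covariance anomaly filtering.

Five per-image scores (noise, contrast, brightness-darkness, blurriness,
average pixel width) are computed identically for every image in a pool,
z-scored, and fitted with a minimum-covariance-determinant Gaussian.  The
samples with the lowest covariance scores (highest anomaly scores, where
anomaly = 1 - rescaled covariance score) are flagged; by default the worst
3% of the pool.  The feature definitions are standard operationalizations
documented below; each is unit-tested for its monotonicity contract only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.covariance import MinCovDet

FEATURE_NAMES = ("noise", "contrast", "brightness_darkness",
                 "blurriness", "avg_pixel_width")

__all__ = ["FEATURE_NAMES", "QualityFeatures", "compute_features",
           "detect_anomalies"]


@dataclass(frozen=True)
class QualityFeatures:
    noise: float
    contrast: float
    brightness_darkness: float
    blurriness: float
    avg_pixel_width: float

    def as_array(self) -> np.ndarray:
        return np.array([self.noise, self.contrast, self.brightness_darkness,
                         self.blurriness, self.avg_pixel_width])


def compute_features(img: np.ndarray) -> QualityFeatures:
    """Five quality scores for one grayscale image in [0, 1].

    noise
        robust scale (1.4826 * median absolute residual) after a 3x3 median
        filter; grows monotonically with added i.i.d. noise.
    contrast
        RMS contrast, i.e. the intensity standard deviation.
    brightness_darkness
        mean intensity minus the fraction of near-black (< 0.02) pixels.
    blurriness
        variance of the Laplacian response; drops when the image is blurred.
    avg_pixel_width
        mean horizontal run length between strong vertical edges (columns
        whose horizontal Sobel response exceeds a quarter of its maximum).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    resid = img - ndimage.median_filter(img, size=3)
    noise = 1.4826 * float(np.median(np.abs(resid)))
    contrast = float(img.std())
    brightness_darkness = float(img.mean() - np.mean(img < 0.02))
    blurriness = float(ndimage.laplace(img).var())

    gh = np.abs(ndimage.sobel(img, axis=1))
    gmax = gh.max()
    if gmax <= 0:
        avg_width = float(img.shape[1])
    else:
        edges_per_row = (gh > 0.25 * gmax).sum(axis=1)
        avg_width = float(np.mean(img.shape[1] / (edges_per_row + 1.0)))
    return QualityFeatures(noise, contrast, brightness_darkness,
                           blurriness, avg_width)


def detect_anomalies(features, contamination: float = 0.03, seed: int = 0):
    """Flag the most anomalous samples of a feature pool.

    Fits a robust (minimum-covariance-determinant) Gaussian to the z-scored
    5-D features with support fraction 1 - contamination and flags the
    ceil(contamination * N) samples with the largest Mahalanobis distances.
    Constant features are dropped with a warning.  Returns
    ``(flags, anomaly_scores)`` with anomaly scores rescaled to [0, 1]
    (1 = most anomalous; equals 1 minus the rescaled covariance score).
    """
    X = np.array([f.as_array() if isinstance(f, QualityFeatures) else np.asarray(f)
                  for f in features], dtype=np.float64)
    n = X.shape[0]
    if n < 20:
        raise ValueError("need at least 20 samples for anomaly detection")
    if not 0.0 < contamination < 0.5:
        raise ValueError("contamination must lie in (0, 0.5)")

    sd = X.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [FEATURE_NAMES[i] for i in np.where(~keep)[0] if i < len(FEATURE_NAMES)]
        warnings.warn(f"dropping constant features: {dropped}")
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] == 0:
        raise ValueError("all features are constant")
    Xz = (X - X.mean(axis=0)) / sd

    support = min(max(1.0 - contamination, 0.5 + 1e-6), 1.0)
    mcd = MinCovDet(support_fraction=support, random_state=int(seed)).fit(Xz)
    d2 = mcd.mahalanobis(Xz)

    lo, hi = d2.min(), d2.max()
    scores = (d2 - lo) / (hi - lo) if hi > lo else np.zeros(n)

    k = int(np.ceil(contamination * n))
    order = np.argsort(-d2, kind="stable")
    flags = np.zeros(n, dtype=bool)
    flags[order[:k]] = True
    return flags, scores
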