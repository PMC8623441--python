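"""Relative distance maps (RDMs) fed to the networks as a second channel.

An RDM encodes each pixel's vertical position relative to the retinal
anatomy, so a purely local convolutional classifier can tell apart regions
with near-identical intensities (vitreous vs. preretinal space).  Four
variants are provided:

``2NetR``
    anchored at the retina: 0 on the ILM, 1 on the RPE, linear elsewhere
    (values < 0 above the retina, > 1 below it).
``2NetPR``
    additionally anchored at the PCV: 0 on the PCV, 0.5 on the ILM, 1 on the
    RPE, piecewise linear and continuous at all three boundaries.
``CumSum``
    per-column cumulative intensity sum scaled to [0, 1]; needs no prior
    boundary segmentation.
``BasicOrient``
    a linear ramp in [0, 1] tilted to the globally estimated retina
    orientation; needs no prior segmentation either.

Boundary inputs may be float-valued; pixel row indices are compared against
them directly, without rounding.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
from scipy import ndimage

VARIANTS = ("2NetR", "2NetPR", "CumSum", "BasicOrient")

__all__ = [
    "VARIANTS",
    "map_2netR",
    "map_2netPR",
    "map_cumsum",
    "map_basic_orient",
    "estimate_orientation",
    "attach_map",
    "save_map",
    "load_map",
]


def _col_arrays(width, *lines):
    out = []
    for ln in lines:
        a = np.asarray(ln, dtype=np.float64)
        if a.ndim == 0:
            a = np.full(width, float(a))
        if a.shape != (width,):
            raise ValueError(f"boundary line has shape {a.shape}, expected ({width},)")
        out.append(a)
    return out


def _safe_denom(d):
    # adhesion / degenerate columns: clamp the denominator to one pixel
    return np.maximum(d, 1.0)


def map_2netR(ilm, rpe, height: int, width: int | None = None) -> np.ndarray:
    """Retina-anchored map M = (y - ILM(x)) / (RPE(x) - ILM(x)).

    0 exactly on the ILM, 1 exactly on the RPE, monotone down each column.
    Columns with RPE <= ILM get a one-pixel denominator instead of an error,
    because zero-height columns are a legitimate degenerate input.
    """
    if width is None:
        width = np.atleast_1d(np.asarray(ilm)).shape[-1] if np.ndim(ilm) else 1
    ilm, rpe = _col_arrays(width, ilm, rpe)
    y = np.arange(height, dtype=np.float64)[:, None]
    return (y - ilm[None, :]) / _safe_denom(rpe - ilm)[None, :]


def map_2netPR(pcv, ilm, rpe, height: int, width: int | None = None) -> np.ndarray:
    """Preretinal-space-anchored piecewise map.

    0 on the PCV, 0.5 on the ILM, 1 on the RPE::

        M = (y - PCV) / (RPE - PCV)                 for y < PCV or y > RPE
        M = (y - PCV) / (ILM - PCV) / 2             for PCV <= y < ILM
        M = ((y - ILM) / (RPE - ILM) + 1) / 2       for ILM <= y <= RPE

    Continuous at all three anchors.  At full adhesion (PCV == ILM) the
    middle branch is empty and the boundary pixel takes the retina-branch
    value 0.5.
    """
    if width is None:
        width = np.atleast_1d(np.asarray(pcv)).shape[-1] if np.ndim(pcv) else 1
    pcv, ilm, rpe = _col_arrays(width, pcv, ilm, rpe)
    if np.any(ilm < pcv) or np.any(rpe < ilm):
        raise ValueError("boundaries must satisfy pcv <= ilm <= rpe")
    y = np.arange(height, dtype=np.float64)[:, None]
    p, i, r = pcv[None, :], ilm[None, :], rpe[None, :]
    outside = (y - p) / _safe_denom(r - p)
    pre = 0.5 * (y - p) / _safe_denom(i - p)
    ret = 0.5 * ((y - i) / _safe_denom(r - i) + 1.0)
    m = np.where((y < p) | (y > r), outside, np.where(y < i, pre, ret))
    return m


def map_cumsum(img: np.ndarray) -> np.ndarray:
    """Per-column cumulative intensity sum scaled to [0, 1].

    All-zero columns map to all zeros.  On a clean retina indicator image the
    anchors agree with the retina-anchored map (0 at the ILM, 1 at the RPE).
    """
    img = np.asarray(img, dtype=np.float64)
    if np.any(img < 0):
        raise ValueError("cumulative-sum map requires non-negative intensities")
    s = np.cumsum(img, axis=0)
    total = s[-1, :]
    out = np.zeros_like(s)
    nz = total > 0
    out[:, nz] = s[:, nz] / total[None, nz]
    return out


def estimate_orientation(img: np.ndarray, sigma: float = 3.0) -> float:
    """Global retina tilt in degrees from the horizontal.

    The image is Gaussian-smoothed (sigma in px), horizontal/vertical Sobel
    edges are taken, and the gradient-magnitude-weighted mean gradient
    direction gives the tilt.  Gradient pairs are sign-aligned to point
    downward first, so the opposite-signed gradients of a band's top and
    bottom edges reinforce rather than cancel.  Near-zero total gradient
    magnitude falls back to 0 degrees.
    """
    img = np.asarray(img, dtype=np.float64)
    sm = ndimage.gaussian_filter(img, sigma)
    gv = ndimage.sobel(sm, axis=0)  # d/dy
    gh = ndimage.sobel(sm, axis=1)  # d/dx
    mag = np.hypot(gv, gh)
    flip = np.where(gv < 0, -1.0, 1.0)
    gv, gh = gv * flip, gh * flip
    wsum = mag.sum()
    if wsum < 1e-12:
        return 0.0
    mv = (mag * gv).sum() / wsum
    mh = (mag * gh).sum() / wsum
    if abs(mv) < 1e-12 and abs(mh) < 1e-12:
        return 0.0
    # gradient of a layer stack points mostly down; its horizontal component
    # measures the tilt of the layer lines.  Sign convention: positive angle
    # means the layers descend toward the right (y grows with x).
    return float(np.degrees(np.arctan2(-mh, mv)))


def map_basic_orient(img: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    """Linear [0, 1] ramp along the image axis tilted by the retina angle.

    For a zero-gradient (e.g. uniform) image this degenerates to a plain
    vertical ramp: row 0 -> 0, last row -> 1.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    theta = np.radians(estimate_orientation(img, sigma))
    y = np.arange(h, dtype=np.float64)[:, None]
    x = np.arange(w, dtype=np.float64)[None, :]
    # projection onto the (rotated) "down" direction
    proj = y * np.cos(theta) - x * np.sin(theta)
    lo, hi = proj.min(), proj.max()
    if hi - lo < 1e-12:
        return np.zeros((h, w))
    return (proj - lo) / (hi - lo)


def attach_map(img: np.ndarray, dmap: np.ndarray | None) -> np.ndarray:
    """Stack the z-scored image and the (unchanged) map as network input.

    Returns a ``(2, H, W)`` float32 array, or ``(1, H, W)`` when ``dmap`` is
    None (the no-map baseline).
    """
    img = np.asarray(img, dtype=np.float64)
    sd = img.std()
    z = (img - img.mean()) / sd if sd > 0 else np.zeros_like(img)
    if dmap is None:
        return z[None].astype(np.float32)
    dmap = np.asarray(dmap)
    if dmap.shape != img.shape:
        raise ValueError(f"map shape {dmap.shape} != image shape {img.shape}")
    return np.stack([z, dmap]).astype(np.float32)


def save_map(path, values: np.ndarray, variant: str, **params) -> None:
    """Save a map as .npy with a JSON sidecar recording variant/parameters."""
    path = pathlib.Path(path)
    np.save(path, np.asarray(values, dtype=np.float32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"variant": variant, "params": params}))


def load_map(path):
    path = pathlib.Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    values = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return values, meta
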