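"""Gradient-based graph-search baseline for retinal boundary segmentation.

Each boundary is the minimum-cost left-to-right path across the B-scan under
edge weights derived from the vertical intensity gradient: an edge between
pixels a and b costs ``2 - (g_a + g_b) + w_min``, so paths hug rows where
the rectified gradient is strong.  Virtual zero-cost endpoint columns let
the path start and end at any row.  The path is restricted to monotone
left-to-right moves (up-right / right / down-right), which admits an exact
dynamic-programming solution; ties are broken toward smaller row indices.

The three boundaries are found sequentially: ILM over the whole image, RPE
below the ILM plus a margin, PCV at or above the ILM.  Segmenting the PCV
this way inherits the historical weakness of the approach: when the PCV line
is invisible (at the noise level) the path degenerates toward the ILM, which
is flagged as low confidence in the returned metadata.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .phantom import BoundarySet

W_MIN = 1e-5

__all__ = ["W_MIN", "vertical_gradient", "shortest_boundary", "segment_retina"]


def vertical_gradient(img: np.ndarray, polarity: str = "dark-to-bright") -> np.ndarray:
    """Rectified, min-max-normalised vertical gradient g(y) = I(y) - I(y-1).

    ``dark-to-bright`` keeps positive steps (intensity increasing downward),
    ``bright-to-dark`` keeps negative ones.  A constant image yields an
    all-zero gradient.
    """
    img = np.asarray(img, dtype=np.float64)
    g = np.zeros_like(img)
    g[1:] = np.diff(img, axis=0)
    if polarity == "bright-to-dark":
        g = -g
    elif polarity != "dark-to-bright":
        raise ValueError("polarity must be 'dark-to-bright' or 'bright-to-dark'")
    g = np.maximum(g, 0.0)
    m = g.max()
    return g / m if m > 0 else g


def shortest_boundary(gradient: np.ndarray, allowed: np.ndarray | None = None,
                      w_min: float = W_MIN):
    """Minimum-cost monotone left-to-right path over a gradient image.

    Returns ``(rows, cost)`` with one row per column.  ``allowed`` optionally
    masks out pixels the path may not visit (each column must keep at least
    one allowed pixel).  Among equal-cost paths the topmost is returned.
    """
    g = np.asarray(gradient, dtype=np.float64)
    h, w = g.shape
    big = 1e18
    node_pen = np.zeros((h, w))
    if allowed is not None:
        node_pen = np.where(np.asarray(allowed, bool), 0.0, big)
        if np.any(node_pen.min(axis=0) > 0):
            raise ValueError("a column has no allowed pixels")

    # cost[r] = best cost of a path from the virtual source to (r, c)
    cost = np.zeros(h) + node_pen[:, 0]
    back = np.zeros((h, w), dtype=np.int8)  # -1 up, 0 straight, +1 down
    for c in range(1, w):
        base = 2.0 + w_min - g[:, c]  # minus g_b; g_a added per candidate
        up = np.full(h, big)
        down = np.full(h, big)
        up[1:] = cost[:-1] - g[:-1, c - 1]       # predecessor r-1
        straight = cost - g[:, c - 1]            # predecessor r
        down[:-1] = cost[1:] - g[1:, c - 1]      # predecessor r+1
        cands = np.stack([up, straight, down])   # ordered so argmin prefers
        choice = cands.argmin(axis=0)            # the smaller predecessor row
        cost = cands[choice, np.arange(h)] + base + node_pen[:, c]
        back[:, c] = choice.astype(np.int8) - 1
    rows = np.empty(w, dtype=np.int64)
    rows[-1] = int(cost.argmin())  # argmin returns the topmost tie
    total = float(cost[rows[-1]])
    for c in range(w - 1, 0, -1):
        rows[c - 1] = rows[c] + back[rows[c], c]
    return rows, total


def segment_retina(img: np.ndarray, rpe_margin: int = 20,
                   smooth_sigma: float = 0.0,
                   pcv_polarity: str = "dark-to-bright"):
    """Sequential ILM -> RPE -> PCV graph search.

    Returns ``(BoundarySet, meta)``.  ``smooth_sigma`` optionally Gaussian
    pre-smooths the image (off by default; the historical preprocessing is
    exposed, not imposed).  ``meta['pcv_low_confidence']`` is set when the
    PCV path carries little gradient support, i.e. the line was effectively
    invisible and the path degenerated toward the ILM.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    if h < 32:
        raise ValueError("image too small for boundary search (min 32 rows)")
    work = ndimage.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    rows_idx = np.arange(h)[:, None]

    g_d2b = vertical_gradient(work, "dark-to-bright")
    ilm, _ = shortest_boundary(g_d2b)

    below = rows_idx > (ilm[None, :] + rpe_margin)
    # keep the deepest row available even for thin images
    below[-1, :] = True
    rpe, _ = shortest_boundary(g_d2b, allowed=below)

    g_pcv = vertical_gradient(work, pcv_polarity)
    # suppress the already-found ILM edge so the PCV search does not lock
    # onto it; the path may still ride along the ILM at zero gradient reward
    g_pcv = np.where(np.abs(rows_idx - ilm[None, :]) <= 1, 0.0, g_pcv)
    above = rows_idx <= ilm[None, :]
    pcv, _ = shortest_boundary(g_pcv, allowed=above)

    pcv = np.minimum(pcv, ilm)
    rpe = np.maximum(rpe, ilm)

    ilm_support = g_d2b[ilm, np.arange(w)].mean()
    pcv_support = g_pcv[pcv, np.arange(w)].mean()
    if pcv_support < 0.2 * max(ilm_support, 1e-12):
        # invisible PCV: the path has no gradient support and degenerates
        # toward the ILM
        pcv = ilm.copy()
    low_conf = bool(pcv_support < 0.2 * max(ilm_support, 1e-12)
                    or np.mean(ilm - pcv <= 1) > 0.95)
    meta = {
        "pcv_low_confidence": low_conf,
        "pcv_gradient_support": float(pcv_support),
        "ilm_gradient_support": float(ilm_support),
    }
    return BoundarySet(pcv=pcv.astype(float), ilm=ilm.astype(float),
                       rpe=rpe.astype(float)), meta
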