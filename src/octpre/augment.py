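"""Joint geometric augmentation of image, mask and distance map.

Four transforms are applied in a fixed order -- horizontal flip, rotation,
vertical translation, random crop -- with one parameter draw shared by all
three arrays.  Images and distance maps are interpolated bilinearly with
reflective fill; masks use nearest neighbour, and rows pushed in from
outside the field of view are filled with class 0 at the top and class 3 at
the bottom so augmented ground truth stays topologically valid.  Ranges
default to the calibration used throughout the package: flips with
probability 0.5, rotations within +-20 degrees, vertical shifts within
+-10% of the image height, and per-axis crops of 80-100%.

Image-derived distance maps (CumSum, BasicOrient) are recomputed from the
augmented image rather than transformed; boundary-derived maps (2NetR,
2NetPR) are transformed geometrically with the image.  This preserves each
map's defining property.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "sample_transform", "apply_transform",
           "augment_sample", "expand_dataset"]

_MIN_CROP_PX = 16


@dataclass
class AugmentConfig:
    hflip_prob: float = 0.5
    rot_deg_range: float = 20.0
    vshift_frac: float = 0.10
    crop_frac_range: tuple = (0.80, 1.00)
    copies_per_image: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")
        lo, hi = self.crop_frac_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("crop fractions must satisfy 0 < lo <= hi <= 1")


def sample_transform(cfg: AugmentConfig, rng: np.random.Generator,
                     height: int, width: int) -> dict:
    """Draw one joint transform; returned dict allows exact replay."""
    lo, hi = cfg.crop_frac_range
    ch = int(round(height * rng.uniform(lo, hi)))
    cw = int(round(width * rng.uniform(lo, hi)))
    ch, cw = min(ch, height), min(cw, width)
    if ch < _MIN_CROP_PX or cw < _MIN_CROP_PX:
        raise ValueError("crop smaller than 16 px")
    return {
        "hflip": bool(rng.uniform() < cfg.hflip_prob),
        "angle_deg": float(rng.uniform(-cfg.rot_deg_range, cfg.rot_deg_range)),
        "vshift_px": float(rng.uniform(-cfg.vshift_frac, cfg.vshift_frac) * height),
        "crop": (int(rng.integers(0, height - ch + 1)),
                 int(rng.integers(0, width - cw + 1)), ch, cw),
    }


def _fill_mask_columns(mask: np.ndarray) -> np.ndarray:
    """Replace out-of-view (-1) pixels: leading runs -> 0, trailing -> 3."""
    out = mask.copy()
    h = out.shape[0]
    invalid = out < 0
    if not invalid.any():
        return out
    first_valid = np.where(invalid.all(axis=0), h, (~invalid).argmax(axis=0))
    last_valid = h - 1 - (~invalid)[::-1].argmax(axis=0)
    rows = np.arange(h)[:, None]
    out = np.where(rows < first_valid[None, :], 0, out)
    out = np.where(rows > last_valid[None, :], 3, out)
    # interior fill-ins cannot occur for affine moves, but stay safe
    out[out < 0] = 0
    return out.astype(mask.dtype)


def _geom(img, angle, shift, order, is_mask):
    if is_mask:
        kw = dict(order=0, mode="constant", cval=-1.0)
        arr = img.astype(np.float64)
    else:
        kw = dict(order=1, mode="reflect")
        arr = np.asarray(img, dtype=np.float64)
    if angle != 0.0:
        arr = ndimage.rotate(arr, angle, reshape=False, **kw)
    if shift != 0.0:
        arr = ndimage.shift(arr, (shift, 0.0), **kw)
    if is_mask:
        out = _fill_mask_columns(np.rint(arr).astype(np.int8))
        # nearest-neighbour resampling of thin bands can alias single pixels
        # out of vertical order; a per-column running maximum restores the
        # class ordering while touching only those aliased pixels
        return np.maximum.accumulate(out, axis=0).astype(np.int8)
    return arr


def apply_transform(img, mask, dmap, params: dict):
    """Apply one sampled transform to the aligned (image, mask, map) triple."""
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask)
    if mask.shape != img.shape or (dmap is not None and np.shape(dmap) != img.shape):
        raise ValueError("image, mask and map must share one shape")
    if params["hflip"]:
        img = img[:, ::-1]
        mask = mask[:, ::-1]
        dmap = dmap[:, ::-1] if dmap is not None else None
    angle, shift = params["angle_deg"], params["vshift_px"]
    if angle != 0.0 or shift != 0.0:
        img = _geom(img, angle, shift, 1, False)
        mask = _geom(mask, angle, shift, 0, True)
        if dmap is not None:
            dmap = _geom(dmap, angle, shift, 1, False)
    top, left, ch, cw = params["crop"]
    sl = (slice(top, top + ch), slice(left, left + cw))
    return (np.ascontiguousarray(img[sl]),
            np.ascontiguousarray(mask[sl]),
            np.ascontiguousarray(dmap[sl]) if dmap is not None else None)


def augment_sample(img, mask, dmap, cfg: AugmentConfig,
                   rng: np.random.Generator):
    """Sample and apply one joint transform; returns (img, mask, map, params)."""
    params = sample_transform(cfg, rng, img.shape[0], img.shape[1])
    out = apply_transform(img, mask, dmap, params)
    return (*out, params)


def expand_dataset(samples, cfg: AugmentConfig, recompute_map=None):
    """Offline expansion of the training subset to (1 + copies) x its size.

    ``samples`` is a list of :class:`octpre.phantom.Sample`; validation and
    test samples pass through untouched, and passing a list that contains
    only non-training samples is an error.  ``recompute_map`` optionally maps
    an augmented image to a fresh image-derived distance map (used for the
    CumSum / BasicOrient variants).  Transform parameters are stored on each
    new sample as ``aug_params`` for replay.
    """
    samples = list(samples)
    if not any(s.subset == "train" for s in samples):
        raise ValueError("expand_dataset expects at least one training sample")
    rng = np.random.default_rng((int(cfg.seed), 0xA6))
    out = []
    for s in samples:
        out.append(s)
        if s.subset != "train":
            continue
        for k in range(cfg.copies_per_image):
            img, mask, _, params = augment_sample(s.image, s.mask, None, cfg, rng)
            new = copy.copy(s)
            new.image, new.mask = img, mask
            new.bounds = None  # boundaries are re-extracted from the mask
            new.sample_id = f"{s.sample_id}_aug{k}"
            new.aug_params = params  # type: ignore[attr-defined]
            if recompute_map is not None:
                new.dmap = recompute_map(img)  # type: ignore[attr-defined]
            out.append(new)
    return out
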