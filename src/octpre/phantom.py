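"""Synthetic OCT B-scan phantoms with exact ground truth.

The generator emulates the statistical structure of macular OCT volumes from
vitreomacular-interface patients: four vertically ordered regions (vitreous /
preretinal space / retina / below retina), a dark vitreous and preretinal
space of near-identical intensity separated only by a thin hyperreflective
PCV line of varying visibility, retina tilt and vertical-position spread,
VMA (PCV adherent to the ILM) vs VMT (PCV elevated with a central adhesion)
shapes, and multiplicative speckle noise.  Every phantom comes with its
generating boundary lines and a topologically valid class mask, so all other
modules are testable without any real data.

Coordinate convention: 0-based rows, row 0 at the top, y grows downward.  A
boundary value is the (float) row coordinate of the first pixel of the region
below it, so class 1 (preretinal space) occupies rows [pcv, ilm) and class 2
(retina) rows [ilm, rpe].
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np

VOXEL_UM = (3.125, 18.18, 49.65)  # y (depth), x (fast scan), z (slice)
CLASS_NAMES = ("Vitreous", "PreretinalSpace", "Retina", "SpaceUnderRetina")

__all__ = [
    "VOXEL_UM",
    "CLASS_NAMES",
    "PhantomConfig",
    "BoundarySet",
    "Sample",
    "generate_boundaries",
    "render_bscan",
    "generate_phantom",
    "generate_samples",
    "generate_dataset",
    "split_sizes",
    "save_sample",
    "load_sample",
]


@dataclass(frozen=True)
class BoundarySet:
    """Per-column row coordinates of the PCV, ILM and RPE lines."""

    pcv: np.ndarray
    ilm: np.ndarray
    rpe: np.ndarray

    def __post_init__(self):
        for name in ("pcv", "ilm", "rpe"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=np.float64))
        if not (self.pcv.shape == self.ilm.shape == self.rpe.shape):
            raise ValueError("boundary lines must share one length")

    @property
    def width(self) -> int:
        return self.pcv.shape[0]

    def validate(self, height: int) -> None:
        ok = (np.all(self.pcv >= 0) and np.all(self.pcv <= self.ilm)
              and np.all(self.ilm <= self.rpe) and np.all(self.rpe <= height - 1))
        if not ok:
            raise ValueError("boundary ordering 0 <= pcv <= ilm <= rpe <= H-1 violated")

    def to_csv(self, path) -> None:
        arr = np.column_stack([np.arange(self.width), self.pcv, self.ilm, self.rpe])
        np.savetxt(path, arr, delimiter=",", header="x,pcv,ilm,rpe", comments="")

    @classmethod
    def from_csv(cls, path) -> "BoundarySet":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(pcv=arr[:, 1], ilm=arr[:, 2], rpe=arr[:, 3])


@dataclass
class PhantomConfig:
    """Shape/intensity statistics of one synthetic B-scan.

    Defaults mirror the acquisition geometry the package targets: 640x384 px
    scans, a ~64 px (about 200 um at 3.125 um/px) retina with +-10 px
    thickness jitter, tilt sampled within +-20 degrees, vertical retina
    position within +-10% of the image height, and a PCV line rendered at
    full contrast on 70% of the columns.  ``speckle_shape`` is the shape
    parameter of unit-mean multiplicative gamma noise; None disables noise.
    Sizes are scaled with ``PhantomConfig.for_size`` for smaller test scans.
    """

    height: int = 640
    width: int = 384
    retina_thickness_px: float = 64.0
    retina_thickness_jitter: float = 10.0
    orientation_deg: float = 20.0
    center_shift_frac: float = 0.10
    case_type: str = "VMA"
    pcv_visibility: float = 0.7
    speckle_shape: float | None = 8.0
    vma_detach_px: float = 45.0
    vmt_elevation_px: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.height <= 16 or self.width <= 16:
            raise ValueError("height and width must exceed 16")
        if self.height % 16 or self.width % 16:
            raise ValueError("height and width must be divisible by 16")
        if not 0.0 <= self.pcv_visibility <= 1.0:
            raise ValueError("pcv_visibility must lie in [0, 1]")
        if self.case_type not in ("VMA", "VMT"):
            raise ValueError("case_type must be 'VMA' or 'VMT'")

    @classmethod
    def for_size(cls, height: int, width: int, **overrides) -> "PhantomConfig":
        """Config with depth-dependent defaults scaled by height/640."""
        s = height / 640.0
        kw = dict(
            height=height,
            width=width,
            retina_thickness_px=64.0 * s,
            retina_thickness_jitter=10.0 * s,
            vma_detach_px=max(45.0 * s, 4.0),
            vmt_elevation_px=max(100.0 * s, 12.0),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class Sample:
    """One phantom: image, mask, generating boundaries and bookkeeping."""

    image: np.ndarray
    mask: np.ndarray
    bounds: BoundarySet
    case_type: str
    seed: int
    subset: str = "train"
    sample_id: str = ""
    group: int = 0  # volume-level grouping key for leakage-free splits


def _smooth_noise(rng, width, n_knots, lo, hi):
    """Low-frequency random profile: linear interp between random knots."""
    knots = rng.uniform(lo, hi, size=n_knots)
    xk = np.linspace(0, width - 1, n_knots)
    return np.interp(np.arange(width), xk, knots)


def generate_boundaries(cfg: PhantomConfig) -> BoundarySet:
    """Sample smooth PCV/ILM/RPE lines for one phantom.

    The ILM is a tilted low-frequency profile with a central foveal pit; the
    RPE follows it at the sampled retina thickness (retina thinner under the
    pit); the PCV detaches around an exact central adhesion zone -- shallowly
    and over a wide attachment for VMA, by tens of pixels off a narrow
    residual adhesion for VMT.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng((int(cfg.seed), 0xB0))
    h, w = cfg.height, cfg.width
    s = h / 640.0
    x = np.arange(w, dtype=np.float64)

    angle = np.radians(rng.uniform(-cfg.orientation_deg, cfg.orientation_deg))
    center = h * (0.55 + rng.uniform(-cfg.center_shift_frac, cfg.center_shift_frac))
    tilt = np.tan(angle) * (x - w / 2.0)
    wave = _smooth_noise(rng, w, 6, -0.015 * h, 0.015 * h)
    base = center + tilt + wave

    # foveal pit in the ILM; the RPE stays smooth
    xc = w * rng.uniform(0.4, 0.6)
    pit_depth = s * rng.uniform(12.0, 22.0)
    pit_sigma = w * rng.uniform(0.04, 0.07)
    pit = pit_depth * np.exp(-0.5 * ((x - xc) / pit_sigma) ** 2)

    thickness = max(cfg.retina_thickness_px
                    + rng.normal(0.0, cfg.retina_thickness_jitter), 8.0 * s)
    thick_prof = thickness * (1.0 - 0.25 * np.exp(-0.5 * ((x - xc) / (1.5 * pit_sigma)) ** 2))

    ilm = base + np.minimum(pit, 0.8 * thick_prof)
    rpe = base + thick_prof
    ilm = np.minimum(ilm, rpe)

    # Both cases share the shape family -- a detached perifovea with a
    # central adhesion zone where pcv == ilm exactly -- and differ in
    # elevation amplitude and adhesion width: VMA detaches shallowly around
    # a wide attachment, VMT pulls the vitreous tens of pixels off a narrow
    # residual adhesion.  Amplitudes are calibrated so that mean per-column
    # gaps land near the clinically measured preretinal volumes (roughly 20
    # px for VMA and 80 px for VMT at 640-px scale).
    if cfg.case_type == "VMA":
        elev_amp = cfg.vma_detach_px * rng.uniform(0.7, 1.5)
        adh_sigma = w * rng.uniform(0.15, 0.30)
    else:
        elev_amp = cfg.vmt_elevation_px * rng.uniform(0.8, 1.4)
        adh_sigma = w * rng.uniform(0.06, 0.12)
    elev = elev_amp * (1.0 - np.exp(-0.5 * ((x - xc) / adh_sigma) ** 2))
    elev = elev + np.abs(x - xc) / adh_sigma \
        * _smooth_noise(rng, w, 6, -0.05 * elev_amp, 0.05 * elev_amp)
    # soft-threshold: an exact central adhesion zone (pcv == ilm) with a
    # continuous, bounded-slope transition into the elevated region
    elev = np.maximum(elev - 0.05 * elev_amp, 0.0)
    # keep the detached cortex inside the field of view
    elev = np.minimum(elev, np.maximum(ilm - 2.0, 0.0))
    pcv = ilm - elev

    pcv = np.clip(pcv, 0.0, ilm)
    if rpe.max() > h - 2 or ilm.min() < 1:
        raise ValueError(
            "config ranges force the retina outside the image "
            f"(rpe max {rpe.max():.1f}, ilm min {ilm.min():.1f}, height {h})")
    return BoundarySet(pcv=pcv, ilm=ilm, rpe=rpe)


def _region_starts(bounds: BoundarySet):
    """Integer first rows of classes 1, 2 and 3 (nearest-pixel rasterisation)."""
    r1 = np.ceil(bounds.pcv - 0.5).astype(np.int64)
    r2 = np.ceil(bounds.ilm - 0.5).astype(np.int64)
    r3 = np.ceil(bounds.rpe + 0.5).astype(np.int64)
    return r1, r2, r3


def render_bscan(bounds: BoundarySet, cfg: PhantomConfig):
    """Rasterise boundaries into a (image, mask) pair.

    The mask assigns class 0 above the PCV, 1 in [pcv, ilm), 2 in [ilm, rpe]
    and 3 below.  The vitreous and preretinal space share the same base
    intensity (deliberately, so only the PCV line separates classes 0 and 1);
    the retina is a stack of bright bands; the PCV line is a 1-2 px bright
    run rendered only where it is elevated at least one pixel off the ILM and
    only on a ``pcv_visibility`` fraction of the columns.  Multiplicative
    gamma speckle is applied last and the image clipped to [0, 1].
    """
    bounds.validate(cfg.height)
    rng = np.random.default_rng((int(cfg.seed), 0x1E))
    h, w = cfg.height, cfg.width
    y = np.arange(h, dtype=np.int64)[:, None]
    r1, r2, r3 = _region_starts(bounds)

    mask = ((y >= r1[None, :]).astype(np.int8)
            + (y >= r2[None, :]).astype(np.int8)
            + (y >= r3[None, :]).astype(np.int8))

    img = np.full((h, w), 0.05, dtype=np.float64)
    img[mask == 3] = 0.2
    # retina bands as a function of relative depth within [ilm, rpe]
    t = (y - bounds.ilm[None, :]) / np.maximum(bounds.rpe - bounds.ilm, 1.0)[None, :]
    retina = np.where(t < 0.15, 0.85, 0.40)
    img = np.where(mask == 2, retina, img)
    # the RPE itself: thin hyperreflective line at the last retina row
    cols = np.arange(w)
    last_c2 = np.clip(r3 - 1, 0, h - 1)
    img[last_c2, cols] = np.where(mask[last_c2, cols] == 2, 0.90,
                                  img[last_c2, cols])

    # PCV line: a 2-px bright run at the top of the preretinal space,
    # rendered only where the PCV is at least a pixel off the ILM and only
    # on a pcv_visibility fraction of columns -- the varying visibility is
    # what makes this boundary hard
    visible = _visibility_mask(rng, w, cfg.pcv_visibility)
    elevated = (r2 - r1) >= 1
    cols = np.where(visible & elevated)[0]
    for cx in cols:
        top = r1[cx]
        img[top:min(top + 2, r2[cx]), cx] = 0.55

    if cfg.speckle_shape is not None and cfg.speckle_shape > 0:
        img *= rng.gamma(cfg.speckle_shape, 1.0 / cfg.speckle_shape, size=img.shape)
    return np.clip(img, 0.0, 1.0), mask


def _visibility_mask(rng, width, visibility):
    if visibility >= 1.0:
        return np.ones(width, dtype=bool)
    if visibility <= 0.0:
        return np.zeros(width, dtype=bool)
    # threshold a smooth field so visible columns form contiguous runs
    f = _smooth_noise(rng, width, max(6, width // 32), 0.0, 1.0)
    thr = np.quantile(f, 1.0 - visibility)
    return f >= thr


def generate_phantom(cfg: PhantomConfig):
    """Boundaries + rendering in one call -> (image, mask, bounds)."""
    bounds = generate_boundaries(cfg)
    img, mask = render_bscan(bounds, cfg)
    return img, mask, bounds


def split_sizes(n: int, split=(0.8, 0.1, 0.1)):
    """Validation/test get floor(ratio*n); the remainder goes to training."""
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    n_val = int(np.floor(split[1] * n))
    n_test = int(np.floor(split[2] * n))
    return n - n_val - n_test, n_val, n_test


def generate_samples(n: int, height: int = 640, width: int = 384,
                     split=(0.8, 0.1, 0.1), seed: int = 0,
                     case_mix: float = 0.5, scans_per_volume: int = 1,
                     **cfg_overrides) -> list[Sample]:
    """Generate ``n`` phantoms in memory with train/val/test subset tags.

    ``case_mix`` is the fraction of VMT cases; consecutive blocks of
    ``scans_per_volume`` phantoms share a group id (a synthetic "volume") so
    splits can be made leakage-free.  Deterministic given ``seed``.
    """
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    n_train, n_val, n_test = split_sizes(n, split)
    tags = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    if scans_per_volume > 1:
        # keep every synthetic volume inside one subset (leakage-free split);
        # subset sizes may shift by at most one volume
        for start in range(0, n, scans_per_volume):
            tags[start:start + scans_per_volume] = \
                [tags[start]] * len(tags[start:start + scans_per_volume])
    rng = np.random.default_rng((int(seed), 0xDA))
    samples = []
    for i in range(n):
        case = "VMT" if rng.uniform() < case_mix else "VMA"
        sample_seed = int(rng.integers(0, 2**31 - 1))
        cfg = PhantomConfig.for_size(height, width, case_type=case,
                                     seed=sample_seed, **cfg_overrides)
        img, mask, bounds = generate_phantom(cfg)
        samples.append(Sample(image=img, mask=mask, bounds=bounds,
                              case_type=case, seed=sample_seed, subset=tags[i],
                              sample_id=f"phantom_{i:05d}",
                              group=i // max(scans_per_volume, 1)))
    return samples


def save_sample(sample: Sample, out_dir) -> dict:
    """Write image (16-bit PNG), mask (8-bit PNG) and boundaries (CSV)."""
    import imageio.v3 as iio

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = sample.sample_id
    img_path = out_dir / f"{sid}_img.png"
    mask_path = out_dir / f"{sid}_mask.png"
    csv_path = out_dir / f"{sid}_bounds.csv"
    iio.imwrite(img_path, (np.clip(sample.image, 0, 1) * 65535).astype(np.uint16))
    iio.imwrite(mask_path, sample.mask.astype(np.uint8))
    sample.bounds.to_csv(csv_path)
    return {
        "id": sid,
        "subset": sample.subset,
        "case_type": sample.case_type,
        "seed": sample.seed,
        "group": sample.group,
        "image": img_path.name,
        "mask": mask_path.name,
        "bounds": csv_path.name,
    }


def load_sample(entry: dict, data_dir) -> Sample:
    import imageio.v3 as iio

    data_dir = pathlib.Path(data_dir)
    img = iio.imread(data_dir / entry["image"]).astype(np.float64) / 65535.0
    mask = iio.imread(data_dir / entry["mask"]).astype(np.int8)
    bounds = BoundarySet.from_csv(data_dir / entry["bounds"])
    return Sample(image=img, mask=mask, bounds=bounds,
                  case_type=entry["case_type"], seed=entry["seed"],
                  subset=entry["subset"], sample_id=entry["id"],
                  group=entry.get("group", 0))


def generate_dataset(n: int, out_dir, split=(0.8, 0.1, 0.1), seed: int = 0,
                     height: int = 640, width: int = 384,
                     **cfg_overrides) -> dict:
    """Generate phantoms, write them to ``out_dir`` and return the manifest."""
    out_dir = pathlib.Path(out_dir)
    samples = generate_samples(n, height=height, width=width, split=split,
                               seed=seed, **cfg_overrides)
    entries = [save_sample(s, out_dir) for s in samples]
    manifest = {
        "n": n,
        "height": height,
        "width": width,
        "split": list(split),
        "seed": seed,
        "voxel_um": list(VOXEL_UM),
        "samples": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
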