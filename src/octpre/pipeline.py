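"""End-to-end orchestration: normalisation, training loop, evaluation.

The training protocol: Adam (default lr 5e-6, betas 0.9/0.999), batch size 1
(inputs of varying size due to random cropping), at least ``min_epochs``
epochs with early stopping once the validation loss has not improved for
``patience`` consecutive epochs, and evaluation always on the checkpoint
with the lowest validation loss.  The default learning rate suits long runs
on large pools; ``FAST_LR`` (1e-4) is the documented preset for small
phantom-scale experiments.
"""

from __future__ import annotations

import copy
import json
import logging
import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import dmaps, metrics, nets, nn
from .augment import AugmentConfig, expand_dataset
from .losses import (LossConfig, class_weights, one_hot, pixel_weight_map,
                     total_loss, total_loss_grad)
from .phantom import Sample

log = logging.getLogger("octpre")

FAST_LR = 1e-4
MAP_VARIANTS = ("none",) + dmaps.VARIANTS

__all__ = ["FAST_LR", "MAP_VARIANTS", "TrainConfig", "normalize",
           "make_dmap", "prepare_input", "train", "evaluate",
           "save_checkpoint", "load_checkpoint"]


def normalize(img: np.ndarray) -> np.ndarray:
    """Per-image z-score; a zero-variance image returns zeros with a warning."""
    img = np.asarray(img, dtype=np.float64)
    sd = img.std()
    if sd == 0:
        warnings.warn("zero-variance image; normalised output is all zeros")
        return np.zeros_like(img)
    return (img - img.mean()) / sd


@dataclass
class TrainConfig:
    """Hyperparameters of one training run."""

    net: nets.NetSpec = field(default_factory=nets.NetSpec)
    loss: LossConfig | None = None  # None -> lambda_c from training pixel counts
    map_variant: str = "none"
    lr: float = 5e-6
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 1
    min_epochs: int = 50
    max_epochs: int = 500
    patience: int = 5
    augment: AugmentConfig | None = None
    augment_online: bool = False  # resample transforms per step instead of
    # expanding the training pool offline
    seed: int = 0

    def __post_init__(self):
        if self.map_variant not in MAP_VARIANTS:
            raise ValueError(f"map_variant must be one of {MAP_VARIANTS}")
        if self.batch_size != 1:
            raise ValueError("batch size is fixed to 1 (inputs vary in size)")
        if self.augment is not None and not self.augment_online \
                and self.map_variant in ("2NetR", "2NetPR"):
            # offline expansion stores no boundary lines for the augmented
            # copies; boundary-anchored maps are supported in online mode,
            # where the map is transformed geometrically with the image
            raise ValueError(
                "offline augmentation supports image-derived maps only; "
                "use augment_online=True for boundary-anchored maps")

    def to_dict(self) -> dict:
        d = {
            "net": self.net.to_dict(),
            "map_variant": self.map_variant,
            "lr": self.lr, "beta1": self.beta1, "beta2": self.beta2,
            "batch_size": self.batch_size, "min_epochs": self.min_epochs,
            "max_epochs": self.max_epochs, "patience": self.patience,
            "seed": self.seed,
        }
        if self.loss is not None:
            d["loss"] = {"alpha": self.loss.alpha, "beta": self.loss.beta,
                         "q1": self.loss.q1, "q2": self.loss.q2,
                         "lambda_c": list(map(float, self.loss.lambda_c))}
        return d


def make_dmap(sample: Sample, variant: str, prior="gt") -> np.ndarray | None:
    """Distance map for one sample.

    For the boundary-anchored variants the prior boundaries come from the
    sample's ground truth (``prior='gt'``), or from any callable mapping an
    image to a BoundarySet (e.g. the graph-search baseline or an earlier
    model) -- the cascaded retraining of the original two-network scheme is
    out of scope.
    """
    if variant == "none":
        return None
    h = sample.image.shape[0]
    if variant == "CumSum":
        return dmaps.map_cumsum(sample.image)
    if variant == "BasicOrient":
        return dmaps.map_basic_orient(sample.image)
    bounds = sample.bounds if prior == "gt" else prior(sample.image)
    if bounds is None:
        bounds, _ = metrics.extract_boundaries(sample.mask)
    if variant == "2NetR":
        return dmaps.map_2netR(bounds.ilm, bounds.rpe, h)
    if variant == "2NetPR":
        return dmaps.map_2netPR(bounds.pcv, bounds.ilm, bounds.rpe, h)
    raise ValueError(f"unknown map variant {variant!r}")


def prepare_input(sample: Sample, variant: str, prior="gt") -> np.ndarray:
    """Z-scored image stacked with its distance map -> (C, H, W) float32."""
    dmap = getattr(sample, "dmap", None)
    if dmap is None:
        dmap = make_dmap(sample, variant, prior)
    return dmaps.attach_map(sample.image, dmap)


def _dataset_lambda(samples) -> np.ndarray:
    counts = np.zeros(4)
    for s in samples:
        counts += np.bincount(np.asarray(s.mask).ravel(), minlength=4)
    if np.any(counts == 0):
        # merge absent classes into a uniform floor so weights stay defined
        counts = np.maximum(counts, 1.0)
    return class_weights(counts)


def train(samples, cfg: TrainConfig, prior="gt"):
    """Train one network; returns ``(model, history)``.

    ``samples`` must contain 'train' and 'val' subsets.  The model returned
    carries the weights of the epoch with the lowest validation loss, never
    the last epoch.  All randomness is derived from ``cfg.seed``.
    """
    train_set = [s for s in samples if s.subset == "train"]
    val_set = [s for s in samples if s.subset == "val"]
    if not train_set or not val_set:
        raise ValueError("need non-empty train and val subsets")

    recompute = None
    if cfg.map_variant == "CumSum":
        recompute = dmaps.map_cumsum
    elif cfg.map_variant == "BasicOrient":
        recompute = dmaps.map_basic_orient
    if cfg.augment is not None and not cfg.augment_online:
        pool = expand_dataset(samples, cfg.augment, recompute_map=recompute)
        train_set = [s for s in pool if s.subset == "train"]

    loss_cfg = cfg.loss
    if loss_cfg is None:
        loss_cfg = LossConfig(lambda_c=_dataset_lambda(train_set))

    if cfg.map_variant != "none" and cfg.net.in_channels != 2:
        raise ValueError("map variants require in_channels=2")

    def pack(s):
        gt1h = one_hot(np.asarray(s.mask))
        return (prepare_input(s, cfg.map_variant, prior), gt1h,
                pixel_weight_map(gt1h, loss_cfg.q1, loss_cfg.q2))

    online = cfg.augment is not None and cfg.augment_online
    if online:
        from .augment import augment_sample

        aug_rng = np.random.default_rng((int(cfg.seed), 0xA7))
        raw = [(s.image, np.asarray(s.mask),
                make_dmap(s, cfg.map_variant, prior)) for s in train_set]

        def step_data(i):
            img, mask, dmap = raw[i]
            img, mask, dmap, _ = augment_sample(img, mask, dmap,
                                                cfg.augment, aug_rng)
            if recompute is not None:
                dmap = recompute(img)
            gt1h = one_hot(mask)
            return (dmaps.attach_map(img, dmap), gt1h,
                    pixel_weight_map(gt1h, loss_cfg.q1, loss_cfg.q2))
    else:
        train_data = [pack(s) for s in train_set]

        def step_data(i):
            return train_data[i]

    n_train = len(train_set)
    val_data = [pack(s) for s in val_set]

    model = nets.build_network(cfg.net)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    rng = np.random.default_rng((int(cfg.seed), 0x7A))

    history = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_val = np.inf
    best_state = None
    stall = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_train)
        ep_loss = 0.0
        for i in order:
            x, gt1h, wmap = step_data(i)
            probs_t = nets.forward_probs(model, x, training=True)
            p = probs_t.data[0].astype(np.float64)
            loss = total_loss(gt1h, p, loss_cfg, wmap)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, sample {i}: {loss}")
            grad = total_loss_grad(gt1h, p, loss_cfg, wmap)
            opt.zero_grad()
            probs_t.backward(grad[None].astype(np.float32))
            opt.step()
            ep_loss += loss
        ep_loss /= n_train

        val_loss = 0.0
        for x, gt1h, wmap in val_data:
            p = nets.forward_probs(model, x, training=False).data[0]
            val_loss += total_loss(gt1h, p.astype(np.float64), loss_cfg, wmap)
        val_loss /= len(val_data)

        history["train_loss"].append(float(ep_loss))
        history["val_loss"].append(float(val_loss))
        log.info("epoch %d: train %.5f val %.5f", epoch, ep_loss, val_loss)

        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            history["best_epoch"] = epoch
            stall = 0
        else:
            stall += 1
        # early stopping armed only after the minimum epoch count
        if epoch + 1 >= cfg.min_epochs and stall >= cfg.patience:
            break

    if best_state is not None:
        model.set_state(best_state)
    history["lambda_c"] = list(map(float, loss_cfg.lambda_c))
    return model, history


def evaluate(model, samples, map_variant: str = "none", subset: str | None = "test",
             prior="gt") -> metrics.EvalReport:
    """Predict every sample of ``subset`` and aggregate the evaluation report."""
    chosen = [s for s in samples if subset is None or s.subset == subset]
    if not chosen:
        raise ValueError(f"no samples in subset {subset!r}")
    gt_masks, pred_masks, gt_bounds = [], [], []
    for s in chosen:
        x = prepare_input(s, map_variant, prior)
        _, pred = nets.predict(model, x)
        gt_masks.append(np.asarray(s.mask))
        pred_masks.append(pred)
        gt_bounds.append(s.bounds if s.bounds is not None
                         else metrics.extract_boundaries(s.mask)[0])
    return metrics.evaluate_masks(gt_masks, pred_masks, gt_bounds=gt_bounds)


def save_checkpoint(path, model, cfg: TrainConfig, history: dict) -> None:
    """Weights as .npz plus a JSON sidecar with spec, config and best epoch."""
    path = pathlib.Path(path)
    state = model.get_state()
    arrays = {f"param_{i}": a for i, a in enumerate(state["params"])}
    for i, s in enumerate(state["bn"]):
        arrays[f"bn_{i}_mean"] = s["mean"]
        arrays[f"bn_{i}_var"] = s["var"]
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "net_spec": cfg.net.to_dict(),
        "train_config": cfg.to_dict(),
        "best_epoch": history.get("best_epoch", -1),
        "val_loss": history.get("val_loss", []),
        "train_loss": history.get("train_loss", []),
        "n_bn_states": len(state["bn"]),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path):
    """Rebuild the model from an .npz checkpoint and its JSON sidecar."""
    path = pathlib.Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = nets.NetSpec.from_dict(meta["net_spec"])
    model = nets.build_network(spec)
    data = np.load(path.with_suffix(".npz"))
    n_params = len(model.parameters())
    state = {
        "params": [data[f"param_{i}"] for i in range(n_params)],
        "bn": [{"mean": data[f"bn_{i}_mean"], "var": data[f"bn_{i}_var"]}
               for i in range(meta["n_bn_states"])],
    }
    model.set_state(state)
    return model, meta
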