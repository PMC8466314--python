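"""Per-ROI U-Net ensemble: training, pooled prediction, Dice validation.

Twelve independent networks are trained, one per ROI (ten muscle groups,
VAT, SAT), each against only its own binary ground-truth mask.  At
prediction time each network's probability map is thresholded at 0.5,
the ten muscle masks are pooled (pixel-wise union) into the muscle ROI,
and every mask is finally gated with its tissue Hounsfield window so
predicted and ground-truth masks are definitionally comparable.

Training uses the Adam optimizer (initial learning rate 1e-3) with a
soft-Dice loss, an internal validation split for early stopping, and a
configurable epoch budget.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from compoct.bodycomp import PatientMeta, compute_indices
from compoct.groundtruth import ROIMaskSet, gate_hu, window_for_roi
from compoct.nn import dice_bce_grad_z, soft_dice_loss
from compoct.phantom import HUSlice
from compoct.rois import ROI_NAMES
from compoct.unet import UNet

__all__ = [
    "UNetConfig",
    "SegmentationEnsemble",
    "EvalReport",
    "build_unet",
    "train_ensemble",
    "predict_masks",
    "dice",
    "evaluate",
    "normalize_hu",
]

#: HU clip range for input normalization; brackets both tissue windows.
_CLIP_LO, _CLIP_HI = -200.0, 250.0


@dataclass(frozen=True)
class UNetConfig:
    """Training configuration shared by all twelve networks."""

    depth: int = 6
    initial_lr: float = 1e-3
    optimizer: str = "adam"
    max_epochs: int = 300
    loss: str = "soft_dice_bce"
    bce_weight: float = 1.0
    bce_pos_weight: float = 5.0
    batch_size: int = 4
    input_size: int = 128
    intensity_normalization: str = "clip[-200,250]+minmax"
    validation_fraction: float = 0.2
    seed: int = 0
    base_channels: int = 6
    max_channels: int = 32
    min_epochs: int = 10
    early_stop_patience: int = 6
    early_stop_min_delta: float = 0.002
    target_val_loss: float = 0.005
    # a network that has learned nothing after restart_check_epoch epochs
    # (validation loss still near 1) is reinitialized with a fresh seed
    restart_check_epoch: int = 5
    restart_threshold: float = 0.9
    max_restarts: int = 2

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 < self.initial_lr < 1:
            raise ValueError("initial_lr must be in (0, 1)")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss not in ("soft_dice", "soft_dice_bce"):
            raise ValueError(f"unsupported loss {self.loss!r}")


def build_unet(config: UNetConfig, seed: int | None = None) -> UNet:
    """Instantiate one network; fails if pooling would lose shape."""
    stride = 2 ** (config.depth - 1)
    if config.input_size % stride:
        raise ValueError(
            f"input_size {config.input_size} not divisible by "
            f"2**(depth-1) = {stride}"
        )
    return UNet(
        depth=config.depth,
        base_channels=config.base_channels,
        max_channels=config.max_channels,
        seed=config.seed if seed is None else seed,
    )


def normalize_hu(values: np.ndarray) -> np.ndarray:
    """Clip HU to [-200, 250] and min-max scale to [0, 1] (float32)."""
    v = np.clip(values, _CLIP_LO, _CLIP_HI)
    return ((v - _CLIP_LO) / (_CLIP_HI - _CLIP_LO)).astype(np.float32)


@dataclass
class SegmentationEnsemble:
    """Twelve trained networks plus their shared config and loss curves."""

    networks: dict[str, UNet]
    config: UNetConfig
    training_report: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in ROI_NAMES if r not in self.networks]
        if missing:
            raise KeyError(f"ensemble missing networks for: {missing}")

    # -- checkpointing --------------------------------------------------
    def save(self, directory: str | pathlib.Path) -> None:
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for roi, net in self.networks.items():
            np.savez(d / f"{roi}.npz", *net.get_state())
        manifest = {
            "config": asdict(self.config),
            "rois": list(ROI_NAMES),
            "training_report": self.training_report,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | pathlib.Path) -> "SegmentationEnsemble":
        d = pathlib.Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        config = UNetConfig(**manifest["config"])
        networks = {}
        for roi in manifest["rois"]:
            net = build_unet(config)
            with np.load(d / f"{roi}.npz") as z:
                net.set_state([z[k] for k in z.files])
            networks[roi] = net
        return cls(networks=networks, config=config,
                   training_report=manifest.get("training_report", {}))


def _stack(pairs: Sequence[tuple[HUSlice, ROIMaskSet]],
           config: UNetConfig) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    size = (config.input_size, config.input_size)
    xs, ys = [], {roi: [] for roi in ROI_NAMES}
    for slc, masks in pairs:
        if slc.shape != size:
            raise ValueError(
                f"slice shape {slc.shape} incompatible with configured "
                f"input_size {config.input_size}"
            )
        xs.append(normalize_hu(slc.values)[None])
        for roi in ROI_NAMES:
            ys[roi].append(masks[roi][None].astype(np.float32))
    x = np.stack(xs)
    y = {roi: np.stack(v) for roi, v in ys.items()}
    return x, y


def _eval_loss(net: UNet, x: np.ndarray, y: np.ndarray, batch: int,
               inwin: np.ndarray | None = None) -> float:
    """Validation loss = 1 - Dice of the thresholded prediction, gated by
    the ROI's HU window when ``inwin`` is given -- the same quantity the
    ensemble is ultimately judged on."""
    inter = total = 0.0
    for i in range(0, len(x), batch):
        p = net.forward(x[i:i + batch], train=False) >= 0.5
        if inwin is not None:
            p &= inwin[i:i + batch]
        t = y[i:i + batch] > 0.5
        inter += float((p & t).sum())
        total += float(p.sum() + t.sum())
    if total == 0:
        return 0.0
    return 1.0 - 2.0 * inter / total


def _train_one(x: np.ndarray, y: np.ndarray, config: UNetConfig,
               seed: int, inwin: np.ndarray | None = None) -> tuple[UNet, dict]:
    rng = np.random.default_rng(seed)
    n = len(x)
    n_val = max(1, int(round(config.validation_fraction * n))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx = perm
    xv, yv = x[val_idx], y[val_idx]
    wv = inwin[val_idx] if inwin is not None else None
    xt, yt = x[tr_idx], y[tr_idx]
    bce_w = config.bce_weight if config.loss == "soft_dice_bce" else 0.0

    for attempt in range(config.max_restarts + 1):
        net = build_unet(config, seed=seed + 104729 * attempt)
        opt = net.make_optimizer(config.initial_lr)
        history = {"train_loss": [], "val_loss": [], "best_epoch": 0,
                   "restarts": attempt}
        best_loss = np.inf
        best_state = net.get_state()
        stale = 0
        restart = False
        for epoch in range(config.max_epochs):
            order = rng.permutation(len(xt))
            ep_loss = 0.0
            nb = 0
            for i in range(0, len(xt), config.batch_size):
                idx = order[i:i + config.batch_size]
                p = net.forward(xt[idx], train=True)
                dice_l, _bce, dz = dice_bce_grad_z(
                    p, yt[idx], bce_weight=bce_w,
                    pos_weight=config.bce_pos_weight)
                net.backward_from_logits(dz)
                opt.step(net.grads())
                ep_loss += dice_l
                nb += 1
            history["train_loss"].append(ep_loss / max(nb, 1))
            vl = (_eval_loss(net, xv, yv, config.batch_size, wv)
                  if n_val else history["train_loss"][-1])
            history["val_loss"].append(vl)
            if vl < best_loss:
                if vl >= best_loss - config.early_stop_min_delta:
                    stale += 1  # an improvement too small to reset patience
                else:
                    stale = 0
                best_loss = vl
                best_state = net.get_state()
                history["best_epoch"] = epoch
            else:
                stale += 1
            if (epoch + 1 == config.restart_check_epoch
                    and best_loss > config.restart_threshold
                    and attempt < config.max_restarts):
                restart = True  # saturated empty prediction: fresh init
                break
            if vl <= config.target_val_loss:
                break
            if (epoch + 1 >= config.min_epochs
                    and stale >= config.early_stop_patience):
                break
        if not restart:
            break
    net.set_state(best_state)
    if not np.all(np.isfinite(history["train_loss"])):
        raise RuntimeError("training diverged: non-finite loss")
    return net, history


def train_ensemble(train: Sequence[tuple[HUSlice, ROIMaskSet]],
                   config: UNetConfig | None = None) -> SegmentationEnsemble:
    """Train one network per ROI against its own ground-truth masks.

    Raises
    ------
    ValueError
        If fewer than two training pairs are given or a ROI is empty in
        every training slice (that network would have nothing to learn).
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training pairs")
    config = config or UNetConfig()
    x, y = _stack(train, config)
    empty = [roi for roi in ROI_NAMES if y[roi].sum() == 0]
    if empty:
        raise ValueError(f"ROI(s) empty in every training slice: {empty}")
    # per-slice HU-window membership, used to gate validation predictions
    inwin = {
        "muscle": np.stack([
            window_for_roi("muscle").contains(slc.values)[None]
            for slc, _ in train]),
        "fat": np.stack([
            window_for_roi("VAT").contains(slc.values)[None]
            for slc, _ in train]),
    }

    networks, report = {}, {}
    for k, roi in enumerate(ROI_NAMES):
        win = inwin["fat" if roi in ("VAT", "SAT") else "muscle"]
        net, history = _train_one(x, y[roi], config,
                                  seed=config.seed + 1000 * k, inwin=win)
        networks[roi] = net
        report[roi] = history
    return SegmentationEnsemble(networks=networks, config=config,
                                training_report=report)


def predict_masks(ensemble: SegmentationEnsemble, slc: HUSlice) -> ROIMaskSet:
    """Segment one slice: threshold at 0.5, then HU-gate each mask."""
    size = (ensemble.config.input_size, ensemble.config.input_size)
    if slc.shape != size:
        raise ValueError(
            f"slice shape {slc.shape} incompatible with configured "
            f"input_size {ensemble.config.input_size}"
        )
    x = normalize_hu(slc.values)[None, None]
    masks = {}
    for roi in ROI_NAMES:
        p = ensemble.networks[roi].forward(x, train=False)[0, 0]
        masks[roi] = gate_hu(slc, p >= 0.5, window_for_roi(roi))
    return ROIMaskSet(masks=masks, provenance="predicted")


def dice(a: np.ndarray, m: np.ndarray) -> float:
    """Dice overlap 2|A n M| / (|A| + |M|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    m = np.asarray(m, dtype=bool)
    if a.shape != m.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {m.shape}")
    denom = int(a.sum()) + int(m.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & m).sum()) / denom


@dataclass
class EvalReport:
    """Held-out segmentation performance.

    ``dice`` holds (mean, sd) per class over the test set for the pooled
    muscle ROI, SAT and VAT; ``abs_diff`` holds (mean, sd) of
    |automatic - manual| for SMI, MA and the fat indices;
    ``pixel_count_correlation`` is the Pearson r between predicted and
    ground-truth pixel counts per class.
    """

    dice: dict[str, tuple[float, float]]
    abs_diff: dict[str, tuple[float, float]]
    pixel_count_correlation: dict[str, float]
    n: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.allclose(a, b):
        return 1.0
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _meta_from_slice(slc: HUSlice) -> PatientMeta:
    md = slc.metadata
    h = float(md.get("height_m", 1.75))
    return PatientMeta(sex=md.get("sex", "male"), height_m=h,
                       weight_kg=24.0 * h * h, age_years=50.0)


def evaluate(ensemble: SegmentationEnsemble,
             test: Sequence[tuple]) -> EvalReport:
    """Compare ensemble predictions with ground truth on a test set.

    ``test`` items are ``(slice, mask_set)`` or
    ``(slice, mask_set, patient_meta)``; when metadata is omitted it is
    reconstructed from the slice provenance.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    classes = ("muscle", "SAT", "VAT")
    d = {c: [] for c in classes}
    counts_pred = {c: [] for c in classes}
    counts_true = {c: [] for c in classes}
    diffs = {k: [] for k in ("smi", "ma_hu", "sat_index", "vat_index")}
    for item in test:
        slc, truth = item[0], item[1]
        meta = item[2] if len(item) > 2 else _meta_from_slice(slc)
        pred = predict_masks(ensemble, slc)
        pairs = {"muscle": (pred.muscle, truth.muscle),
                 "SAT": (pred["SAT"], truth["SAT"]),
                 "VAT": (pred["VAT"], truth["VAT"])}
        for c, (pm, tm) in pairs.items():
            d[c].append(dice(pm, tm))
            counts_pred[c].append(int(pm.sum()))
            counts_true[c].append(int(tm.sum()))
        bc_pred = compute_indices(slc, pred, meta)
        bc_true = compute_indices(slc, truth, meta)
        for k in diffs:
            a, b = getattr(bc_pred, k), getattr(bc_true, k)
            if np.isnan(a) or np.isnan(b):
                continue
            diffs[k].append(abs(a - b))
    return EvalReport(
        dice={c: (float(np.mean(v)), float(np.std(v))) for c, v in d.items()},
        abs_diff={k: ((float(np.mean(v)), float(np.std(v))) if v else (float("nan"),) * 2)
                  for k, v in diffs.items()},
        pixel_count_correlation={
            c: _pearson(counts_pred[c], counts_true[c]) for c in classes},
        n=len(test),
    )
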