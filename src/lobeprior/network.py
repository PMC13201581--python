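"""The two-stage attention U-Net.

Stage 1 runs on the whole CT at low resolution (128^3 at full scale) and
produces coarse masks for the five lobes, the whole lung, and the airway.
Stage 2 refines at high resolution over sliding-window patches from a
13-channel input — CT (1) + probabilistic lobe prior (5) + stage-1 masks
(7) — through one shared encoder and seven independent decoders, one per
structure, each ending in a sigmoid head.

The seven structure channels are ordered (LLL, LUL, RLL, RML, RUL, lung,
airway), i.e. label codes 1..6 with the whole lung inserted at index 5.

Stage 1 cannot put lobes, whole lung, and airway under one softmax (the
lung is a superset of the lobes), so its head is a 6-way softmax over
background + lobes plus two auxiliary sigmoid channels for lung and airway.

Spatial attention gates re-weight each skip connection with a learned
sigmoid heatmap computed from the gating (decoder) feature and the skip
feature before concatenation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .volume_io import CTVolume

log = logging.getLogger(__name__)

STRUCTURES = ("LLL", "LUL", "RLL", "RML", "RUL", "lung", "airway")
N_STRUCTURES = 7
LUNG_CH = 5
AIRWAY_CH = 6

STAGE2_IN_CHANNELS = 1 + 5 + 7  # CT + prior + stage-1 masks = 13


@dataclass
class NetConfig:
    in_channels: int = 1
    base_channels: int = 8
    depth: int = 2
    stage: int = 1
    attention: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        if self.stage == 2 and self.in_channels != STAGE2_IN_CHANNELS:
            raise ValueError(f"stage 2 takes {STAGE2_IN_CHANNELS} input channels")

    @property
    def n_decoders(self) -> int:
        return N_STRUCTURES if self.stage == 2 else 1

    @property
    def head_channels(self) -> int:
        # stage 1: 6-way softmax (BG + lobes) + lung + airway sigmoids
        return 8 if self.stage == 1 else 1


@dataclass
class StagePrediction:
    """Per-structure activations in [0, 1], channel order ``STRUCTURES``."""

    activations: np.ndarray  # (7, Z, H, W)
    stage: int
    grid_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.activations.shape[0] != N_STRUCTURES:
            raise ValueError("expected 7 structure channels")


class AttUNet:
    """Encoder-decoder with spatial-attention-gated skips.

    Channel widths double per level: base, 2*base, ... with the bottleneck
    at ``depth`` poolings. Stage 2 shares the encoder across its seven
    decoder paths.
    """

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, nn.Parameter] = {}
        c = cfg.base_channels
        self.channels = [c * 2**l for l in range(cfg.depth + 1)]
        self._conv("in_proj", cfg.in_channels, self.channels[0], 1, rng)
        for l in range(cfg.depth + 1):
            cin = self.channels[l - 1] if l > 0 else self.channels[0]
            self._conv(f"enc{l}", cin, self.channels[l], 3, rng)
        for d in range(cfg.n_decoders):
            for l in reversed(range(cfg.depth)):
                cup = self.channels[l + 1]
                cskip = self.channels[l]
                if cfg.attention:
                    self._conv(f"dec{d}_att{l}_g", cup, cskip, 1, rng)
                    self._conv(f"dec{d}_att{l}_x", cskip, cskip, 1, rng)
                    self._conv(f"dec{d}_att{l}_psi", cskip, 1, 1, rng)
                self._conv(f"dec{d}_conv{l}", cup + cskip, cskip, 3, rng)
            self._conv(f"dec{d}_head", self.channels[0], cfg.head_channels, 1, rng)

    def _conv(self, name, cin, cout, k, rng):
        self.params[f"{name}_w"] = nn.Parameter(
            nn.he_init(rng, (cout, cin, k, k, k), cin * k**3))
        self.params[f"{name}_b"] = nn.Parameter(np.zeros(cout, dtype=np.float32))

    def _apply(self, name, x):
        return nn.conv3d(x, self.params[f"{name}_w"], self.params[f"{name}_b"])

    def _check_size(self, shape):
        f = 2**self.cfg.depth
        if any(s % f or s < 2 * f for s in shape):
            raise ValueError(
                f"input {shape} incompatible with depth {self.cfg.depth}: "
                f"spatial dims must be multiples of {f} and at least {2 * f}")

    def forward(self, x_np: np.ndarray) -> list[nn.Tensor]:
        """Raw head outputs (pre-activation), one tensor per decoder."""
        if x_np.shape[0] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels")
        self._check_size(x_np.shape[1:])
        x = nn.Tensor(x_np)
        feat = nn.relu(self._apply("in_proj", x))
        skips = []
        for l in range(self.cfg.depth + 1):
            if l > 0:
                feat = nn.maxpool2(feat)
            feat = nn.relu(self._apply(f"enc{l}", feat))
            if l < self.cfg.depth:
                skips.append(feat)
        heads = []
        for d in range(self.cfg.n_decoders):
            h = feat
            for l in reversed(range(self.cfg.depth)):
                up = nn.upsample2(h)
                skip = skips[l]
                if self.cfg.attention:
                    gate = nn.relu(nn.add(self._apply(f"dec{d}_att{l}_g", up),
                                          self._apply(f"dec{d}_att{l}_x", skip)))
                    att = nn.sigmoid(self._apply(f"dec{d}_att{l}_psi", gate))
                    skip = nn.mul(att, skip)
                h = nn.relu(self._apply(f"dec{d}_conv{l}",
                                        nn.concat_channels([up, skip])))
            heads.append(self._apply(f"dec{d}_head", h))
        return heads

    def activations(self, x_np: np.ndarray) -> nn.Tensor:
        """Structure activations (7, Z, H, W) on the autodiff tape."""
        heads = self.forward(x_np)
        if self.cfg.stage == 1:
            raw = heads[0]
            soft = nn.softmax_channels(nn.slice_channels(raw, 0, 6))
            lobes = nn.slice_channels(soft, 1, 6)
            aux = nn.sigmoid(nn.slice_channels(raw, 6, 8))
            return nn.concat_channels([lobes, aux])
        return nn.concat_channels([nn.sigmoid(h) for h in heads])

    def predict(self, x_np: np.ndarray) -> np.ndarray:
        return self.activations(x_np).data

    def loss(self, x_np: np.ndarray, labels: np.ndarray) -> nn.Tensor:
        """Soft Dice loss against an integer 7-class label grid."""
        # mean soft Dice over the foreground structures present in the
        # sample; background is handled implicitly by the stage-1 softmax,
        # and structures absent from a training patch are skipped so they
        # exert no collapse pressure on their decoder
        target = structure_targets(labels)
        return nn.soft_dice_loss(self.activations(x_np), target,
                                 skip_empty=True)

    # -- checkpointing --
    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict):
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=np.float32)

    def save(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(json.dumps(asdict(self.cfg)))

    @classmethod
    def load(cls, path) -> "AttUNet":
        path = Path(path)
        cfg = NetConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        with np.load(path.with_suffix(".npz")) as z:
            model.load_state_dict({k: z[k] for k in z.files})
        return model


def build_attunet(cfg: NetConfig) -> AttUNet:
    return AttUNet(cfg)


def structure_targets(labels: np.ndarray) -> np.ndarray:
    """Integer 7-class label grid -> (7, ...) binary structure targets."""
    lung = (labels >= 1) & (labels <= 5)
    chans = [(labels == k) for k in range(1, 6)] + [lung, labels == 6]
    return np.stack(chans).astype(np.float32)


def _zoom_to(arr: np.ndarray, target_shape, order: int) -> np.ndarray:
    """Corner-aligned resize of a 3D grid (trilinear or nearest)."""
    if tuple(arr.shape) == tuple(target_shape):
        return arr.astype(np.float64) if order else arr
    factors = [t / s for t, s in zip(target_shape, arr.shape)]
    coords = np.meshgrid(
        *[np.arange(t) / f for t, f in zip(target_shape, factors)], indexing="ij")
    return ndimage.map_coordinates(arr.astype(np.float64), coords, order=order,
                                   mode="nearest")


def upsample_activations(act: np.ndarray, target_shape) -> np.ndarray:
    """Trilinear per-channel resize of an activation stack."""
    return np.stack([_zoom_to(c, target_shape, order=1) for c in act])


def stage1_predict(model: AttUNet, ct: CTVolume,
                   target_size=(128, 128, 128)) -> StagePrediction:
    """Coarse whole-volume prediction at ``target_size`` resolution."""
    x = _zoom_to(ct.intensities, target_size, order=1)[None].astype(np.float32)
    act = model.predict(x)
    if not np.all(np.isfinite(act)):
        raise FloatingPointError("non-finite stage-1 activations")
    return StagePrediction(act, stage=1,
                           grid_meta={"orig_shape": tuple(ct.shape)})


def _patch_starts(size: int, patch: int, stride: int) -> list:
    starts = list(range(0, max(size - patch, 0) + 1, stride))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return sorted(set(starts))


def stage2_refine(model: AttUNet, ct: CTVolume, prior_probs: np.ndarray,
                  coarse: StagePrediction, patch=(128, 128, 128),
                  overlap: float = 0.5) -> StagePrediction:
    """Patch-based refinement with mean stitching of overlapping windows.

    ``prior_probs`` is the (5, Z, H, W) warped atlas on the working grid;
    ``coarse`` activations are upsampled trilinearly to that grid and
    passed as channels 6..12 of the 13-channel input.
    """
    shape = tuple(ct.shape)
    patch = tuple(int(p) for p in patch)
    if any(p > s for p, s in zip(patch, shape)):
        f = 2**model.cfg.depth
        patch = tuple(min(p, s) // f * f for p, s in zip(patch, shape))
        log.warning("patch larger than volume; shrunk to %s", patch)
    if prior_probs.shape != (5,) + shape:
        raise ValueError("prior grid does not match the working grid")
    coarse_up = upsample_activations(coarse.activations, shape)
    x_full = np.concatenate([
        ct.intensities[None], prior_probs, coarse_up]).astype(np.float32)

    acc = np.zeros((N_STRUCTURES,) + shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.float64)
    strides = [max(1, int(round(p * (1.0 - overlap)))) for p in patch]
    for z0 in _patch_starts(shape[0], patch[0], strides[0]):
        for h0 in _patch_starts(shape[1], patch[1], strides[1]):
            for w0 in _patch_starts(shape[2], patch[2], strides[2]):
                sl = (slice(z0, z0 + patch[0]), slice(h0, h0 + patch[1]),
                      slice(w0, w0 + patch[2]))
                out = model.predict(x_full[(slice(None),) + sl])
                acc[(slice(None),) + sl] += out
                cnt[sl] += 1.0
    act = (acc / cnt).astype(np.float32)
    if not np.all(np.isfinite(act)):
        raise FloatingPointError("non-finite stage-2 activations")
    return StagePrediction(act, stage=2, grid_meta={"orig_shape": shape})


@dataclass
class Hyperparameters:
    """Training settings (full-scale defaults; desk runs shrink epochs/lr)."""

    lr: float = 1e-4
    weight_decay: float = 1e-5
    lr_decay: float = 0.985
    epochs: int = 50
    seed: int = 0


def train_stage(model: AttUNet, train_samples, val_samples,
                hp: Hyperparameters):
    """Optimize soft Dice loss; keep the lowest-validation-loss checkpoint.

    Samples are (input (C, Z, H, W) float array, labels (Z, H, W) int grid)
    pairs. Returns (model with best weights loaded, history dict with
    per-epoch train/val loss and lr).
    """
    train_samples = list(train_samples)
    val_samples = list(val_samples)
    if not train_samples or not val_samples:
        raise ValueError("need at least one training and one validation sample")
    rng = np.random.default_rng(hp.seed)
    opt = nn.AdamW(model.params, lr=hp.lr, weight_decay=hp.weight_decay,
                   lr_decay=hp.lr_decay)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best = (np.inf, model.state_dict())
    for epoch in range(hp.epochs):
        opt.set_epoch(epoch)
        order = rng.permutation(len(train_samples))
        losses = []
        for i in order:
            x, y = train_samples[i]
            opt.zero_grad()
            loss = model.loss(x, y)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}, sample {i}")
            loss.backward()
            opt.step()
            losses.append(lval)
        val = float(np.mean([float(model.loss(x, y).data)
                             for x, y in val_samples]))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val)
        history["lr"].append(opt.lr)
        log.info("epoch %d train %.4f val %.4f lr %.2e",
                 epoch, history["train_loss"][-1], val, opt.lr)
        if val < best[0]:
            best = (val, model.state_dict())
    model.load_state_dict(best[1])
    return model, history
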