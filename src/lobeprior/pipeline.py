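"""End-to-end orchestration: configuration, training workflow, and the
three-stage inference path (preprocess -> atlas selection -> coarse
segmentation -> patch refinement -> prior-guided post-processing -> native
space).

All randomness flows from one config seed through named substreams (model
init, patch sampling, augmentation), so identical inputs + config + seed
give byte-identical histories and segmentations.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import network as net
from . import postprocess as post
from . import prior_model as pm
from . import registration as reg
from .lesion_augment import AugmentConfig, LesionBank, augment
from .volume_io import (CTVolume, LabelMap, normalize_hu, read_labels,
                        read_volume, resample_isotropic, resample_labels_to,
                        write_labels)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; round-trips through YAML unchanged.

    Defaults are the full-scale settings (128^3 stages, [10000, 1000, 100]
    demons schedule, 50 epochs at lr 1e-4); ``desk_scale`` produces the
    reduced configuration used for phantom-sized experiments.
    """

    # paths
    atlas_dir: str = "atlases"
    checkpoint_dir: str = "checkpoints"
    cache_dir: str | None = ".lobeprior_cache"
    output_dir: str = "output"
    # preprocessing
    target_mm: float = 1.0
    hu_lo: float = -1024.0
    hu_hi: float = 600.0
    # stage sizes
    stage1_size: tuple = (128, 128, 128)
    patch: tuple = (128, 128, 128)
    overlap: float = 0.5
    # registration / atlas
    reg_levels: tuple = (10000, 1000, 100)
    dice_threshold: float = 0.80
    atlas_sigma: float = 1.0
    # network / training
    base_channels: int = 8
    stage2_base_channels: int | None = None  # None -> base_channels
    depth: int = 2
    attention: bool = True
    lr: float = 1e-4
    weight_decay: float = 1e-5
    lr_decay: float = 0.985
    epochs: int = 50
    stage2_epochs: int | None = None  # None -> epochs
    val_fraction: float = 0.2
    patches_per_volume: int = 2
    augment_enabled: bool = True
    # postprocess
    use_prior_fill: bool = True
    fusion_threshold: float = 0.5
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("stage1_size", "patch", "reg_levels"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for k in ("stage1_size", "patch", "reg_levels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "PipelineConfig":
        """Reduced configuration for phantom-sized (~48^3) experiments."""
        # stage 2 sees the prior and coarse masks as inputs, so it trains
        # well at lower capacity; patches cover the whole 48^3 phantom so
        # every structure is present in every training sample
        base = dict(stage1_size=(32, 32, 32), patch=(48, 48, 48),
                    reg_levels=(100, 50, 25), epochs=20, stage2_epochs=12,
                    lr=1e-2, base_channels=8, stage2_base_channels=4,
                    patches_per_volume=1, seed=seed)
        base.update(overrides)
        return cls(**base)

    def seeds(self) -> dict:
        """Named substream seeds derived from the config seed."""
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(3)
        names = ("init", "sampling", "augmentation")
        return {n: int(k.generate_state(1)[0] % 2**31)
                for n, k in zip(names, kids)}


def preprocess(ct: CTVolume, cfg: PipelineConfig) -> CTVolume:
    """Isotropic resampling + HU normalization (no-op if already done)."""
    if ct.normalized:
        return ct
    iso = resample_isotropic(ct, cfg.target_mm)
    return normalize_hu(iso, cfg.hu_lo, cfg.hu_hi)


def _split_ids(n: int, val_fraction: float, seed: int):
    """Deterministic patient-level train/validation split by ID."""
    rng = np.random.default_rng(seed)
    ids = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction)))
    return sorted(ids[n_val:].tolist()), sorted(ids[:n_val].tolist())


def _stage1_sample(ct: CTVolume, lab: LabelMap, size):
    x = net._zoom_to(ct.intensities, size, order=1)[None].astype(np.float32)
    y = net._zoom_to(lab.labels.astype(np.float64), size, order=0).astype(np.int16)
    return x, y


def _lung_patches(shape, labels, patch, count, rng):
    """Random patch origins biased to contain lung."""
    lung = (labels >= 1) & (labels <= 5)
    centers = np.argwhere(lung)
    starts = []
    for _ in range(count):
        c = centers[rng.integers(len(centers))]
        s = [int(np.clip(c[i] - patch[i] // 2, 0, shape[i] - patch[i]))
             for i in range(3)]
        starts.append(tuple(s))
    return starts


def _stage2_samples(warped, atlases, assignment, stage1, cfg, rng,
                    lesion_bank=None, aug_rng=None):
    """13-channel patch samples for stage-2 training.

    Each member's working-space image is paired with its group's prior and
    the frozen stage-1 activations; patches are sampled around the lung.
    """
    samples = []
    aug_cfg = AugmentConfig(crop=None)
    for mi, (ct, lab) in enumerate(warped):
        gi = assignment.group_of(mi)
        atlas = atlases[gi]
        img, labels = ct, lab
        if cfg.augment_enabled and lesion_bank is not None and aug_rng is not None:
            lung = (lab.labels >= 1) & (lab.labels <= 5)
            img, labels = augment(ct, lab, aug_cfg, aug_rng,
                                  lesion_bank=lesion_bank, lung_mask=lung,
                                  atlas_space_id=atlas.group_id)
        pred1 = net.stage1_predict(stage1, img, cfg.stage1_size)
        coarse_up = net.upsample_activations(pred1.activations, img.shape)
        x_full = np.concatenate(
            [img.intensities[None], atlases[gi].probs, coarse_up]
        ).astype(np.float32)
        for s in _lung_patches(img.shape, labels.labels, cfg.patch,
                               cfg.patches_per_volume, rng):
            sl = tuple(slice(s[i], s[i] + cfg.patch[i]) for i in range(3))
            samples.append((x_full[(slice(None),) + sl], labels.labels[sl]))
    return samples


def run_training(manifest, cfg: PipelineConfig, atlases=None, assignment=None,
                 warped=None, lesion_bank: LesionBank | None = None):
    """Train stage 1 then stage 2 (sequentially; stage 1 frozen for stage 2).

    ``manifest`` is a list of (CTVolume, LabelMap) pairs (or (ct_path,
    labels_path) tuples), already preprocessed or raw. If atlases are not
    supplied they are built from the manifest (registration to a common
    reference, Dice grouping, label fusion).

    Returns (stage1 model, stage2 model, history dict). Checkpoints and the
    history are written under ``cfg.checkpoint_dir``.
    """
    t_start = time.time()
    cohort = []
    for item in manifest:
        ct, lab = item[0], item[1]
        if not isinstance(ct, CTVolume):
            ct, lab = read_volume(ct), read_labels(lab)
        ct = preprocess(ct, cfg)
        lab = resample_labels_to(ct, lab)
        cohort.append((ct, lab))
    if len(cohort) < 2:
        raise ValueError("training needs at least two volumes")

    if atlases is None:
        atlases, assignment, warped = pm.build_group_atlases(
            cohort, threshold=cfg.dice_threshold, sigma=cfg.atlas_sigma,
            levels=cfg.reg_levels, cache_dir=cfg.cache_dir)
    log.info("atlas groups: %s", [len(g) for g in assignment.groups])

    seeds = cfg.seeds()
    train_ids, val_ids = _split_ids(len(warped), cfg.val_fraction,
                                    seeds["sampling"])
    if set(train_ids) & set(val_ids):
        raise ValueError("train/validation IDs overlap")
    log.info("train ids %s / val ids %s", train_ids, val_ids)

    hp = net.Hyperparameters(lr=cfg.lr, weight_decay=cfg.weight_decay,
                             lr_decay=cfg.lr_decay, epochs=cfg.epochs,
                             seed=seeds["sampling"])

    aug_rng = np.random.default_rng(seeds["augmentation"])
    s1_pool = []
    for mi, (ct, lab) in enumerate(warped):
        img, labels = ct, lab
        if cfg.augment_enabled and lesion_bank is not None:
            lung = (lab.labels >= 1) & (lab.labels <= 5)
            img, labels = augment(ct, lab, AugmentConfig(crop=None), aug_rng,
                                  lesion_bank=lesion_bank, lung_mask=lung,
                                  atlas_space_id=assignment.group_of(mi))
        s1_pool.append(_stage1_sample(img, labels, cfg.stage1_size))

    stage1 = net.AttUNet(net.NetConfig(
        in_channels=1, base_channels=cfg.base_channels, depth=cfg.depth,
        stage=1, attention=cfg.attention, seed=seeds["init"]))
    t0 = time.time()
    stage1, hist1 = net.train_stage(
        stage1, [s1_pool[i] for i in train_ids], [s1_pool[i] for i in val_ids], hp)
    log.info("stage-1 training: %.1f s", time.time() - t0)

    patch_rng = np.random.default_rng(seeds["sampling"])
    s2_pool = _stage2_samples(warped, atlases, assignment, stage1, cfg,
                              patch_rng, lesion_bank=lesion_bank,
                              aug_rng=np.random.default_rng(seeds["augmentation"]))
    ppv = cfg.patches_per_volume
    s2_train = [s for i in train_ids for s in s2_pool[i * ppv:(i + 1) * ppv]]
    s2_val = [s for i in val_ids for s in s2_pool[i * ppv:(i + 1) * ppv]]
    stage2 = net.AttUNet(net.NetConfig(
        in_channels=net.STAGE2_IN_CHANNELS,
        base_channels=cfg.stage2_base_channels or cfg.base_channels,
        depth=cfg.depth, stage=2, attention=cfg.attention,
        seed=seeds["init"] + 1))
    hp2 = net.Hyperparameters(lr=cfg.lr, weight_decay=cfg.weight_decay,
                              lr_decay=cfg.lr_decay,
                              epochs=cfg.stage2_epochs or cfg.epochs,
                              seed=seeds["sampling"])
    t0 = time.time()
    stage2, hist2 = net.train_stage(stage2, s2_train, s2_val, hp2)
    log.info("stage-2 training: %.1f s", time.time() - t0)

    ckpt = Path(cfg.checkpoint_dir)
    ckpt.mkdir(parents=True, exist_ok=True)
    stage1.save(ckpt / "stage1")
    stage2.save(ckpt / "stage2")
    for gi, a in enumerate(atlases):
        pm.save_atlas(a, Path(cfg.atlas_dir) / f"group{gi}")
    history = {"stage1": hist1, "stage2": hist2,
               "train_ids": train_ids, "val_ids": val_ids,
               "groups": assignment.groups,
               "total_seconds": time.time() - t_start}
    (ckpt / "history.json").write_text(json.dumps(history))
    return stage1, stage2, history


def load_models(cfg: PipelineConfig):
    ckpt = Path(cfg.checkpoint_dir)
    if not (ckpt / "stage1.npz").exists() or not (ckpt / "stage2.npz").exists():
        raise FileNotFoundError(f"missing checkpoints under {ckpt}")
    return net.AttUNet.load(ckpt / "stage1"), net.AttUNet.load(ckpt / "stage2")


def run_inference(ct, cfg: PipelineConfig, stage1=None, stage2=None,
                  atlases=None, out_path=None,
                  use_prior_fill: bool | None = None) -> LabelMap:
    """Full three-stage inference for one CT (path or CTVolume).

    Returns the native-space LabelMap; also writes it (plus a JSON sidecar
    describing the label codes) when ``out_path`` is given.
    """
    timings = {}
    native = read_volume(ct) if not isinstance(ct, CTVolume) else ct
    if use_prior_fill is None:
        use_prior_fill = cfg.use_prior_fill
    t0 = time.time()
    pre = preprocess(native, cfg)
    timings["preprocess"] = time.time() - t0

    if stage1 is None or stage2 is None:
        stage1, stage2 = load_models(cfg)
    if atlases is None:
        atlas_root = Path(cfg.atlas_dir)
        atlases = [pm.load_atlas(d) for d in sorted(atlas_root.iterdir())
                   if (d / "atlas.json").exists()]
        if not atlases:
            raise FileNotFoundError(f"no atlases under {atlas_root}")

    t0 = time.time()
    atlas, t = pm.select_atlas(pre, atlases, levels=cfg.reg_levels,
                               cache_dir=cfg.cache_dir)
    working = reg.apply_transform(t, pre, "forward")
    timings["atlas_selection"] = time.time() - t0
    log.info("selected atlas group %d", atlas.group_id)

    t0 = time.time()
    pred1 = net.stage1_predict(stage1, working, cfg.stage1_size)
    timings["stage1"] = time.time() - t0
    if pred1.activations[net.LUNG_CH].max() <= cfg.fusion_threshold:
        log.warning("no lung-like content detected; emitting all-background map")
        out = LabelMap(np.zeros(native.shape, dtype=np.int16),
                       native.spacing.copy(), native.affine.copy())
        if out_path is not None:
            _write_result(out, out_path)
        return out

    t0 = time.time()
    pred2 = net.stage2_refine(stage2, working, atlas.probs, pred1,
                              patch=cfg.patch, overlap=cfg.overlap)
    timings["stage2"] = time.time() - t0

    t0 = time.time()
    fr = post.fuse_decoders(pred2, threshold=cfg.fusion_threshold,
                            spacing=working.spacing, affine=working.affine)
    out = post.finalize(fr, atlas if use_prior_fill else None, t, native)
    timings["postprocess"] = time.time() - t0
    log.info("stage timings (s): %s",
             {k: round(v, 2) for k, v in timings.items()})
    if out_path is not None:
        _write_result(out, out_path)
    return out


def _write_result(labels: LabelMap, out_path) -> None:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    write_labels(labels, out_path)
    codes = {str(i): n for i, n in enumerate(labels.class_names)}
    sidecar = out_path.with_name(out_path.name.split(".")[0] + "_labels.json")
    sidecar.write_text(json.dumps(codes))
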