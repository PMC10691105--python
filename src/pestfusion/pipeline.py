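"""Group-batch sampling, the two-branch model, training and evaluation.

Training processes *groups*: an anchor image plus N_t - 1 more images
drawn from the anchor's class.  Every group passes through a shared CNN
trunk; the **general branch** classifies each pooled embedding directly
(after dropout), while the **improving branch** localizes the target in
feature space (epoch-scheduled lambda), pools the localized features,
fuses the group with gated attention, and classifies through the same FC
layer.  The two cross-entropy losses are summed and optimized jointly
with SGD, so both branches shape the shared trunk and classifier.

At test time the general branch scores single images; the improving
branch fuses n_test same-class images and soft-votes one decision per
group (grouping by true label mirrors the evaluation protocol; the
`predict` path instead accepts caller-defined groups).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import eflm as _eflm
from .affm import AFFM
from .autodiff import Tensor, concat, interp2d, no_grad
from .backbone import FeatureBlock, TinyBackbone, build_backbone
from .config import config_hash, default_config
from .eflm import BoundingBox, LambdaSchedule, lambda_at
from .fusion_head import (MetricsReport, ProbabilityMatrix, classify,
                          compute_metrics, group_nll, hard_vote, soft_vote)
from .nn import SGD, Dropout, Linear

logger = logging.getLogger(__name__)

__all__ = ["GroupBatchSpec", "OptimConfig", "PestFusionModel",
           "build_group_batches", "forward_group", "fit", "evaluate",
           "load_checkpoint", "save_checkpoint", "load_manifest",
           "load_images"]


@dataclass
class GroupBatchSpec:
    batch_anchors: int = 16
    n_t: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_t < 1:
            raise ValueError("N_t must be >= 1")


@dataclass
class OptimConfig:
    lr: float = 1.0e-3
    momentum: float = 0.9
    weight_decay: float = 1.0e-4
    epochs: int = 20
    lr_decay_factor: float = 0.1
    lr_decay_at_epoch: int = 10

    def __post_init__(self):
        if min(self.lr, self.momentum, self.weight_decay, self.epochs,
               self.lr_decay_factor, self.lr_decay_at_epoch) < 0:
            raise ValueError("optimizer settings must be positive")

    def lr_at(self, epoch: int) -> float:
        """0-based epoch; the rate drops once after `lr_decay_at_epoch` epochs."""
        if epoch >= self.lr_decay_at_epoch:
            return self.lr * self.lr_decay_factor
        return self.lr


class PestFusionModel:
    """The full two-branch model built from a config dict."""

    def __init__(self, config: dict | None = None, n_classes: int = 5,
                 seed: int = 0):
        cfg = default_config()
        if config:
            for sec, vals in config.items():
                cfg[sec].update(vals)
        self.config = cfg
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        if cfg["backbone"]["name"] == "tiny":
            self.backbone = TinyBackbone(cfg["backbone"]["channels"], rng=rng)
        else:
            self.backbone = build_backbone(cfg["backbone"]["name"], rng=rng)
        d = self.backbone.embed_dim
        self.embed_dim = d
        p = cfg["affm"]["p"]
        if p is None:
            p = 1.0 / (2.0 * cfg["data"]["n_t"])
        self.affm = AFFM(d, heads=cfg["affm"]["heads"], p=p,
                         qk_mask=cfg["affm"]["qk_mask"],
                         v_mask=cfg["affm"]["v_mask"], rng=rng)
        self.fc = Linear(d, n_classes, rng=rng)
        self.dropout = Dropout(cfg["backbone"]["dropout_rate"])
        self.schedule = LambdaSchedule(cfg["optim"]["epochs"],
                                       cfg["eflm"]["test_lambda"])

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self):
        for name, p in self.backbone.parameters():
            yield f"backbone.{name}", p
        for name, p in self.affm.parameters():
            yield f"affm.{name}", p
        for name, p in self.fc.parameters():
            yield f"fc.{name}", p

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {name: p.data for name, p in self.parameters()}
        for name, b in self.affm.buffers():
            out[f"affm.{name}"] = b
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        own = dict(self.parameters())
        bufs = {f"affm.{n}": b for n, b in self.affm.buffers()}
        for name, arr in arrays.items():
            if name in own:
                own[name].data[...] = arr
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unknown checkpoint key {name}")

    # -- lambda ---------------------------------------------------------------
    def lambda_for(self, epoch: int, phase: str) -> float:
        if phase == "test":
            return lambda_at(self.schedule, 0, "test")
        if not self.config["eflm"]["gradual"]:
            return 1.0
        return lambda_at(self.schedule, epoch, phase)


def load_manifest(manifest) -> pd.DataFrame:
    if isinstance(manifest, pd.DataFrame):
        df = manifest.copy()
    else:
        path = Path(manifest)
        if not path.exists():
            raise FileNotFoundError(f"manifest not found: {path}")
        df = pd.read_csv(path)
        root = path.parent
        df["path"] = [str(root / p) for p in df["path"]]
    missing = {"path", "label", "split"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("manifest is empty")
    return df


def load_images(paths, image_size: int) -> np.ndarray:
    """Decode, bilinear-resize to square, scale to [-1, 1], NCHW."""
    out = np.empty((len(paths), 3, image_size, image_size))
    for i, p in enumerate(paths):
        try:
            with Image.open(p) as im:
                im = im.convert("RGB").resize((image_size, image_size),
                                              Image.BILINEAR)
        except OSError as exc:
            raise OSError(f"cannot read image {p}: {exc}") from exc
        arr = np.asarray(im, dtype=np.float64) / 255.0
        out[i] = ((arr - 0.5) / 0.5).transpose(2, 0, 1)
    return out


def build_group_batches(manifest: pd.DataFrame, spec: GroupBatchSpec,
                        epoch: int):
    """Yield index groups: each anchor plus N_t - 1 same-class images.

    Sampling is uniform without replacement when the class is large
    enough, with replacement otherwise; deterministic in (seed, epoch).
    """
    df = manifest
    if len(df) == 0:
        raise ValueError("empty manifest")
    rng = np.random.default_rng([spec.seed, epoch])
    train = df.index[df["split"] == "train"].to_numpy()
    if train.size == 0:
        raise ValueError("manifest has no training rows")
    by_label: dict[int, np.ndarray] = {
        lbl: df.index[(df["split"] == "train") & (df["label"] == lbl)].to_numpy()
        for lbl in df.loc[train, "label"].unique()}
    for anchor in rng.permutation(train):
        label = df.at[anchor, "label"]
        pool = by_label[label]
        others = pool[pool != anchor]
        k = spec.n_t - 1
        if k == 0:
            yield [int(anchor)]
            continue
        if others.size >= k:
            chosen = rng.choice(others, size=k, replace=False)
        else:
            source = others if others.size else pool
            chosen = rng.choice(source, size=k, replace=True)
        yield [int(anchor)] + [int(c) for c in chosen]


def _per_image_boxes(block_outs: list[Tensor], lam: float,
                     num_blocks: int) -> list[BoundingBox]:
    """Localization decisions (mask -> box) per image, on detached values."""
    n = block_outs[0].shape[0]
    chosen = block_outs[-num_blocks:]
    boxes = []
    for i in range(n):
        masks = [_eflm.threshold_mask(
            _eflm.aggregate_channels(FeatureBlock(t.data[i])), lam)
            for t in chosen]
        boxes.append(_eflm.mask_to_bbox(_eflm.intersect_masks(masks)))
    return boxes


def _pool_spatial(t: Tensor) -> Tensor:
    return t.mean(axis=(2, 3)) if t.ndim == 4 else t.mean(axis=(1, 2))


def forward_group(images: np.ndarray, model: PestFusionModel, phase: str,
                  epoch: int = 0, rng: np.random.Generator | None = None,
                  return_tensors: bool = False):
    """Run one group through both branches.

    Returns (general ProbabilityMatrix, improving ProbabilityMatrix,
    boxes); with `return_tensors` also the two logits Tensors for loss
    computation.  In eval phases everything is deterministic.
    """
    cfg = model.config
    training = phase == "train"
    rng = rng or np.random.default_rng()
    x = Tensor(images)
    outs = model.backbone.forward_with_hooks(x)
    h, w = outs[-1].shape[2], outs[-1].shape[3]
    n = images.shape[0]

    general_emb = _pool_spatial(outs[-1])
    general_emb = model.dropout.forward(general_emb, training=training, rng=rng)
    general_logits = model.fc.forward(general_emb)

    boxes: list[BoundingBox] = []
    if cfg["eflm"]["enabled"]:
        lam = model.lambda_for(epoch, phase)
        boxes = _per_image_boxes(outs, lam, cfg["eflm"]["num_blocks"])
        rows = []
        for i, box in enumerate(boxes):
            crop = outs[-1][i][:, box.row_start:box.row_stop,
                               box.col_start:box.col_stop]
            rows.append(_pool_spatial(interp2d(crop, h, w)).reshape(1, -1))
        improving_emb = rows[0] if n == 1 else concat(rows, axis=0)
    else:
        boxes = [BoundingBox(0, h, 0, w)] * n
        improving_emb = _pool_spatial(outs[-1])
    if cfg["affm"]["enabled"]:
        improving_emb = model.affm.forward(improving_emb, training=training)
    improving_logits = model.fc.forward(improving_emb)

    def probs(logits: Tensor) -> ProbabilityMatrix:
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        return ProbabilityMatrix(e / e.sum(axis=1, keepdims=True))

    gp, ip = probs(general_logits), probs(improving_logits)
    if return_tensors:
        return gp, ip, boxes, general_logits, improving_logits
    return gp, ip, boxes


def _train_step(model: PestFusionModel, cache: np.ndarray,
                batch_groups: list[list[int]], labels: np.ndarray,
                epoch: int, rng: np.random.Generator):
    """One optimizer step over a batch of groups.

    The backbone, pooling, dropout and the shared FC see all images of
    the batch at once; attention fusion stays within each group, but the
    fusion BN normalizes over every row of the batch, mixing classes the
    way a standard training batch does.
    """
    cfg = model.config
    flat = [i for g in batch_groups for i in g]
    truth = labels[flat]
    x = Tensor(cache[flat])
    outs = model.backbone.forward_with_hooks(x)
    h, w = outs[-1].shape[2], outs[-1].shape[3]

    general_emb = _pool_spatial(outs[-1])
    general_emb = model.dropout.forward(general_emb, training=True, rng=rng)
    general_logits = model.fc.forward(general_emb)

    if cfg["eflm"]["enabled"]:
        lam = model.lambda_for(epoch, "train")
        boxes = _per_image_boxes(outs, lam, cfg["eflm"]["num_blocks"])
        rows = []
        for i, box in enumerate(boxes):
            crop = outs[-1][i][:, box.row_start:box.row_stop,
                               box.col_start:box.col_stop]
            rows.append(_pool_spatial(interp2d(crop, h, w)).reshape(1, -1))
    else:
        pooled = _pool_spatial(outs[-1])
        rows = [pooled[i].reshape(1, -1) for i in range(len(flat))]
    group_embs = []
    offset = 0
    for g in batch_groups:
        members = rows[offset:offset + len(g)]
        group_embs.append(members[0] if len(g) == 1
                          else concat(members, axis=0))
        offset += len(g)
    if cfg["affm"]["enabled"]:
        group_embs = model.affm.forward_groups(group_embs, training=True)
    improving_emb = (group_embs[0] if len(group_embs) == 1
                     else concat(group_embs, axis=0))
    improving_logits = model.fc.forward(improving_emb)
    return group_nll(general_logits, truth), group_nll(improving_logits, truth)


def save_checkpoint(model: PestFusionModel, path, epoch: int,
                    metrics: dict | None = None) -> None:
    meta = {"config": model.config, "config_hash": config_hash(model.config),
            "n_classes": model.n_classes, "epoch": epoch,
            "metrics": metrics or {}}
    arrays = model.state_arrays()
    np.savez(path, _meta=np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> PestFusionModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        arrays = {k: data[k] for k in data.files if k != "_meta"}
    model = PestFusionModel(meta["config"], n_classes=meta["n_classes"])
    model.load_state(arrays)
    model._meta = meta
    return model


def fit(manifest, config: dict | None = None, seed: int = 0,
        checkpoint_path=None, log_path=None,
        progress: bool = False) -> tuple[PestFusionModel, list[dict]]:
    """Train the two-branch model; returns the model and per-epoch log rows."""
    cfg = default_config()
    if config:
        for sec, vals in config.items():
            cfg[sec].update(vals)
    df = load_manifest(manifest)
    labels = sorted(df["label"].unique())
    if labels != list(range(len(labels))):
        raise ValueError("labels must be 0..m-1")
    model = PestFusionModel(cfg, n_classes=len(labels), seed=seed)
    opt_cfg = OptimConfig(**cfg["optim"])
    spec = GroupBatchSpec(cfg["data"]["batch_anchors"], cfg["data"]["n_t"],
                          seed=seed)
    optimizer = SGD(list(model.parameters()), lr=opt_cfg.lr,
                    momentum=opt_cfg.momentum,
                    weight_decay=opt_cfg.weight_decay)
    image_size = cfg["backbone"]["image_size"]
    cache = load_images(df["path"].tolist(), image_size)
    drop_rng = np.random.default_rng([seed, 7919])
    log_rows: list[dict] = []
    header = {"event": "start", "config_hash": config_hash(cfg), "seed": seed,
              "ablation": {"eflm": cfg["eflm"]["enabled"],
                           "affm": cfg["affm"]["enabled"],
                           "qk_mask": cfg["affm"]["qk_mask"],
                           "v_mask": cfg["affm"]["v_mask"],
                           "voting": cfg["head"]["voting"],
                           "gradual_lambda": cfg["eflm"]["gradual"],
                           "num_blocks": cfg["eflm"]["num_blocks"]}}
    log_rows.append(header)
    for epoch in range(opt_cfg.epochs):
        optimizer.lr = opt_cfg.lr_at(epoch)
        lam = model.lambda_for(epoch, "train")
        sums = np.zeros(2)
        n_steps = 0
        batch: list[list[int]] = []
        all_labels = df["label"].to_numpy()

        def step(batch_groups):
            optimizer.zero_grad()
            lg, li = _train_step(model, cache, batch_groups, all_labels,
                                 epoch, drop_rng)
            loss = lg + li
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"L_general={lg.data}, L_improving={li.data}")
            loss.backward()
            optimizer.step()
            return float(lg.data), float(li.data)

        for group in build_group_batches(df, spec, epoch):
            batch.append(group)
            if len(batch) == spec.batch_anchors:
                sums += step(batch)
                n_steps += 1
                batch = []
        if batch:
            sums += step(batch)
            n_steps += 1
        row = {"event": "epoch", "epoch": epoch, "lambda": lam,
               "lr": optimizer.lr,
               "L_general": sums[0] / n_steps,
               "L_improving": sums[1] / n_steps,
               "L_total": sums.sum() / n_steps}
        if (df["split"] == "test").any():
            for mode in ("general", "improving"):
                rep = evaluate(df, model, mode=mode,
                               n_test=cfg["data"]["n_t"], seed=seed,
                               image_cache=cache)
                row[f"val_acc_{mode}"] = rep.accuracy
        log_rows.append(row)
        if progress:
            logger.info("epoch %d: %s", epoch, row)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, opt_cfg.epochs - 1,
                        metrics={k: v for k, v in log_rows[-1].items()
                                 if isinstance(v, float)})
    if log_path is not None:
        with open(log_path, "w") as fh:
            for row in log_rows:
                fh.write(json.dumps(row) + "\n")
    return model, log_rows


def evaluate(manifest, model_or_checkpoint, mode: str = "improving",
             n_test: int = 5, seed: int = 0, group_ids=None,
             image_cache: np.ndarray | None = None) -> MetricsReport:
    """Score the test split.

    general: one prediction per image.  improving: images grouped by true
    label (or by `group_ids`), fused, one soft-vote decision per group.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    if mode not in ("general", "improving"):
        raise ValueError(f"unknown mode {mode!r}")
    model = (model_or_checkpoint if isinstance(model_or_checkpoint,
                                               PestFusionModel)
             else load_checkpoint(model_or_checkpoint))
    df = load_manifest(manifest)
    test = df[df["split"] == "test"]
    if len(test) == 0:
        raise ValueError("manifest has no test rows")
    image_size = model.config["backbone"]["image_size"]
    if image_cache is None:
        cache = load_images(test["path"].tolist(), image_size)
        pos = {idx: i for i, idx in enumerate(test.index)}
    else:
        cache = image_cache
        pos = {idx: i for i, idx in enumerate(df.index)}
    m = model.n_classes
    preds: list[int] = []
    truths: list[int] = []
    rng = np.random.default_rng([seed, 104729])
    with no_grad():
        if mode == "general":
            for start in range(0, len(test), 16):
                rows = test.index[start:start + 16]
                images = cache[[pos[r] for r in rows]]
                gp, _, _ = forward_group(images, model, "test")
                preds.extend(np.argmax(gp.values, axis=1).tolist())
                truths.extend(test.loc[rows, "label"].tolist())
        else:
            groups = _test_groups(test, n_test, rng, group_ids)
            voting = model.config["head"]["voting"]
            for rows, label in groups:
                images = cache[[pos[r] for r in rows]]
                _, ip, _ = forward_group(images, model, "test")
                if voting == "soft":
                    cls, _ = soft_vote(ip)
                    preds.append(cls)
                    truths.append(label)
                elif voting == "hard":
                    per_img = np.argmax(ip.values, axis=1).tolist()
                    preds.append(hard_vote(per_img, ip))
                    truths.append(label)
                else:   # no voting: per-image decisions
                    preds.extend(np.argmax(ip.values, axis=1).tolist())
                    truths.extend([label] * len(rows))
    return compute_metrics(preds, truths, m)


def _test_groups(test: pd.DataFrame, n_test: int, rng: np.random.Generator,
                 group_ids=None):
    """Partition test rows into same-label groups of size n_test."""
    groups = []
    if group_ids is not None:
        gids = np.asarray(group_ids)
        for gid in np.unique(gids):
            rows = test.index[gids == gid]
            label = int(test.loc[rows, "label"].mode().iat[0])
            groups.append((list(rows), label))
        return groups
    for label in sorted(test["label"].unique()):
        rows = test.index[test["label"] == label].to_numpy()
        if rows.size < n_test:
            warnings.warn(f"class {label} has {rows.size} < n_test={n_test} "
                          "test images; sampling with replacement")
        order = rng.permutation(rows)
        for start in range(0, order.size, n_test):
            chunk = list(order[start:start + n_test])
            if len(chunk) < n_test:
                extra = rng.choice(rows, size=n_test - len(chunk),
                                   replace=True)
                chunk += [int(e) for e in extra]
            groups.append((chunk, int(label)))
    return groups
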