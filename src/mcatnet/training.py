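"""Small-sample training: augmentation, triplet pretraining, fine-tuning.

The two-stage schedule first pretrains the feature-embedding module with a
triplet metric objective on an augmented pool (pulling same-class lesions
together on the unit sphere, pushing opposite classes apart by a margin),
then fine-tunes the evaluation head with binary cross-entropy while the
embedding trains at a reduced learning rate (factor 0.1 by default, or
frozen). The end-to-end comparator trains embedding and head jointly with
cross-entropy under *budget parity*: the same augmented pool and the same
total number of gradient steps as pretraining + fine-tuning combined.

Augmentation applies one shared geometric transform (flips, rotation, scale
jitter) to every channel of a stack so channels stay registered, plus a
global intensity offset; outputs are re-clipped to [0, 1]. Validation data is
never augmented: augmented records carry ``provenance['origin'] ==
'augmented'`` and the evaluation harness asserts on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import SimilarityTransform, warp

from . import nn
from .cohort import LesionRecord
from .preprocessing import ModalityStack, RoiPatch

STAGES = ("pretrain", "finetune", "end_to_end")


@dataclass(frozen=True)
class AugmentationPolicy:
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_deg: float = 15.0
    scale_jitter: float = 0.10
    translate_frac: float = 0.0  # shift range as a fraction of patch side
    intensity_sd: float = 0.02
    multiplicity: int = 8  # augmented copies per original in the pool

    def __post_init__(self):
        if min(self.rotation_deg, self.scale_jitter, self.translate_frac, self.intensity_sd) < 0:
            raise ValueError("augmentation ranges must be nonnegative")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    @property
    def is_identity(self) -> bool:
        return not (
            self.horizontal_flip
            or self.vertical_flip
            or self.rotation_deg
            or self.scale_jitter
            or self.translate_frac
            or self.intensity_sd
        )


@dataclass(frozen=True)
class TrainingConfig:
    stage: str = "pretrain"
    epochs: int = 30
    batch_size: int = 32
    lr: float | None = None  # default per stage
    momentum: float = 0.9
    weight_decay: float | None = None  # default per stage
    margin: float = 0.3
    mining: str = "batch_all"
    embedding_lr_factor: float = 0.1
    freeze_embedding: bool = False
    # the modality gate has ~10 parameters whose gradients are averaged over
    # the full spatial extent; it trains at a higher rate, and only after a
    # warmup that lets the backbone commit to the informative channels
    gate_lr_factor: float = 20.0
    gate_warmup_epochs: int | None = None  # None -> epochs // 3
    seed: int = 0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.margin <= 0:
            raise ValueError("margin must be positive")

    @property
    def effective_lr(self) -> float:
        if self.lr is not None:
            return self.lr
        return {"pretrain": 0.1, "finetune": 0.01, "end_to_end": 0.02}[self.stage]

    @property
    def effective_weight_decay(self) -> float:
        if self.weight_decay is not None:
            return self.weight_decay
        return {"pretrain": 1e-4, "finetune": 1e-4, "end_to_end": 1e-3}[self.stage]

    @property
    def warmup_epochs(self) -> int:
        if self.gate_warmup_epochs is not None:
            return self.gate_warmup_epochs
        return self.epochs // 3


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(stack: ModalityStack, policy: AugmentationPolicy, rng) -> ModalityStack:
    """One random augmentation; the same transform hits every channel."""
    side = stack.side
    flip_h = policy.horizontal_flip and bool(rng.integers(2))
    flip_v = policy.vertical_flip and bool(rng.integers(2))
    angle = float(rng.uniform(-policy.rotation_deg, policy.rotation_deg)) if policy.rotation_deg else 0.0
    scale = float(rng.uniform(1 - policy.scale_jitter, 1 + policy.scale_jitter)) if policy.scale_jitter else 1.0
    if policy.translate_frac:
        t_max = policy.translate_frac * side
        shift_rc = rng.uniform(-t_max, t_max, size=2)
    else:
        shift_rc = np.zeros(2)
    offset = float(rng.normal(0.0, policy.intensity_sd)) if policy.intensity_sd else 0.0

    tform = None
    if angle != 0.0 or scale != 1.0 or shift_rc.any():
        center = (side - 1) / 2.0
        shift = SimilarityTransform(translation=(-center, -center))
        rot = SimilarityTransform(rotation=np.deg2rad(angle), scale=scale)
        unshift = SimilarityTransform(translation=(center + shift_rc[1], center + shift_rc[0]))
        tform = shift + rot + unshift

    out = []
    for patch in stack.channels:
        img = patch.pixels.astype(np.float64)
        if flip_h:
            img = img[:, ::-1]
        if flip_v:
            img = img[::-1, :]
        if tform is not None:
            img = warp(img, tform.inverse, order=1, mode="edge", preserve_range=True)
        if offset:
            img = img + offset
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        out.append(RoiPatch(pixels=img, channel_name=patch.channel_name))
    return ModalityStack(channels=out, modality=stack.modality)


def augment_record(record: LesionRecord, policy: AugmentationPolicy, rng, copy_idx: int) -> LesionRecord:
    ct = augment(record.ct_stack, policy, rng) if record.ct_stack is not None else None
    mr = augment(record.mri_stack, policy, rng) if record.mri_stack is not None else None
    prov = dict(record.provenance)
    prov["origin"] = "augmented"
    prov["source"] = record.lesion_id
    return LesionRecord(
        lesion_id=f"{record.lesion_id}+aug{copy_idx}",
        label=record.label,
        availability=record.availability,
        ct_stack=ct,
        mri_stack=mr,
        provenance=prov,
    )


def build_augmented_pool(records, policy: AugmentationPolicy, rng) -> list[LesionRecord]:
    """Originals plus ``multiplicity`` augmented copies of each."""
    pool = list(records)
    for rec in records:
        for j in range(policy.multiplicity):
            pool.append(augment_record(rec, policy, rng, j))
    return pool


def records_to_arrays(records, modality: str):
    """(N, C, S, S) float32 inputs and int label vector for one modality."""
    xs = [rec.stack(modality).to_array() for rec in records]
    y = np.array([rec.label for rec in records], dtype=np.int64)
    return np.stack(xs), y


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _steps_per_epoch(n: int, batch_size: int) -> int:
    return max(1, math.ceil(n / batch_size))


def _iterate_batches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def pretrain_embedding(branch, records, policy: AugmentationPolicy, cfg: TrainingConfig):
    """Triplet-metric pretraining of the embedding module. Returns loss history."""
    if cfg.stage != "pretrain":
        raise ValueError("cfg.stage must be 'pretrain'")
    labels = {rec.label for rec in records}
    if len(labels) < 2:
        raise nn.NoValidTripletsError("pretraining needs both classes present")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    pool = build_augmented_pool(records, policy, rng)
    x, y = records_to_arrays(pool, branch.cfg.modality)
    gate = getattr(branch, "gate", None)
    if gate is not None:
        gate_refs = list(gate.named_parameters())
        body_refs = [r for r in branch.embedding_param_refs() if r[0] is not gate]
        groups_warm = [(body_refs, 1.0)]
        groups_full = [(body_refs, 1.0), (gate_refs, cfg.gate_lr_factor)]
    else:
        groups_warm = groups_full = [(branch.embedding_param_refs(), 1.0)]
    kw = dict(lr=cfg.effective_lr, momentum=cfg.momentum, weight_decay=cfg.effective_weight_decay)
    opt_warm = nn.SGD(groups_warm, **kw)
    opt_full = nn.SGD(groups_full, **kw)
    history = []
    branch.train(True)
    for epoch in range(cfg.epochs):
        opt = opt_warm if epoch < cfg.warmup_epochs else opt_full
        losses = []
        for idx in _iterate_batches(len(y), cfg.batch_size, rng):
            counts = np.bincount(y[idx], minlength=2)
            if counts.min() == 0 or counts.max() < 2:
                continue  # batch cannot form a triplet
            emb = branch.forward_embedding(x[idx])
            loss, demb, _ = nn.triplet_loss_batch(emb, y[idx], cfg.margin, cfg.mining)
            opt.zero_grad()
            branch.backward_from_embedding(demb)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)) if losses else float("nan"))
    branch.eval()
    return history


def finetune_classifier(branch, records, cfg: TrainingConfig, policy: AugmentationPolicy | None = None):
    """Cross-entropy fine-tuning of the head; embedding at reduced rate."""
    if cfg.stage != "finetune":
        raise ValueError("cfg.stage must be 'finetune'")
    if not records:
        raise ValueError("empty training set")
    if len({rec.label for rec in records}) < 2:
        raise ValueError("fine-tuning needs both classes present")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 211]))
    train_records = (
        build_augmented_pool(records, policy, rng) if policy is not None else list(records)
    )
    x, y = records_to_arrays(train_records, branch.cfg.modality)
    groups = [(branch.head_param_refs(), 1.0)]
    if not cfg.freeze_embedding:
        groups.append((branch.embedding_param_refs(), cfg.embedding_lr_factor))
    opt = nn.SGD(groups, lr=cfg.effective_lr, momentum=cfg.momentum,
                 weight_decay=cfg.effective_weight_decay)
    history = []
    branch.train(True)
    for _ in range(cfg.epochs):
        losses = []
        for idx in _iterate_batches(len(y), cfg.batch_size, rng):
            _, logit = branch.forward_logit(x[idx])
            loss, dlogit = nn.bce_with_logits(logit, y[idx])
            opt.zero_grad()
            branch.backward_from_logit(dlogit)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    branch.eval()
    return history


def train_end_to_end(net, records, policy: AugmentationPolicy, cfg: TrainingConfig, modality=None):
    """Single-stage joint cross-entropy training (the comparison mode)."""
    if cfg.stage != "end_to_end":
        raise ValueError("cfg.stage must be 'end_to_end'")
    if not records:
        raise ValueError("empty training set")
    if len({rec.label for rec in records}) < 2:
        raise ValueError("end-to-end training needs both classes present")
    modality = modality or getattr(getattr(net, "cfg", None), "modality", None)
    if modality is None:
        raise ValueError("modality must be given for baseline networks")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 307]))
    pool = build_augmented_pool(records, policy, rng)
    x, y = records_to_arrays(pool, modality)
    opt = nn.SGD(
        list(net.named_parameters()),
        lr=cfg.effective_lr,
        momentum=cfg.momentum,
        weight_decay=cfg.effective_weight_decay,
    )
    history = []
    net.train(True)
    for _ in range(cfg.epochs):
        losses = []
        for idx in _iterate_batches(len(y), cfg.batch_size, rng):
            _, logit = net.forward_logit(x[idx])
            loss, dlogit = nn.bce_with_logits(logit, y[idx])
            opt.zero_grad()
            net.backward_from_logit(dlogit)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    net.eval()
    return history


def train_two_stage(branch, records, policy, pretrain_cfg, finetune_cfg):
    """Convenience wrapper: pretraining followed by fine-tuning."""
    h1 = pretrain_embedding(branch, records, policy, pretrain_cfg)
    h2 = finetune_classifier(branch, records, finetune_cfg)
    return h1, h2


def end_to_end_epochs_for_parity(
    n_records: int,
    policy: AugmentationPolicy,
    pretrain_cfg: TrainingConfig,
    finetune_cfg: TrainingConfig,
) -> int:
    """Epochs giving the end-to-end mode the same total gradient steps.

    Two-stage steps: pretraining runs on the augmented pool, fine-tuning on
    the originals; the end-to-end mode runs on the augmented pool.
    """
    n_pool = n_records * (1 + policy.multiplicity)
    steps_pre = pretrain_cfg.epochs * _steps_per_epoch(n_pool, pretrain_cfg.batch_size)
    steps_fine = finetune_cfg.epochs * _steps_per_epoch(n_records, finetune_cfg.batch_size)
    per_epoch = _steps_per_epoch(n_pool, pretrain_cfg.batch_size)
    return max(1, round((steps_pre + steps_fine) / per_epoch))


def matched_end_to_end_config(pretrain_cfg: TrainingConfig, epochs: int) -> TrainingConfig:
    return replace(pretrain_cfg, stage="end_to_end", epochs=epochs)
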