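"""Late fusion of the CT and MRI branches with availability-based routing.

A both-modality lesion is scored by the convex combination
``p = w_ct * p_ct + w_mr * p_mr`` (weights on the probability simplex,
default 0.5/0.5). Lesions with a single modality route to that branch alone.
``joint_update`` backpropagates cross-entropy on the fused probability into
both branches on mixed (both-modality) data; optionally the fusion weights
are learned too, re-projected onto the simplex after every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .cohort import LesionRecord
from .preprocessing import CT, MRI


@dataclass
class FusionConfig:
    w_ct: float = 0.5
    w_mr: float = 0.5
    epochs: int = 10
    batch_size: int = 16
    lr: float = 0.003
    momentum: float = 0.9
    weight_decay: float = 1e-4
    learnable_weights: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.w_ct < 0 or self.w_mr < 0 or abs(self.w_ct + self.w_mr - 1.0) > 1e-9:
            raise ValueError("fusion weights must be nonnegative and sum to 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def project_to_simplex(w: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex."""
    w = np.asarray(w, dtype=np.float64)
    u = np.sort(w)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.flatnonzero(u - css / (np.arange(len(w)) + 1) > 0)[-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(w - theta, 0.0)


class DoubleBranchModel:
    """CT branch + MRI branch + fusion weights; branches stay individually callable."""

    def __init__(self, ct_branch, mri_branch, weights=(0.5, 0.5), provenance=None):
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (2,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("fusion weights must be a 2-vector on the simplex")
        self.ct_branch = ct_branch
        self.mri_branch = mri_branch
        self.weights = w
        self.provenance = dict(provenance or {})

    @property
    def w_ct(self) -> float:
        return float(self.weights[0])

    @property
    def w_mr(self) -> float:
        return float(self.weights[1])

    def branch_probability(self, record: LesionRecord, modality: str) -> float:
        x = record.stack(modality).to_array()[None]
        branch = self.ct_branch if modality == CT else self.mri_branch
        return float(branch.predict_proba(x)[0])

    def predict(self, record: LesionRecord):
        """Return (probability, route) with route in {'ct', 'mri', 'fused'}."""
        has_ct = record.ct_stack is not None
        has_mri = record.mri_stack is not None
        if not has_ct and not has_mri:
            raise ValueError(f"lesion {record.lesion_id} has no modality stacks")
        if has_ct and has_mri:
            p = self.w_ct * self.branch_probability(record, CT) + self.w_mr * self.branch_probability(record, MRI)
            return p, "fused"
        if has_ct:
            return self.branch_probability(record, CT), "ct"
        return self.branch_probability(record, MRI), "mri"

    def predict_many(self, records):
        probs, routes = [], []
        for rec in records:
            p, r = self.predict(rec)
            probs.append(p)
            routes.append(r)
        return np.array(probs), routes


def fuse_branches(ct_branch, mri_branch, cfg: FusionConfig) -> DoubleBranchModel:
    return DoubleBranchModel(ct_branch, mri_branch, (cfg.w_ct, cfg.w_mr))


def joint_update(model: DoubleBranchModel, mixed_records, cfg: FusionConfig) -> DoubleBranchModel:
    """Cross-entropy on the fused probability, backpropagated into both branches.

    All records must have both modalities. Deterministic given ``cfg.seed``.
    Updates the model in place and returns it.
    """
    for rec in mixed_records:
        if rec.ct_stack is None or rec.mri_stack is None:
            raise ValueError(f"lesion {rec.lesion_id} lacks a modality; joint update needs both")
    if cfg.epochs == 0 or not mixed_records:
        return model
    x_ct = np.stack([rec.ct_stack.to_array() for rec in mixed_records])
    x_mr = np.stack([rec.mri_stack.to_array() for rec in mixed_records])
    y = np.array([rec.label for rec in mixed_records], dtype=np.float64)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 401]))
    opt_ct = nn.SGD(
        list(model.ct_branch.named_parameters()),
        lr=cfg.lr, momentum=cfg.momentum, weight_decay=cfg.weight_decay,
    )
    opt_mr = nn.SGD(
        list(model.mri_branch.named_parameters()),
        lr=cfg.lr, momentum=cfg.momentum, weight_decay=cfg.weight_decay,
    )
    model.ct_branch.train(True)
    model.mri_branch.train(True)
    eps = 1e-7
    n = len(y)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            _, z_ct = model.ct_branch.forward_logit(x_ct[idx])
            _, z_mr = model.mri_branch.forward_logit(x_mr[idx])
            p_ct, p_mr = nn.sigmoid(z_ct), nn.sigmoid(z_mr)
            w_ct, w_mr = model.weights
            p = np.clip(w_ct * p_ct + w_mr * p_mr, eps, 1 - eps)
            t = y[idx]
            dp = (p - t) / (p * (1.0 - p)) / len(idx)
            opt_ct.zero_grad()
            opt_mr.zero_grad()
            model.ct_branch.backward_from_logit(dp * w_ct * p_ct * (1 - p_ct))
            model.mri_branch.backward_from_logit(dp * w_mr * p_mr * (1 - p_mr))
            opt_ct.step()
            opt_mr.step()
            if cfg.learnable_weights:
                dw = np.array([float(dp @ p_ct), float(dp @ p_mr)])
                model.weights = project_to_simplex(model.weights - cfg.lr * dw)
    model.ct_branch.eval()
    model.mri_branch.eval()
    return model
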