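"""Losses: binary cross-entropy with logits and the triplet margin loss.

The triplet objective operates on L2-normalised embeddings with *squared*
Euclidean distances: ``max(0, d²(a,p) − d²(a,n) + m)``. Mining offers
``batch_all`` (every valid triple) and ``batch_hard`` (per anchor: farthest
positive, nearest negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import DTYPE, sigmoid


class NoValidTripletsError(ValueError):
    """The batch contains no anchor with both a positive and a negative."""


def bce_with_logits(logits, targets):
    """Mean binary cross-entropy; returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    if z.shape != t.shape:
        raise ValueError("logits and targets must have the same length")
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - t) / z.size
    return float(loss), dz.astype(DTYPE).reshape(np.shape(logits))


def triplet_loss(e_a, e_p, e_n, margin):
    """max(0, ||a−p||² − ||a−n||² + m) for single embeddings or batches."""
    e_a, e_p, e_n = (np.asarray(e, dtype=np.float64) for e in (e_a, e_p, e_n))
    if not (e_a.shape == e_p.shape == e_n.shape):
        raise ValueError("embedding dimension mismatch")
    d_ap = ((e_a - e_p) ** 2).sum(axis=-1)
    d_an = ((e_a - e_n) ** 2).sum(axis=-1)
    return np.maximum(0.0, d_ap - d_an + margin)


@dataclass(frozen=True)
class TripletBatch:
    """Index triples (anchor, positive, negative) into one batch."""

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray
    strategy: str

    def __len__(self):
        return len(self.anchors)

    def as_tuples(self):
        return list(zip(self.anchors.tolist(), self.positives.tolist(), self.negatives.tolist()))


def _squared_distances(emb):
    sq = (emb * emb).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (emb @ emb.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def mine_triplets(embeddings, labels, strategy="batch_hard") -> TripletBatch:
    emb = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels).ravel()
    if emb.shape[0] != y.shape[0]:
        raise ValueError("embeddings and labels length mismatch")
    if strategy not in ("batch_all", "batch_hard"):
        raise ValueError(f"unknown mining strategy: {strategy}")
    same = y[:, None] == y[None, :]
    pos_mask = same & ~np.eye(len(y), dtype=bool)
    neg_mask = ~same
    valid_anchor = pos_mask.any(axis=1) & neg_mask.any(axis=1)
    if not valid_anchor.any():
        raise NoValidTripletsError("no valid triplets: batch needs both classes")

    if strategy == "batch_all":
        a_idx, p_idx, n_idx = [], [], []
        for a in np.flatnonzero(valid_anchor):
            ps = np.flatnonzero(pos_mask[a])
            ns = np.flatnonzero(neg_mask[a])
            for p in ps:
                for n in ns:
                    a_idx.append(a)
                    p_idx.append(p)
                    n_idx.append(n)
        return TripletBatch(np.array(a_idx), np.array(p_idx), np.array(n_idx), strategy)

    d2 = _squared_distances(emb)
    anchors = np.flatnonzero(valid_anchor)
    pos_d = np.where(pos_mask[anchors], d2[anchors], -np.inf)
    neg_d = np.where(neg_mask[anchors], d2[anchors], np.inf)
    positives = pos_d.argmax(axis=1)
    negatives = neg_d.argmin(axis=1)
    return TripletBatch(anchors, positives, negatives, strategy)


def triplet_loss_batch(embeddings, labels, margin, strategy="batch_hard"):
    """Mean triplet loss over mined triples; returns (loss, dloss/dembeddings).

    Gradients flow only through triples with positive loss.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    batch = mine_triplets(emb, labels, strategy)
    a, p, n = batch.anchors, batch.positives, batch.negatives
    diff_ap = emb[a] - emb[p]
    diff_an = emb[a] - emb[n]
    losses = (diff_ap**2).sum(axis=1) - (diff_an**2).sum(axis=1) + margin
    active = losses > 0
    k = len(losses)
    loss = float(np.maximum(losses, 0.0).mean())
    demb = np.zeros_like(emb)
    if active.any():
        w = 2.0 / k
        aa, pp, nn = a[active], p[active], n[active]
        g_ap = diff_ap[active] * w
        g_an = diff_an[active] * w
        np.add.at(demb, aa, g_ap - g_an)
        np.add.at(demb, pp, -g_ap)
        np.add.at(demb, nn, g_an)
    return loss, demb.astype(DTYPE), batch
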