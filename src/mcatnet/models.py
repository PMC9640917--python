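"""Network definitions: the attention-gated branch network and the baselines.

A *branch* handles one modality (CT: 3 input channels, MRI: 6). Its feature
embedding module is an input modality-channel gate (SE-style, biased by a
radiologist prior over channels) followed by a small 3-stage residual
backbone (16/32/64 filters, optional per-stage SE attention), global average
pooling and a linear projection to an L2-normalised embedding. The evaluation
module is a single linear head producing an MVI-positive logit/probability.

Baselines (``2dcnn``, ``resnet18``, ``senet18``, ``ecanet18``) are standard
architectures adapted to the input channel count and a binary output;
``senet18``/``ecanet18`` are ``resnet18`` with SE / ECA blocks per residual
unit. The ResNet-18 family uses a stride-2 3x3 stem (no max-pool), sized for
64x64 lesion patches rather than natural images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .preprocessing import CT, MODALITY_CHANNELS, MRI

DEFAULT_PRIORS = {CT: (1.0, 2.0, 1.0), MRI: (1.0,) * 6}  # CT upweights AP

BASELINE_KINDS = ("2dcnn", "resnet18", "senet18", "ecanet18")


@dataclass(frozen=True)
class MAWMConfig:
    """Input modality-gate settings: bottleneck ratio and channel prior."""

    n_channels: int
    reduction: int = 2
    prior_weights: tuple | None = None

    def __post_init__(self):
        if self.reduction < 1:
            raise ValueError("reduction ratio must be >= 1")
        if self.prior_weights is not None and len(self.prior_weights) != self.n_channels:
            raise ValueError("prior length must equal n_channels")


@dataclass(frozen=True)
class BranchConfig:
    modality: str = CT
    widths: tuple = (16, 32, 64)
    embedding_dim: int = 128
    mawm_reduction: int = 2
    se_reduction: int = 4
    prior_weights: tuple | None = None  # None -> modality default
    input_gate: bool = True
    stage_attention: bool = True
    # low-pass the input before the stem: pixel noise cannot be represented,
    # so tiny cohorts cannot be memorised through it (small-sample bias)
    input_pool: int = 2

    def __post_init__(self):
        if self.modality not in (CT, MRI):
            raise ValueError(f"unknown modality: {self.modality}")
        if self.embedding_dim <= 0:
            raise ValueError("embedding dimension must be positive")

    @property
    def n_channels(self) -> int:
        return len(MODALITY_CHANNELS[self.modality])

    @property
    def prior(self) -> tuple:
        if self.prior_weights is not None:
            return tuple(self.prior_weights)
        return DEFAULT_PRIORS[self.modality]


@dataclass(frozen=True)
class AttentionProfile:
    """Batch-averaged per-channel gate values from a modality gate."""

    gates: tuple
    channel_names: tuple

    def __post_init__(self):
        if len(self.gates) != len(self.channel_names):
            raise ValueError("one gate per channel required")
        if any(not (0.0 <= g <= 1.0) for g in self.gates):
            raise ValueError("gates must lie in [0, 1]")

    def as_dict(self) -> dict:
        return dict(zip(self.channel_names, self.gates))


def mawm_forward(x, cfg: MAWMConfig, gate: nn.ModalityChannelGate | None = None, seed: int = 0):
    """Functional gate application: returns (reweighted x, AttentionProfile).

    If ``gate`` is None a fresh zero-initialised gate is built from ``cfg``
    (gates start at the prior). Channel names default to indices.
    """
    x = np.asarray(x, dtype=nn.DTYPE)
    if x.shape[1] != cfg.n_channels:
        raise ValueError(f"expected {cfg.n_channels} channels, got {x.shape[1]}")
    if gate is None:
        gate = nn.ModalityChannelGate(
            cfg.n_channels,
            cfg.reduction,
            cfg.prior_weights,
            rng=np.random.default_rng(seed),
        )
    out = gate.forward(x)
    names = tuple(str(i) for i in range(cfg.n_channels))
    return out, AttentionProfile(tuple(float(g) for g in gate.last_gates), names)


class BranchNet(nn.Module):
    """Single-modality branch: gated embedding module + linear evaluation head."""

    def __init__(self, cfg: BranchConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        ss = np.random.SeedSequence([seed, 17])
        gate_rng, body_rng, head_rng = (np.random.default_rng(s) for s in ss.spawn(3))
        c_in = cfg.n_channels
        self.gate = (
            nn.ModalityChannelGate(c_in, cfg.mawm_reduction, cfg.prior, rng=gate_rng)
            if cfg.input_gate
            else None
        )
        w1, w2, w3 = cfg.widths

        def se(c):
            return nn.SEBlock(c, cfg.se_reduction, rng=body_rng) if cfg.stage_attention else None

        pool = [nn.AvgPool2d(cfg.input_pool)] if cfg.input_pool > 1 else []
        self.body = nn.Sequential(
            *pool,
            # per-input-channel weight-normalised stem: the gate alone carries
            # modality-channel gain, keeping the attention profile identifiable
            nn.ChannelNormalizedConv2d(c_in, w1, 3, stride=2, rng=body_rng),
            nn.BatchNorm2d(w1),
            nn.ReLU(),
            nn.ResidualBlock(w1, w1, 1, se(w1), rng=body_rng),
            nn.ResidualBlock(w1, w2, 2, se(w2), rng=body_rng),
            nn.ResidualBlock(w2, w3, 2, se(w3), rng=body_rng),
            nn.GlobalAvgPool(),
            nn.Linear(w3, cfg.embedding_dim, rng=body_rng),
            nn.L2Normalize(),
        )
        self.head = nn.Linear(cfg.embedding_dim, 1, rng=head_rng)

    def children(self):
        out = [] if self.gate is None else [self.gate]
        return out + [self.body, self.head]

    # -- forward/backward -------------------------------------------------
    def forward_embedding(self, x):
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim != 4 or x.shape[1] != self.cfg.n_channels:
            raise ValueError(
                f"expected (N, {self.cfg.n_channels}, S, S) input, got {x.shape}"
            )
        if self.gate is not None:
            x = self.gate.forward(x)
        return self.body.forward(x)

    def forward_logit(self, x):
        emb = self.forward_embedding(x)
        return emb, self.head.forward(emb)[:, 0]

    def forward(self, x):
        """(embedding, probability) pair for inference."""
        emb, logit = self.forward_logit(x)
        return emb, nn.sigmoid(logit)

    def backward_from_embedding(self, demb):
        d = self.body.backward(demb)
        if self.gate is not None:
            d = self.gate.backward(d)
        return d

    def backward_from_logit(self, dlogit):
        demb = self.head.backward(np.asarray(dlogit, dtype=nn.DTYPE)[:, None])
        return self.backward_from_embedding(demb)

    # -- parameter groups --------------------------------------------------
    def embedding_param_refs(self):
        mods = ([self.gate] if self.gate is not None else []) + [self.body]
        return [(m, k) for mod in mods for m, k in mod.named_parameters()]

    def head_param_refs(self):
        return list(self.head.named_parameters())

    def predict_proba(self, x):
        self.eval()
        _, prob = self.forward(x)
        return prob

    def attention_profile(self) -> AttentionProfile:
        if self.gate is None or self.gate.last_gates is None:
            raise ValueError("no input gate, or no forward pass recorded yet")
        names = MODALITY_CHANNELS[self.cfg.modality]
        return AttentionProfile(tuple(float(g) for g in self.gate.last_gates), names)


def build_single_branch(cfg: BranchConfig, seed: int = 0) -> BranchNet:
    return BranchNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

class BaselineNet(nn.Sequential):
    """Plain feed-forward classifier emitting a single logit per sample."""

    def __init__(self, *layers, kind: str):
        super().__init__(*layers)
        self.kind = kind

    def forward_logit(self, x):
        return None, super().forward(np.asarray(x, dtype=nn.DTYPE))[:, 0]

    def backward_from_logit(self, dlogit):
        return super().backward(np.asarray(dlogit, dtype=nn.DTYPE)[:, None])

    def predict_proba(self, x):
        self.eval()
        _, logit = self.forward_logit(x)
        return nn.sigmoid(logit)


def _resnet18(channels: int, attention: str | None, rng) -> BaselineNet:
    def attn(c):
        if attention == "se":
            return nn.SEBlock(c, 16, rng=rng)
        if attention == "eca":
            return nn.ECABlock(c, rng=rng)
        return None

    layers = [
        nn.Conv2d(channels, 64, 3, stride=2, rng=rng),
        nn.BatchNorm2d(64),
        nn.ReLU(),
    ]
    c_in = 64
    for c_out, stride in ((64, 1), (128, 2), (256, 2), (512, 2)):
        layers.append(nn.ResidualBlock(c_in, c_out, stride, attn(c_out), rng=rng))
        layers.append(nn.ResidualBlock(c_out, c_out, 1, attn(c_out), rng=rng))
        c_in = c_out
    layers += [nn.GlobalAvgPool(), nn.Linear(512, 1, rng=rng)]
    kind = {"se": "senet18", "eca": "ecanet18", None: "resnet18"}[attention]
    return BaselineNet(*layers, kind=kind)


def _cnn2d(channels: int, rng) -> BaselineNet:
    layers = []
    c_in = channels
    for c_out in (16, 32, 64, 128):
        layers += [
            nn.Conv2d(c_in, c_out, 3, stride=2, rng=rng),
            nn.BatchNorm2d(c_out),
            nn.ReLU(),
        ]
        c_in = c_out
    layers += [nn.GlobalAvgPool(), nn.Linear(128, 1, rng=rng)]
    return BaselineNet(*layers, kind="2dcnn")


def build_baseline(kind: str, channels: int, seed: int = 0) -> BaselineNet:
    """Build a named baseline classifier for ``channels`` input channels."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    if kind == "2dcnn":
        return _cnn2d(channels, rng)
    if kind == "resnet18":
        return _resnet18(channels, None, rng)
    if kind == "senet18":
        return _resnet18(channels, "se", rng)
    if kind == "ecanet18":
        return _resnet18(channels, "eca", rng)
    raise ValueError(f"unknown baseline kind: {kind!r} (choose from {BASELINE_KINDS})")
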