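"""Synthetic multimodal lesion cohorts with a known planted class signal.

Each lesion is a set of per-channel 2D patches. A channel image is the sum of

* a fixed, deterministic lesion disk (same for every lesion — carries no
  class information),
* a smoothed Gaussian random texture, drawn independently per channel,
* the class signal: ``label * delta_c * T_c`` where ``T_c`` is a unit-norm
  channel-specific spatial template, and
* white Gaussian pixel noise.

``delta_c`` is calibrated so that the *standardized* effect of channel ``c``
on its template projection is exactly the configured ``d_c``: the projection
``u_c = <T_c, image_c>`` is Gaussian with class-conditional means separated by
``d_c`` standard deviations. Because textures and noise are independent across
channels, the optimal linear readout over informative channels has combined
effect ``d_eff = sqrt(sum_c d_c^2)`` and Bayes AUC ``Phi(d_eff / sqrt(2))`` —
a closed form used to calibrate and test everything downstream.

Default cohort composition mirrors a 121-lesion clinical cohort: 49 CT-only
(18 MVI-positive / 31 negative), 32 MRI-only (12/20), 40 with both modalities
(14/26). Default signal placement is complementary: CT arterial phase and MRI
DWI each carry d = 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .preprocessing import (
    CT,
    CT_CHANNELS,
    MODALITY_CHANNELS,
    MRI,
    MRI_CHANNELS,
    ModalityStack,
    RoiPatch,
    normalize_greyscale,
)

ALL_CHANNELS = tuple((CT, c) for c in CT_CHANNELS) + tuple((MRI, c) for c in MRI_CHANNELS)


@dataclass
class CohortSpec:
    """Generating parameters for one synthetic cohort."""

    n_ct_only: int = 49
    n_mri_only: int = 32
    n_mixed: int = 40
    pos_ct_only: int = 18
    pos_mri_only: int = 12
    pos_mixed: int = 14
    side: int = 64
    ct_effects: tuple = (0.0, 1.5, 0.0)  # (plain, AP, PVP)
    mri_effects: tuple = (0.0, 1.5, 0.0, 0.0, 0.0, 0.0)  # DWI informative
    texture_sd: float = 0.3
    noise_sd: float = 0.15
    smooth_sigma: float | None = None  # default: side / 16
    seed: int = 0

    def __post_init__(self):
        for n in (self.n_ct_only, self.n_mri_only, self.n_mixed):
            if n < 0:
                raise ValueError("group counts must be nonnegative")
        for n, p in (
            (self.n_ct_only, self.pos_ct_only),
            (self.n_mri_only, self.pos_mri_only),
            (self.n_mixed, self.pos_mixed),
        ):
            if not 0 <= p <= n:
                raise ValueError("positive counts must lie within group sizes")
        if len(self.ct_effects) != 3 or len(self.mri_effects) != 6:
            raise ValueError("need 3 CT and 6 MRI effect sizes")
        eff = np.concatenate([self.ct_effects, self.mri_effects])
        if not np.all(np.isfinite(eff)) or np.any(eff < 0):
            raise ValueError("effect sizes must be finite and nonnegative")
        if self.side < 8:
            raise ValueError("patch side too small")

    @property
    def sigma(self) -> float:
        return self.smooth_sigma if self.smooth_sigma is not None else self.side / 16.0

    def effect(self, modality: str, channel: str) -> float:
        names = MODALITY_CHANNELS[modality]
        effs = self.ct_effects if modality == CT else self.mri_effects
        return float(effs[names.index(channel)])


@dataclass
class LesionRecord:
    """One lesion: label, modality availability, and the available stacks."""

    lesion_id: str
    label: int
    availability: str  # 'CT', 'MRI', or 'both'
    ct_stack: ModalityStack | None = None
    mri_stack: ModalityStack | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be binary")
        need_ct = self.availability in (CT, "both")
        need_mri = self.availability in (MRI, "both")
        if self.availability not in (CT, MRI, "both"):
            raise ValueError(f"bad availability: {self.availability}")
        if need_ct != (self.ct_stack is not None) or need_mri != (self.mri_stack is not None):
            raise ValueError("availability inconsistent with present stacks")

    def stack(self, modality: str) -> ModalityStack:
        s = self.ct_stack if modality == CT else self.mri_stack
        if s is None:
            raise ValueError(f"lesion {self.lesion_id} has no {modality} stack")
        return s

    @property
    def origin(self) -> str:
        return self.provenance.get("origin", "original")


# ---------------------------------------------------------------------------
# spatial structures
# ---------------------------------------------------------------------------

def lesion_disk(side: int) -> np.ndarray:
    """Soft-edged disk shared by every lesion (class-neutral background)."""
    yy, xx = np.mgrid[0:side, 0:side]
    r = np.hypot(yy - (side - 1) / 2.0, xx - (side - 1) / 2.0)
    radius = 0.30 * side
    return 1.0 / (1.0 + np.exp((r - radius) / (0.05 * side)))


def lesion_mask(side: int) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    r = np.hypot(yy - (side - 1) / 2.0, xx - (side - 1) / 2.0)
    return (r <= 0.30 * side).astype(np.uint8)


def channel_template(modality: str, channel: str, side: int) -> np.ndarray:
    """Unit-norm Gaussian bump at a channel-specific offset inside the lesion."""
    idx = ALL_CHANNELS.index((modality, channel))
    theta = 2.0 * np.pi * idx / len(ALL_CHANNELS)
    cy = (side - 1) / 2.0 + 0.125 * side * np.sin(theta)
    cx = (side - 1) / 2.0 + 0.125 * side * np.cos(theta)
    yy, xx = np.mgrid[0:side, 0:side]
    width = 0.18 * side  # broad bump: a contrast-enhancement-like intensity pattern
    t = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * width**2)))
    return t / np.linalg.norm(t)


def projection_sd(spec: CohortSpec, template: np.ndarray) -> float:
    """Exact SD of <T, image> under the generator's noise model.

    The texture term is smoothed white noise with zero padding, whose adjoint
    is the same smoothing, so Var(<T, texture>) = texture_sd^2 ||k*T||^2;
    the white-noise term contributes noise_sd^2 ||T||^2 = noise_sd^2.
    """
    smoothed = gaussian_filter(template, spec.sigma, mode="constant")
    return float(
        np.sqrt(spec.texture_sd**2 * np.sum(smoothed**2) + spec.noise_sd**2)
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

class _Generator:
    """Caches templates / calibrated amplitudes for one spec."""

    def __init__(self, spec: CohortSpec):
        self.spec = spec
        self.disk = lesion_disk(spec.side)
        self.templates: dict[tuple[str, str], np.ndarray] = {}
        self.sds: dict[tuple[str, str], float] = {}
        self.deltas: dict[tuple[str, str], float] = {}
        for modality, channel in ALL_CHANNELS:
            t = channel_template(modality, channel, spec.side)
            self.templates[(modality, channel)] = t
            sd = projection_sd(spec, t)
            self.sds[(modality, channel)] = sd
            self.deltas[(modality, channel)] = spec.effect(modality, channel) * sd

    def raw_channel(self, rng, modality, channel, label):
        spec = self.spec
        texture = spec.texture_sd * gaussian_filter(
            rng.standard_normal((spec.side, spec.side)), spec.sigma, mode="constant"
        )
        img = self.disk + texture
        delta = self.deltas[(modality, channel)]
        if label and delta:
            img = img + delta * self.templates[(modality, channel)]
        img = img + spec.noise_sd * rng.standard_normal((spec.side, spec.side))
        return img

    def raw_modality(self, rng, modality, label):
        return {c: self.raw_channel(rng, modality, c, label) for c in MODALITY_CHANNELS[modality]}

    def oracle_score(self, images_by_modality) -> dict[str, float]:
        """LDA readout per modality and combined, from raw channel images."""
        per_mod = {}
        for modality, images in images_by_modality.items():
            s = 0.0
            for channel, img in images.items():
                d = self.spec.effect(modality, channel)
                if d:
                    key = (modality, channel)
                    s += d * float(np.sum(self.templates[key] * img)) / self.sds[key]
            per_mod[modality] = s
        out = {m: per_mod.get(m, np.nan) for m in (CT, MRI)}
        out["both"] = float(np.nansum([v for v in per_mod.values()]))
        return out


def _stack_from_raw(images: dict, modality: str) -> ModalityStack:
    patches = [
        RoiPatch(pixels=normalize_greyscale(images[c]), channel_name=c)
        for c in MODALITY_CHANNELS[modality]
    ]
    return ModalityStack(channels=patches, modality=modality)


def _group_labels(n: int, n_pos: int, rng) -> np.ndarray:
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    return rng.permutation(labels)


def generate_cohort(spec: CohortSpec) -> list[LesionRecord]:
    """Deterministic (given ``spec.seed``) cohort with exact group composition."""
    rng = np.random.default_rng(spec.seed)
    gen = _Generator(spec)
    records: list[LesionRecord] = []
    groups = [
        ("ct", CT, spec.n_ct_only, spec.pos_ct_only),
        ("mr", MRI, spec.n_mri_only, spec.pos_mri_only),
        ("mx", "both", spec.n_mixed, spec.pos_mixed),
    ]
    for prefix, availability, n, n_pos in groups:
        labels = _group_labels(n, n_pos, rng)
        for i, label in enumerate(labels):
            label = int(label)
            images = {}
            if availability in (CT, "both"):
                images[CT] = gen.raw_modality(rng, CT, label)
            if availability in (MRI, "both"):
                images[MRI] = gen.raw_modality(rng, MRI, label)
            scores = gen.oracle_score(images)
            records.append(
                LesionRecord(
                    lesion_id=f"{prefix}-{i:03d}",
                    label=label,
                    availability=availability,
                    ct_stack=_stack_from_raw(images[CT], CT) if CT in images else None,
                    mri_stack=_stack_from_raw(images[MRI], MRI) if MRI in images else None,
                    provenance={
                        "origin": "original",
                        "oracle_ct": scores[CT],
                        "oracle_mri": scores[MRI],
                        "oracle_both": scores["both"],
                    },
                )
            )
    return records


def simulate_oracle_scores(spec: CohortSpec, n: int, seed: int, positive_fraction: float = 0.5):
    """Stream ``n`` both-modality lesions; keep only labels and oracle scores.

    Returns ``(labels, scores)`` where scores has keys 'CT', 'MRI', 'both'.
    Used for Monte-Carlo calibration against the closed-form Bayes AUC
    without materialising image stacks.
    """
    rng = np.random.default_rng(seed)
    gen = _Generator(spec)
    n_pos = int(round(n * positive_fraction))
    labels = _group_labels(n, n_pos, rng)
    scores = {CT: np.empty(n), MRI: np.empty(n), "both": np.empty(n)}
    for i, label in enumerate(labels):
        images = {CT: gen.raw_modality(rng, CT, int(label)), MRI: gen.raw_modality(rng, MRI, int(label))}
        s = gen.oracle_score(images)
        for k in scores:
            scores[k][i] = s[k]
    return labels, scores


def d_eff(spec: CohortSpec, modality: str = "both") -> float:
    """Combined standardized effect over the informative channels."""
    eff = []
    if modality in (CT, "both"):
        eff.extend(spec.ct_effects)
    if modality in (MRI, "both"):
        eff.extend(spec.mri_effects)
    if modality not in (CT, MRI, "both"):
        raise ValueError(f"bad modality: {modality}")
    return float(np.sqrt(np.sum(np.square(eff))))


def planted_bayes_auc(spec: CohortSpec, modality: str = "both") -> float:
    """Closed-form AUC of the oracle linear readout: Phi(d_eff / sqrt(2))."""
    return float(norm.cdf(d_eff(spec, modality) / np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# manifest + PNG round trip (same layout roi preprocessing reads)
# ---------------------------------------------------------------------------

def write_cohort(records, out_dir) -> Path:
    """Write 16-bit PNG channel images + masks and a manifest CSV.

    Images are min-max scaled per patch before quantisation (the reader
    re-normalises, so only per-pixel relative intensity matters).
    """
    import pandas as pd
    from PIL import Image

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    mask_cache: dict[int, str] = {}
    for rec in records:
        for modality in (CT, MRI):
            stack = rec.ct_stack if modality == CT else rec.mri_stack
            if stack is None:
                continue
            side = stack.side
            if side not in mask_cache:
                mask_name = f"mask_{side}.png"
                Image.fromarray(lesion_mask(side) * 255).save(img_dir / mask_name)
                mask_cache[side] = f"images/{mask_name}"
            for patch in stack.channels:
                safe = patch.channel_name.replace("/", "-")
                name = f"{rec.lesion_id}_{modality}_{safe}.png"
                arr = np.round(patch.pixels.astype(np.float64) * 65535).astype(np.uint16)
                Image.fromarray(arr).save(img_dir / name)
                rows.append(
                    {
                        "lesion_id": rec.lesion_id,
                        "label": rec.label,
                        "modality": modality,
                        "channel": patch.channel_name,
                        "image_path": f"images/{name}",
                        "mask_path": mask_cache[side],
                    }
                )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
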