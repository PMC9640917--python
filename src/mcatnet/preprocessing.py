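"""ROI extraction and normalization for segmented CT/MRI lesion volumes.

The pipeline follows the single-slice convention used for small-sample lesion
classification: for each channel volume, take the 2D slice with the largest
lesion mask area, crop a margin-padded bounding box around the mask, min-max
normalize to [0, 1], and resample (bilinear) to a fixed patch side ``S``.
Channels of one modality are assembled into a fixed-order ``ModalityStack``:

* CT: plain scan, arterial phase (AP), portal-venous phase (PVP)
* MRI: T2WI, DWI, T1 precontrast, T1-AP, T1-PVP, T1-EP

Inter-channel registration is assumed given: each channel contributes its own
largest-lesion slice and no cross-phase alignment is attempted. Bounding boxes
are 0-based half-open ``(row_start, row_stop, col_start, col_stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

CT = "CT"
MRI = "MRI"
CT_CHANNELS = ("plain", "AP", "PVP")
MRI_CHANNELS = ("T2WI", "DWI", "T1pre", "T1-AP", "T1-PVP", "T1-EP")
MODALITY_CHANNELS = {CT: CT_CHANNELS, MRI: MRI_CHANNELS}

DEFAULT_PATCH_SIDE = 64
DEFAULT_CROP_MARGIN = 4


class EmptyMaskError(ValueError):
    """The lesion mask contains no nonzero voxel."""


@dataclass
class AnnotatedVolume:
    """One channel's segmented volume: (slices, rows, cols) image + binary mask."""

    image: np.ndarray
    mask: np.ndarray
    channel_name: str
    spacing: tuple | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3:
            raise ValueError("image must be 3D (slices, rows, cols)")
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary {0,1}")


@dataclass
class RoiPatch:
    """Fixed-size normalized 2D lesion patch with provenance."""

    pixels: np.ndarray
    channel_name: str
    source_slice: int | None = None
    bbox: tuple[int, int, int, int] | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("patch must be 2D")
        if self.pixels.size and (self.pixels.min() < -1e-6 or self.pixels.max() > 1 + 1e-6):
            raise ValueError("patch values must lie in [0, 1]")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ModalityStack:
    """Ordered per-channel ROI patches for one modality of one lesion."""

    channels: list[RoiPatch]
    modality: str

    def __post_init__(self):
        expected = MODALITY_CHANNELS.get(self.modality)
        if expected is None:
            raise ValueError(f"unknown modality: {self.modality}")
        names = tuple(p.channel_name for p in self.channels)
        if names != expected:
            raise ValueError(f"channel order must be {expected}, got {names}")
        sides = {p.pixels.shape for p in self.channels}
        if len(sides) > 1:
            raise ValueError("all channels must share the same patch size")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return MODALITY_CHANNELS[self.modality]

    @property
    def side(self) -> int:
        return self.channels[0].side

    def to_array(self) -> np.ndarray:
        """(C, S, S) float32 array in canonical channel order."""
        return np.stack([p.pixels for p in self.channels]).astype(np.float32)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def select_largest_lesion_slice(volume: AnnotatedVolume) -> int:
    """Index of the slice with the largest mask area; ties -> lowest index."""
    areas = volume.mask.reshape(volume.mask.shape[0], -1).sum(axis=1)
    if areas.sum() == 0:
        raise EmptyMaskError("empty mask: no nonzero voxel in any slice")
    return int(np.argmax(areas))


def crop_roi(slice_image: np.ndarray, slice_mask: np.ndarray, margin: int = DEFAULT_CROP_MARGIN):
    """Crop the margin-expanded tight mask bounding box, clipped to the image.

    Returns ``(patch, bbox)`` with bbox as half-open (r0, r1, c0, c1).
    """
    slice_image = np.asarray(slice_image)
    slice_mask = np.asarray(slice_mask)
    if slice_image.shape != slice_mask.shape or slice_image.ndim != 2:
        raise ValueError("slice image and mask must be 2D with equal shapes")
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    rows = np.flatnonzero(slice_mask.any(axis=1))
    cols = np.flatnonzero(slice_mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("empty mask on the selected slice")
    r0 = max(0, int(rows[0]) - margin)
    r1 = min(slice_image.shape[0], int(rows[-1]) + 1 + margin)
    c0 = max(0, int(cols[0]) - margin)
    c1 = min(slice_image.shape[1], int(cols[-1]) + 1 + margin)
    return slice_image[r0:r1, c0:c1], (r0, r1, c0, c1)


def normalize_greyscale(patch: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant patch maps to all zeros."""
    patch = np.asarray(patch, dtype=np.float64)
    if not np.all(np.isfinite(patch)):
        raise ValueError("patch contains non-finite values")
    lo, hi = patch.min(), patch.max()
    if hi == lo:
        return np.zeros_like(patch, dtype=np.float32)
    return ((patch - lo) / (hi - lo)).astype(np.float32)


def resample_patch(patch: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resample to ``side`` x ``side`` (values stay in [0, 1])."""
    out = resize(
        np.asarray(patch, dtype=np.float64),
        (side, side),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def extract_roi_patch(
    volume: AnnotatedVolume,
    side: int = DEFAULT_PATCH_SIDE,
    margin: int = DEFAULT_CROP_MARGIN,
    mask_background: bool = False,
) -> RoiPatch:
    """Full per-channel pipeline: slice selection -> crop -> normalize -> resample."""
    idx = select_largest_lesion_slice(volume)
    img = np.asarray(volume.image[idx], dtype=np.float64)
    msk = volume.mask[idx]
    if mask_background:
        img = img * msk
    cropped, bbox = crop_roi(img, msk, margin)
    pixels = resample_patch(normalize_greyscale(cropped), side)
    return RoiPatch(pixels=pixels, channel_name=volume.channel_name, source_slice=idx, bbox=bbox)


def assemble_modality_stack(patches, modality: str) -> ModalityStack:
    """Order named patches canonically; reject missing/duplicate channels."""
    expected = MODALITY_CHANNELS.get(modality)
    if expected is None:
        raise ValueError(f"unknown modality: {modality}")
    by_name: dict[str, RoiPatch] = {}
    for p in patches:
        if p.channel_name in by_name:
            raise ValueError(f"duplicate channel {p.channel_name!r}")
        by_name[p.channel_name] = p
    missing = [c for c in expected if c not in by_name]
    if missing:
        raise ValueError(f"missing channel {missing[0]!r}")
    extra = [c for c in by_name if c not in expected]
    if extra:
        raise ValueError(f"unexpected channel {extra[0]!r} for modality {modality}")
    return ModalityStack(channels=[by_name[c] for c in expected], modality=modality)


# ---------------------------------------------------------------------------
# file IO: NIfTI / PNG volumes and the cohort manifest
# ---------------------------------------------------------------------------

def load_channel_volume(image_path, mask_path, channel_name: str) -> AnnotatedVolume:
    """Read an image+mask pair from NIfTI (.nii/.nii.gz) or a 2D PNG."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    if image_path.suffix == ".png":
        from PIL import Image

        img = np.asarray(Image.open(image_path), dtype=np.float64)[None]
        msk = np.asarray(Image.open(mask_path))[None]
    else:
        import nibabel as nib

        img = np.asarray(nib.load(str(image_path)).get_fdata(), dtype=np.float64)
        msk = np.asarray(nib.load(str(mask_path)).get_fdata())
        # NIfTI is (x, y, z); treat the last axis as the slice axis
        img = np.moveaxis(img, -1, 0)
        msk = np.moveaxis(msk, -1, 0)
    msk = (np.asarray(msk) > 0).astype(np.uint8)
    return AnnotatedVolume(image=img, mask=msk, channel_name=channel_name)


@dataclass
class ManifestEntry:
    lesion_id: str
    label: int
    modality: str
    channel: str
    image_path: str
    mask_path: str


def read_manifest(path) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    df = pd.read_csv(path, dtype={"lesion_id": str})
    required = {"lesion_id", "label", "modality", "channel", "image_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def build_stacks_from_manifest(
    manifest_path,
    side: int = DEFAULT_PATCH_SIDE,
    margin: int = DEFAULT_CROP_MARGIN,
    mask_background: bool = False,
):
    """Assemble per-lesion modality stacks from a manifest CSV.

    Returns a list of ``(lesion_id, label, {modality: ModalityStack})`` sorted
    by lesion id. Relative paths are resolved against the manifest directory.
    """
    df = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    out = []
    for lesion_id, group in df.groupby("lesion_id", sort=True):
        labels = group["label"].unique()
        if len(labels) != 1:
            raise ValueError(f"lesion {lesion_id}: inconsistent labels")
        stacks = {}
        for modality, chan_group in group.groupby("modality"):
            patches = []
            for row in chan_group.itertuples():
                vol = load_channel_volume(
                    base / row.image_path, base / row.mask_path, row.channel
                )
                patches.append(
                    extract_roi_patch(vol, side=side, margin=margin, mask_background=mask_background)
                )
            stacks[modality] = assemble_modality_stack(patches, modality)
        out.append((str(lesion_id), int(labels[0]), stacks))
    return out
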