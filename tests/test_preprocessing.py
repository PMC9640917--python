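import numpy as np
import pytest

from mcatnet.preprocessing import (
    CT,
    CT_CHANNELS,
    MRI,
    MRI_CHANNELS,
    AnnotatedVolume,
    EmptyMaskError,
    RoiPatch,
    assemble_modality_stack,
    build_stacks_from_manifest,
    crop_roi,
    extract_roi_patch,
    load_channel_volume,
    normalize_greyscale,
    resample_patch,
    select_largest_lesion_slice,
)


def volume_with_areas(areas, side=6, channel="AP"):
    mask = np.zeros((len(areas), side, side), dtype=np.uint8)
    for i, a in enumerate(areas):
        mask[i].flat[:a] = 1
    img = np.random.default_rng(0).random(mask.shape)
    return AnnotatedVolume(image=img, mask=mask, channel_name=channel)


class TestSliceSelection:
    def test_argmax_area(self):
        assert select_largest_lesion_slice(volume_with_areas([0, 5, 9, 3])) == 2

    def test_tie_breaks_to_lowest_index(self):
        assert select_largest_lesion_slice(volume_with_areas([4, 4, 1])) == 0

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            select_largest_lesion_slice(volume_with_areas([0, 0]))

    def test_selected_slice_dominates_all_others(self, rng):
        mask = (rng.random((7, 9, 9)) > 0.6).astype(np.uint8)
        vol = AnnotatedVolume(image=np.zeros_like(mask, dtype=float), mask=mask, channel_name="DWI")
        idx = select_largest_lesion_slice(vol)
        areas = mask.reshape(7, -1).sum(axis=1)
        assert all(areas[idx] >= a for a in areas)


class TestCrop:
    def setup_method(self):
        self.mask = np.zeros((8, 9), dtype=np.uint8)
        self.mask[2:6, 3:8] = 1
        self.img = np.arange(72, dtype=float).reshape(8, 9)

    def test_tight_box(self):
        patch, bbox = crop_roi(self.img, self.mask, margin=0)
        assert bbox == (2, 6, 3, 8)
        assert patch.shape == (4, 5)
        np.testing.assert_array_equal(patch, self.img[2:6, 3:8])

    def test_margin_clipped_to_image(self):
        # tight box (2,6)x(3,8) expanded by 3: rows [-1,9) -> [0,8), cols [0,11) -> [0,9)
        patch, bbox = crop_roi(self.img, self.mask, margin=3)
        assert bbox == (0, 8, 0, 9)
        assert patch.shape == (8, 9)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            crop_roi(self.img, np.zeros_like(self.mask), margin=1)


class TestNormalize:
    def test_min_max_values(self):
        out = normalize_greyscale(np.array([[0.0, 128.0, 255.0]]))
        np.testing.assert_allclose(out, [[0.0, 128 / 255, 1.0]], atol=1e-7)

    def test_constant_patch_maps_to_zero(self):
        assert not normalize_greyscale(np.full((4, 4), 7.0)).any()

    def test_unit_range_unchanged(self):
        patch = np.array([[0.0, 0.25], [0.75, 1.0]])
        np.testing.assert_allclose(normalize_greyscale(patch), patch, atol=1e-7)

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        patch = np.random.default_rng(seed).random((12, 12)) * 40 - 7
        once = normalize_greyscale(patch)
        np.testing.assert_allclose(normalize_greyscale(once), once, atol=1e-6)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            normalize_greyscale(np.array([[1.0, np.nan]]))


class TestStackAssembly:
    @staticmethod
    def patches(names, side=8):
        return [RoiPatch(pixels=np.zeros((side, side)), channel_name=n) for n in names]

    def test_ct_stack_canonical_order(self):
        stack = assemble_modality_stack(self.patches(("PVP", "plain", "AP")), CT)
        assert tuple(p.channel_name for p in stack.channels) == CT_CHANNELS

    def test_missing_mri_channel(self):
        with pytest.raises(ValueError, match="T1-EP"):
            assemble_modality_stack(self.patches(MRI_CHANNELS[:5]), MRI)

    def test_duplicate_channel(self):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_modality_stack(self.patches(("plain", "AP", "AP")), CT)

    def test_mismatched_sizes(self):
        ps = self.patches(("plain", "AP"), side=8) + self.patches(("PVP",), side=16)
        with pytest.raises(ValueError, match="size"):
            assemble_modality_stack(ps, CT)


class TestPipelineProperties:
    @pytest.mark.parametrize("pos", [(10, 14), (22, 9), (16, 16)])
    def test_impulse_argmax_survives_crop_resample(self, pos):
        # a single bright pixel keeps its (rescaled) argmax through the pipeline
        side = 32
        img3 = np.zeros((1, side, side))
        img3[0][pos] = 1.0
        mask = np.zeros_like(img3, dtype=np.uint8)
        mask[0, 4:28, 4:28] = 1
        vol = AnnotatedVolume(image=img3, mask=mask, channel_name="AP")
        patch = extract_roi_patch(vol, side=24, margin=0)
        r, c = np.unravel_index(np.argmax(patch.pixels), patch.pixels.shape)
        scale = 24 / 24.0  # crop is 24x24 -> resample to 24
        assert abs(r - (pos[0] - 4) * scale) <= 1
        assert abs(c - (pos[1] - 4) * scale) <= 1

    def test_resample_preserves_range(self, rng):
        out = resample_patch(rng.random((13, 17)), 32)
        assert out.shape == (32, 32)
        assert out.min() >= 0 and out.max() <= 1


class TestFileIO:
    def test_nifti_roundtrip(self, tmp_path):
        import nibabel as nib

        rng = np.random.default_rng(5)
        img = rng.random((6, 7, 4))  # (x, y, z): 4 slices
        mask = np.zeros_like(img)
        mask[2:5, 2:5, 1] = 1
        nib.save(nib.Nifti1Image(img, np.eye(4)), tmp_path / "img.nii.gz")
        nib.save(nib.Nifti1Image(mask, np.eye(4)), tmp_path / "mask.nii.gz")
        vol = load_channel_volume(tmp_path / "img.nii.gz", tmp_path / "mask.nii.gz", "T2WI")
        assert vol.image.shape == (4, 6, 7)
        assert select_largest_lesion_slice(vol) == 1

    def test_manifest_roundtrip_with_synthetic_cohort(self, tmp_path):
        from mcatnet.cohort import CohortSpec, generate_cohort, write_cohort

        spec = CohortSpec(
            n_ct_only=2, n_mri_only=1, n_mixed=1,
            pos_ct_only=1, pos_mri_only=1, pos_mixed=0, side=24, seed=4,
        )
        records = generate_cohort(spec)
        manifest = write_cohort(records, tmp_path)
        entries = build_stacks_from_manifest(manifest, side=24, margin=2)
        assert len(entries) == 4
        by_id = {e[0]: e for e in entries}
        for rec in records:
            lesion_id, label, stacks = by_id[rec.lesion_id]
            assert label == rec.label
            assert (CT in stacks) == (rec.ct_stack is not None)
            assert (MRI in stacks) == (rec.mri_stack is not None)
            for stack in stacks.values():
                assert stack.side == 24
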