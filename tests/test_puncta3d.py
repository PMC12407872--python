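"""3D axon surfaces, skeleton lengths, blob segmentation, density and rotation null."""

import numpy as np
import pytest

from axsite import puncta3d as p3
from axsite import synthetic_data as sd


def _tube_mask(shape, radius_vox, axis="x"):
    """Axis-aligned solid tube through the volume center."""
    z, y, x = np.indices(shape)
    cz, cy, cx = [(s - 1) / 2 for s in shape]
    if axis == "x":
        d2 = (z - cz) ** 2 + (y - cy) ** 2
        return d2 <= radius_vox**2
    raise ValueError(axis)


class TestSegmentAxonSurface:
    def test_bright_tube_recovered(self):
        """One component covering >= 90% of the true tube voxels at SNR >= 10."""
        for seed in (0, 1, 2):
            cfg = sd.PunctaSimConfig3D(seed=seed, axon_count=1, snr=10.0)
            vol, gt = sd.simulate_axon_volume(cfg)
            surf = p3.segment_axon_surface(vol.channels["axonA"], cfg.voxel_size_um)
            true = gt.true_axon_masks["axonA"]
            assert surf.n_components == 1
            assert (surf.mask & true).sum() / true.sum() >= 0.90
            # outside-mask intensities zeroed
            assert np.all(surf.masked_channel[~surf.mask] == 0)

    def test_min_voxel_filter(self):
        """A connected component below min_voxels is removed."""
        cfg = sd.PunctaSimConfig3D(seed=0, axon_count=1)
        vol, _ = sd.simulate_axon_volume(cfg)
        ref = p3.segment_axon_surface(vol.channels["axonA"], cfg.voxel_size_um, min_voxels=1)
        from scipy.ndimage import label

        lab, n = label(ref.mask, structure=np.ones((3, 3, 3), int))
        sizes = sorted(np.bincount(lab.ravel())[1:])
        biggest = sizes[-1]
        cut = p3.segment_axon_surface(
            vol.channels["axonA"], cfg.voxel_size_um, min_voxels=biggest + 1
        )
        assert not cut.mask.any()

    def test_constant_volume_gives_empty_surface(self):
        surf = p3.segment_axon_surface(np.full((8, 32, 32), 3.0), (0.2, 0.05, 0.05))
        assert not surf.mask.any()
        assert surf.n_components == 0


class TestAxonLength:
    def test_straight_tube_length(self):
        """100-voxel straight tube at 0.5 um/voxel skeletonizes to ~49.5 um."""
        mask = np.zeros((20, 20, 110), dtype=bool)
        z, y = np.mgrid[:20, :20]
        sel = (z - 10) ** 2 + (y - 10) ** 2 <= 9
        for x in range(5, 105):
            mask[:, :, x] |= sel
        surf = p3.AxonSurface(mask, mask.astype(float), (0.5, 0.5, 0.5), 1)
        assert p3.estimate_axon_length(surf) == pytest.approx(49.5, rel=0.05)

    def test_diagonal_tube_length(self):
        """The same tube along the xy diagonal keeps its physical length within 10%."""
        shape = (16, 80, 80)
        z, y, x = np.indices(shape).astype(float)
        # line y = x in the z = 8 plane; distance in voxel units (isotropic here)
        d2 = (z - 8.0) ** 2 + (y - x) ** 2 / 2.0
        along = (y + x) / 2.0
        mask = (d2 <= 9.0) & (along >= 6) & (along <= 74)
        surf = p3.AxonSurface(mask, mask.astype(float), (0.5, 0.5, 0.5), 1)
        true_len = (74 - 6) * np.sqrt(2) * 0.5
        assert p3.estimate_axon_length(surf) == pytest.approx(true_len, rel=0.10)

    def test_two_disjoint_tubes_add(self):
        mask = np.zeros((20, 40, 110), dtype=bool)
        z, y = np.mgrid[:20, :40]
        sel1 = (z - 10) ** 2 + (y - 10) ** 2 <= 9
        sel2 = (z - 10) ** 2 + (y - 30) ** 2 <= 9
        for x in range(5, 105):
            mask[:, :, x] |= sel1 | sel2
        surf = p3.AxonSurface(mask, mask.astype(float), (0.5, 0.5, 0.5), 2)
        single = np.zeros_like(mask)
        for x in range(5, 105):
            single[:, :, x] |= sel1
        s1 = p3.AxonSurface(single, single.astype(float), (0.5, 0.5, 0.5), 1)
        L1 = p3.estimate_axon_length(s1)
        assert p3.estimate_axon_length(surf) == pytest.approx(2 * L1, rel=1e-6)

    def test_empty_mask_rejected(self):
        surf = p3.AxonSurface(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4)), (1, 1, 1), 0)
        with pytest.raises(ValueError, match="empty"):
            p3.estimate_axon_length(surf)


class TestSegmentBlobs:
    VOX = (0.2, 0.05, 0.05)

    def _volume_with_blobs(self, centers_um, volume_um3=0.01, shape=(12, 64, 64), noise=0.0, seed=0):
        vol = np.zeros(shape)
        for c in centers_um:
            sd._render_blob(vol, self.VOX, np.asarray(c), sd._sigma_for_volume(volume_um3), 10.0)
        if noise:
            vol = vol + np.random.default_rng(seed).normal(0, noise, shape)
        return vol

    def test_two_blobs_at_300nm_are_split(self):
        vol = self._volume_with_blobs([(1.2, 1.6, 1.4), (1.2, 1.6, 1.7)], noise=1.0)
        blobs = p3.segment_blobs(vol, self.VOX)
        assert blobs.n == 2

    def test_oversized_blob_excluded_by_volume_filter(self):
        vol = self._volume_with_blobs([(1.2, 1.6, 1.6)], volume_um3=0.05, noise=1.0)
        blobs = p3.segment_blobs(vol, self.VOX)
        assert blobs.n == 0

    def test_empty_channel_gives_empty_blobset(self):
        blobs = p3.segment_blobs(np.zeros((8, 32, 32)), self.VOX)
        assert blobs.n == 0
        assert blobs.labels.max() == 0


class TestAssignAndDensity:
    def test_density_is_count_over_length(self):
        labels = np.zeros((6, 20, 20), dtype=np.int32)
        labels[2, 5, 5] = 1
        labels[2, 10, 10] = 2
        import pandas as pd

        blobs = p3.BlobSet(
            labels=labels,
            voxel_size_um=(0.5, 0.5, 0.5),
            table=pd.DataFrame(
                {"blob": [1, 2], "volume_um3": [0.01, 0.02], "quality": [5.0, 6.0],
                 "n_voxels": [1, 1], "z_um": [1, 1], "y_um": [2, 5], "x_um": [2, 5]}
            ),
        )
        mask = np.zeros((6, 20, 20), bool)
        mask[1:4, 3:13, 3:13] = True
        surf = p3.AxonSurface(mask, mask.astype(float), (0.5, 0.5, 0.5), 1)
        surf.skeleton_length_um = 20.0
        res = p3.assign_and_density(blobs, {"axonA": surf})["axonA"]
        assert res.n_blobs == 2
        assert res.density_per_um == pytest.approx(0.1)
        assert res.density_per_um * res.axon_length_um == res.n_blobs
        assert res.mean_blob_volume_um3 == pytest.approx(0.015)

    def test_overlap_ratio_thresholding(self):
        """A half-inside blob is dropped at r_min=1.0 and kept at r_min=0.4."""
        labels = np.zeros((4, 10, 10), dtype=np.int32)
        labels[1, 4, 2:6] = 1  # 4 voxels, 2 inside the mask below
        import pandas as pd

        blobs = p3.BlobSet(
            labels=labels,
            voxel_size_um=(0.5, 0.5, 0.5),
            table=pd.DataFrame(
                {"blob": [1], "volume_um3": [0.01], "quality": [5.0],
                 "n_voxels": [4], "z_um": [0.75], "y_um": [2.25], "x_um": [2.0]}
            ),
        )
        mask = np.zeros((4, 10, 10), bool)
        mask[:, :, 4:]= True
        surf = p3.AxonSurface(mask, mask.astype(float), (0.5, 0.5, 0.5), 1)
        surf.skeleton_length_um = 10.0
        strict = p3.assign_and_density(blobs, {"axonA": surf}, r_min=1.0)["axonA"]
        loose = p3.assign_and_density(blobs, {"axonA": surf}, r_min=0.4)["axonA"]
        assert strict.n_blobs == 0
        assert loose.n_blobs == 1

    def test_fully_inside_blob_assigned_at_any_rmin(self):
        labels = np.zeros((4, 10, 10), dtype=np.int32)
        labels[1, 4, 6:8] = 1
        import pandas as pd

        blobs = p3.BlobSet(
            labels=labels, voxel_size_um=(0.5, 0.5, 0.5),
            table=pd.DataFrame({"blob": [1], "volume_um3": [0.01], "quality": [5.0],
                                "n_voxels": [2], "z_um": [0.75], "y_um": [2.25], "x_um": [3.5]}),
        )
        mask = np.zeros((4, 10, 10), bool)
        mask[:, :, 4:] = True
        surf = p3.AxonSurface(mask, mask.astype(float), (0.5, 0.5, 0.5), 1)
        surf.skeleton_length_um = 10.0
        assert p3.assign_and_density(blobs, {"a": surf}, r_min=1.0)["a"].n_blobs == 1

    def test_empty_surface_reports_missing(self):
        import pandas as pd

        blobs = p3.BlobSet(labels=np.zeros((4, 8, 8), np.int32), voxel_size_um=(0.5, 0.5, 0.5),
                           table=pd.DataFrame(columns=["blob", "volume_um3", "quality", "n_voxels", "z_um", "y_um", "x_um"]))
        surf = p3.AxonSurface(np.zeros((4, 8, 8), bool), np.zeros((4, 8, 8)), (0.5, 0.5, 0.5), 0)
        res = p3.assign_and_density(blobs, {"a": surf})["a"]
        assert res.density_per_um is None
        assert res.axon_length_um is None


class TestRotationNull:
    def test_rotation_is_an_involution(self):
        cfg = sd.PunctaSimConfig3D(seed=4, axon_count=1, shape_vox=(12, 128, 128), axon_length_um=5.0)
        vol, _ = sd.simulate_axon_volume(cfg)
        p = vol.channels["puncta"]
        np.testing.assert_array_equal(p3.rotate_puncta_180(p3.rotate_puncta_180(p)), p)

    def test_double_rotation_restores_densities(self):
        cfg = sd.PunctaSimConfig3D(seed=4, axon_count=1, shape_vox=(12, 128, 128), axon_length_um=5.0)
        vol, _ = sd.simulate_axon_volume(cfg)
        orig, _ = p3.rotation_null(vol, axon_channels=("axonA",))
        twice = sd.LabeledVolume3D(
            channels={"axonA": vol.channels["axonA"],
                      "puncta": p3.rotate_puncta_180(p3.rotate_puncta_180(vol.channels["puncta"]))},
            voxel_size_um=vol.voxel_size_um,
        )
        again, _ = p3.rotation_null(twice, axon_channels=("axonA",))
        assert orig["axonA"].density_per_um == again["axonA"].density_per_um
        assert orig["axonA"].n_blobs == again["axonA"].n_blobs

    def test_off_center_axon_loses_density_under_rotation(self):
        cfg = sd.PunctaSimConfig3D(seed=31, axon_count=1, off_axon_puncta_per_um3=0.0)
        vol, _ = sd.simulate_axon_volume(cfg)
        orig, rot = p3.rotation_null(vol, axon_channels=("axonA",))
        assert rot["axonA"].density_per_um < orig["axonA"].density_per_um


class TestPipelineInvariants:
    def test_translation_equivariance(self):
        """Shifting all channels by the same voxel offset barely changes density."""
        cfg = sd.PunctaSimConfig3D(seed=12, axon_count=1)
        vol, _ = sd.simulate_axon_volume(cfg)
        res0 = p3.analyze_volume(vol, axon_channels=("axonA",))["axonA"]
        shifted = sd.LabeledVolume3D(
            channels={n: np.roll(c, (0, 3, 4), axis=(0, 1, 2)) for n, c in vol.channels.items()},
            voxel_size_um=vol.voxel_size_um,
        )
        res1 = p3.analyze_volume(shifted, axon_channels=("axonA",))["axonA"]
        assert res1.n_blobs == res0.n_blobs
        assert res1.density_per_um == pytest.approx(res0.density_per_um, rel=0.01)

    def test_genotype_effect_detectable(self):
        """A 0.7x on-axon density reduction is detected by a pooled t-test."""
        from axsite import stats as axs

        dens = {"A": [], "B": []}
        for i in range(5):
            for grp, d in (("A", 0.5), ("B", 0.35)):
                cfg = sd.PunctaSimConfig3D(
                    seed=500 + i * 2 + (grp == "B"), axon_count=1,
                    puncta_density_per_um=d, off_axon_puncta_per_um3=0.0,
                )
                vol, _ = sd.simulate_axon_volume(cfg)
                res = p3.analyze_volume(vol, axon_channels=("axonA",))["axonA"]
                dens[grp].append(res.density_per_um)
        r = axs.t_test(dens["A"], dens["B"], "pooled")
        assert np.mean(dens["B"]) < np.mean(dens["A"])
        assert r.p < 0.05
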