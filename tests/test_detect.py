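"""Detection and sub-pixel fitting against analytic and rendered fixtures."""

import numpy as np
import pandas as pd
import pytest

from silencescope import (ImageStack, subtract_background, detect_candidates,
                          fit_spot_3d, filter_spots, detect_spots)
from silencescope.detect import Spot

VX, VZ = 107.5, 200.0


def _render_one(center_nm, amplitude=100.0, sigma_xy=130.0, sigma_z=300.0,
                shape=(11, 33, 33), offset=0.0):
    """Analytic anisotropic Gaussian sampled at voxel centers."""
    zz, yy, xx = np.meshgrid((np.arange(shape[0]) + 0.5) * VZ,
                             (np.arange(shape[1]) + 0.5) * VX,
                             (np.arange(shape[2]) + 0.5) * VX, indexing="ij")
    cz, cy, cx = center_nm
    img = amplitude * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_xy ** 2)
                               + (zz - cz) ** 2 / (2 * sigma_z ** 2))) + offset
    return ImageStack(img, channel_name="mrna")


class TestSubtractBackground:
    def test_constant_image_becomes_zero(self):
        out = subtract_background(ImageStack(np.full((5, 32, 32), 7.0)))
        assert np.allclose(out.voxels, 0.0)

    def test_spot_on_offset_preserved_offset_removed(self):
        center = (5.5 * VZ, 16.5 * VX, 16.5 * VX)
        stack = _render_one(center, amplitude=100.0, offset=50.0)
        out = subtract_background(stack)
        peak = out.voxels.max()
        assert abs(peak / 100.0 - 1.0) < 0.05
        corner = out.voxels[0, 0, 0]
        assert corner < 5.0

    def test_pure_gradient_mostly_removed(self):
        grad = np.tile(np.linspace(0, 100, 64)[None, None, :], (5, 64, 1))
        out = subtract_background(ImageStack(grad))
        # residual structure well below the gradient range (edges excepted)
        assert out.voxels[:, :, 8:-8].max() < 5.0


class TestDetectCandidates:
    def test_blank_image_yields_nothing(self):
        assert len(detect_candidates(ImageStack(np.zeros((5, 32, 32))))) == 0

    def test_single_spot_at_snr10_found_once(self, rng):
        center = (5.2 * VZ, 16.7 * VX, 15.9 * VX)
        stack = _render_one(center, amplitude=50.0)
        noisy = ImageStack(np.clip(stack.voxels + rng.normal(0, 5.0, stack.shape), 0, None))
        cands = detect_candidates(noisy)
        assert len(cands) == 1
        assert np.all(np.abs(cands[0] - np.array([5.2, 16.7, 15.9])) <= 1.0)

    def test_two_separated_spots_found(self):
        a = _render_one((5.5 * VZ, 10.5 * VX, 10.5 * VX))
        b = _render_one((5.5 * VZ, 20.5 * VX, 20.5 * VX))
        stack = ImageStack(a.voxels + b.voxels)
        assert len(detect_candidates(stack)) == 2


class TestFitSpot3D:
    @pytest.mark.parametrize("frac", [(0.5, 0.5, 0.5), (0.23, 0.71, 0.38)])
    def test_subpixel_round_trip(self, frac):
        center = ((5 + frac[0]) * VZ, (16 + frac[1]) * VX, (16 + frac[2]) * VX)
        stack = _render_one(center, amplitude=200.0)
        spot = fit_spot_3d(stack, (5, 16, 16))
        assert spot.valid
        err_vox = np.abs(spot.position_nm - center) / np.array([VZ, VX, VX])
        assert np.all(err_vox < 0.02)

    def test_integrated_intensity_matches_closed_form(self):
        A, sxy, sz = 1000.0, 150.0, 300.0
        center = (5.5 * VZ, 16.5 * VX, 16.5 * VX)
        stack = _render_one(center, amplitude=A, sigma_xy=sxy, sigma_z=sz)
        spot = fit_spot_3d(stack, (5, 16, 16))
        expected = A * (2 * np.pi) ** 1.5 * sxy ** 2 * sz / (VX * VX * VZ)
        assert abs(spot.integrated_intensity / expected - 1.0) < 0.01
        # and the voxel sum agrees with the same closed form
        assert abs(stack.voxels.sum() / expected - 1.0) < 0.01

    def test_intensity_linearity(self):
        center = (5.3 * VZ, 16.2 * VX, 16.8 * VX)
        i1 = fit_spot_3d(_render_one(center, amplitude=100.0), (5, 16, 16))
        i2 = fit_spot_3d(_render_one(center, amplitude=200.0), (5, 16, 16))
        assert abs(i2.integrated_intensity / i1.integrated_intensity - 2.0) < 0.04

    def test_window_shrinks_at_boundary(self):
        center = (0.5 * VZ, 1.5 * VX, 1.5 * VX)
        stack = _render_one(center, amplitude=100.0)
        spot = fit_spot_3d(stack, (0, 1, 1))
        assert np.all(np.isfinite(spot.position_nm))


class TestFilterSpots:
    def _spot(self, pos_vox, intensity, valid=True, residual=0.1):
        pos = np.asarray(pos_vox, float) * np.array([VZ, VX, VX])
        return Spot(channel="mrna", position_nm=pos, amplitude=intensity,
                    integrated_intensity=intensity, sigma_xy_nm=130.0,
                    sigma_z_nm=300.0, background=0.0, residual=residual,
                    valid=valid)

    def test_empty_input_gives_empty_table(self):
        assert len(filter_spots([])) == 0

    def test_duplicate_fits_keep_the_brighter(self):
        spots = [self._spot((5, 10, 10), 100.0), self._spot((5, 10.4, 10.2), 300.0)]
        out = filter_spots(spots)
        assert len(out) == 1
        assert out.integrated_intensity.iloc[0] == 300.0

    def test_invalid_and_poor_fits_dropped(self):
        spots = [self._spot((5, 10, 10), 100.0, valid=False),
                 self._spot((5, 20, 20), 100.0, residual=0.9),
                 self._spot((5, 30, 30), 100.0)]
        out = filter_spots(spots)
        assert len(out) == 1


class TestDetectSpotsEndToEnd:
    def test_rendered_field_f1_and_localization(self, rng):
        # spot brightness lognormal around SNR ~15, floored at SNR ≥ 5
        from silencescope import SimulationConfig, render_field, CellGeometry
        cfg = SimulationConfig(design="translation", n_cells=1, seed=5,
                               field_shape=(15, 256, 256))
        n = 60
        pos = np.column_stack([rng.uniform(2, 13, n) * VZ,
                               rng.uniform(10, 246, n) * VX,
                               rng.uniform(10, 246, n) * VX])
        inten = np.clip(np.exp(rng.normal(0.0, 0.3, n)), 0.35, None)
        truth = pd.DataFrame({
            "spot_id": np.arange(n), "cell_id": 0, "species": "reporter_mRNA",
            "z_nm": pos[:, 0], "y_nm": pos[:, 1], "x_nm": pos[:, 2],
            "intensity": inten, "compartment": "cytoplasmic",
            "linked_mrna_id": np.nan, "ribosome_count": np.nan,
            "translated": False, "risc_bound": False})
        geom = CellGeometry(cell_id=0, field_shape_yx=(256, 256),
                            center_px=(128.0, 128.0),
                            cell_radii_px=cfg.cell_radii_px,
                            nucleus_radii_px=cfg.nucleus_radii_px)
        stacks = render_field(truth, [geom], cfg, channels=("mrna",))
        det = detect_spots(stacks["mrna"])
        from scipy.spatial import cKDTree
        scale = np.array([VZ, VX, VX])
        d, _ = cKDTree(det[["z_nm", "y_nm", "x_nm"]].to_numpy() / scale
                       ).query(pos / scale, k=1)
        tp = int((d <= 1.0).sum())
        precision = tp / len(det)
        recall = tp / n
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.95

    def test_noiseless_localization_under_5nm_lateral(self, rng):
        from silencescope import SimulationConfig, render_field, CellGeometry
        cfg = SimulationConfig(design="translation", n_cells=1, seed=5,
                               field_shape=(11, 96, 96), shot_scale=0.0,
                               read_noise_sd=0.0, background_level=0.0)
        n = 12
        pos = np.column_stack([rng.uniform(3, 8, n) * VZ,
                               rng.uniform(10, 86, n) * VX,
                               rng.uniform(10, 86, n) * VX])
        # keep spots isolated so single-Gaussian fits are unbiased
        keep = np.ones(n, bool)
        for i in range(n):
            for j in range(i):
                if keep[j] and np.linalg.norm((pos[i] - pos[j]) / np.array([VZ, VX, VX])) < 8:
                    keep[i] = False
        pos = pos[keep]
        truth = pd.DataFrame({
            "spot_id": np.arange(len(pos)), "cell_id": 0, "species": "reporter_mRNA",
            "z_nm": pos[:, 0], "y_nm": pos[:, 1], "x_nm": pos[:, 2],
            "intensity": 1.0, "compartment": "cytoplasmic",
            "linked_mrna_id": np.nan, "ribosome_count": np.nan,
            "translated": False, "risc_bound": False})
        geom = CellGeometry(cell_id=0, field_shape_yx=(96, 96), center_px=(48.0, 48.0),
                            cell_radii_px=(40.0, 38.0), nucleus_radii_px=(15.0, 14.0))
        stacks = render_field(truth, [geom], cfg, channels=("mrna",))
        det = detect_spots(stacks["mrna"], subtract_bg=False)
        from scipy.spatial import cKDTree
        scale = np.array([VZ, VX, VX])
        d, j = cKDTree(det[["z_nm", "y_nm", "x_nm"]].to_numpy() / scale
                       ).query(pos / scale, k=1)
        assert (d <= 1.0).all()
        err = det[["z_nm", "y_nm", "x_nm"]].to_numpy()[j] - pos
        assert np.abs(err[:, 1:]).mean() < 5.0
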