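"""Shared fixtures: small, seeded synthetic configurations.

All fixtures are generated programmatically; nothing is loaded from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from silencescope import SimulationConfig, CellGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_render_config():
    """Two small cells in a 15×256×256 field, suitable for rendering tests."""
    return SimulationConfig(
        design="translation", n_cells=2, seed=7,
        field_shape=(15, 256, 256), cell_radii_um=(5.0, 4.5),
        nucleus_radii_um=(2.2, 2.0), n_free_suntag=40, mrna_mean=25)


@pytest.fixture
def noiseless_render_config():
    """Single-cell render config with all noise sources off."""
    return SimulationConfig(
        design="translation", n_cells=1, seed=7,
        field_shape=(15, 128, 128), cell_radii_um=(5.0, 4.5),
        nucleus_radii_um=(2.2, 2.0), n_free_suntag=10, mrna_mean=10,
        shot_scale=0.0, read_noise_sd=0.0, background_level=0.0)


@pytest.fixture
def clean_spots_config():
    """Spots-only triple-design config with zero measurement noise/drift."""
    return SimulationConfig(
        design="triple", condition="miR21", n_cells=10, seed=3,
        loc_noise_nm=0.0, intensity_meas_cv=0.0)


def single_cell_geometry(field=(256, 256), center=(128.0, 128.0),
                         cell_radii=(90.0, 80.0), nucleus_radii=(40.0, 35.0)):
    return CellGeometry(cell_id=0, field_shape_yx=field, center_px=center,
                        cell_radii_px=cell_radii, nucleus_radii_px=nucleus_radii)


def greedy_match_oracle(mpos, ppos, gate):
    """Brute-force reference for greedy ascending-distance one-to-one matching,
    computed over the full distance matrix (returns row-index pairs)."""
    mpos = np.asarray(mpos, float)
    ppos = np.asarray(ppos, float)
    if len(mpos) == 0 or len(ppos) == 0:
        return []
    d = np.linalg.norm(mpos[:, None, :] - ppos[None, :, :], axis=2)
    ii, jj = np.nonzero(d <= gate)
    order = np.lexsort((jj, ii, d[ii, jj]))
    used_m, used_p, pairs = set(), set(), []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i not in used_m and j not in used_p:
            used_m.add(i)
            used_p.add(j)
            pairs.append((i, j, float(d[i, j])))
    return pairs


def spot_table(positions_nm, intensities=None, channel="mrna",
               compartment="cytoplasmic", cell_id=0):
    """Hand-build a minimal spot table from an (n, 3) position array."""
    pos = np.atleast_2d(np.asarray(positions_nm, dtype=float))
    n = len(pos)
    inten = np.ones(n) if intensities is None else np.asarray(intensities, float)
    return pd.DataFrame({
        "spot_id": np.arange(n), "channel": channel,
        "z_nm": pos[:, 0], "y_nm": pos[:, 1], "x_nm": pos[:, 2],
        "amplitude": inten, "integrated_intensity": inten,
        "sigma_xy_nm": 130.0, "sigma_z_nm": 300.0,
        "background": 0.0, "residual": 0.0,
        "cell_id": cell_id, "compartment": compartment,
    })
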