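"""Generator contracts: kinetic limits, determinism, noise calibration."""

import numpy as np
import pandas as pd
import pytest

from silencescope import (SimulationConfig, sample_cell_population,
                          emit_spot_tables, render_field)


def _cfg(**kw):
    base = dict(design="triple", n_cells=5, seed=42)
    base.update(kw)
    return SimulationConfig(**base)


class TestSampleCellPopulation:
    def test_zero_export_rate_keeps_all_mrnas_nuclear(self):
        _, truth = sample_cell_population(_cfg(k_export=0.0, time_min=60.0))
        mrnas = truth[truth.species == "reporter_mRNA"]
        assert len(mrnas) > 0
        assert (mrnas.compartment == "nuclear").all()

    def test_certain_binding_links_every_cytoplasmic_mrna_to_ago(self):
        _, truth = sample_cell_population(_cfg(p_risc_bind=1.0, time_min=0.0))
        cyto = truth[(truth.species == "reporter_mRNA")
                     & (truth.compartment == "cytoplasmic")]
        ago_on = truth[truth.species == "ago_on_mRNA"]
        assert set(ago_on.linked_mrna_id.astype(int)) == set(cyto.spot_id)

    def test_risc_bound_fraction_matches_binomial(self):
        # ~2000 cytoplasmic mRNAs pooled over cells; binomial(n, 0.5) oracle
        cfg = _cfg(n_cells=50, p_risc_bind=0.5, k_export=50.0, seed=9)
        _, truth = sample_cell_population(cfg)
        cyto = truth[(truth.species == "reporter_mRNA")
                     & (truth.compartment == "cytoplasmic")]
        n = len(cyto)
        assert n > 1500
        frac = cyto.risc_bound.mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_on_mrna_partners_sit_inside_the_gates(self):
        _, truth = sample_cell_population(_cfg(p_risc_bind=1.0, n_cells=10))
        mrna_pos = truth[truth.species == "reporter_mRNA"].set_index("spot_id")
        for species, gate in (("suntag_on_mRNA", 500.0), ("ago_on_mRNA", 250.0)):
            part = truth[truth.species == species]
            assert len(part) > 0
            linked = mrna_pos.loc[part.linked_mrna_id.astype(int)]
            d = np.linalg.norm(
                part[["z_nm", "y_nm", "x_nm"]].to_numpy()
                - linked[["z_nm", "y_nm", "x_nm"]].to_numpy(), axis=1)
            assert d.max() <= gate - 50.0  # margin inside the gate

    def test_class_counts_conserve_total_reporter_count(self):
        _, truth = sample_cell_population(_cfg(n_cells=10))
        mrnas = truth[truth.species == "reporter_mRNA"]
        by_class = mrnas.groupby(["compartment", "translated", "risc_bound"]).size()
        assert by_class.sum() == len(mrnas)

    def test_identical_seed_and_config_is_bit_identical(self):
        g1, t1 = sample_cell_population(_cfg())
        g2, t2 = sample_cell_population(_cfg())
        pd.testing.assert_frame_equal(t1, t2)
        assert all(a.center_px == b.center_px for a, b in zip(g1, g2))

    def test_different_seed_changes_realization(self):
        _, t1 = sample_cell_population(_cfg(seed=1))
        _, t2 = sample_cell_population(_cfg(seed=2))
        assert not t1[["z_nm"]].equals(t2[["z_nm"]])

    def test_copy_number_distribution_matches_published_summaries(self):
        cfg = _cfg(n_cells=300, seed=5, design="translation", n_free_suntag=0,
                   field_shape=(25, 4800, 3200))
        _, truth = sample_cell_population(cfg)
        counts = truth[truth.species == "reporter_mRNA"].groupby("cell_id").size()
        assert counts.max() <= 100
        assert 32 <= counts.median() <= 48    # median ~40 mRNAs per cell

    def test_decay_halves_cytoplasmic_reporters_only_late_and_only_mir21(self):
        kw = dict(design="decay", n_cells=80, k_export=50.0, seed=13,
                  decay_survival=0.5, field_shape=(25, 2500, 2000))
        out = {}
        for cond, t in (("miR21", 30.0), ("miR21", 60.0), ("mutant", 60.0)):
            _, truth = sample_cell_population(_cfg(condition=cond, time_min=t, **kw))
            sun = (truth.species == "reporter_mRNA").sum()
            fluc = (truth.species == "fluc_mRNA").sum()
            out[(cond, t)] = sun / fluc
        assert out[("miR21", 30.0)] > 0.85
        assert out[("mutant", 60.0)] > 0.85
        assert 0.4 < out[("miR21", 60.0)] < 0.6

    def test_nonphysical_geometry_rejected(self):
        with pytest.raises(ValueError, match="nucleus"):
            _cfg(nucleus_radii_um=(13.0, 11.0))
        with pytest.raises(ValueError):
            _cfg(p_risc_bind=1.5)
        with pytest.raises(ValueError, match="too small"):
            sample_cell_population(_cfg(field_shape=(25, 128, 128), n_cells=50))


class TestEmitSpotTables:
    def test_zero_noise_reproduces_truth_positions(self):
        cfg = _cfg(loc_noise_nm=0.0, intensity_meas_cv=0.0)
        _, truth = sample_cell_population(cfg)
        tables = emit_spot_tables(truth, cfg)
        mrna_truth = truth[truth.species == "reporter_mRNA"]
        np.testing.assert_allclose(
            tables["mrna"][["z_nm", "y_nm", "x_nm"]].to_numpy(),
            mrna_truth[["z_nm", "y_nm", "x_nm"]].to_numpy())

    def test_channel_drift_shifts_mean_displacement(self):
        drift = (50.0, -30.0, 20.0)
        cfg = _cfg(loc_noise_nm=0.0, drift_nm={"ago": drift})
        _, truth = sample_cell_population(cfg)
        tables = emit_spot_tables(truth, cfg)
        ago_truth = truth[truth.species.str.startswith("ago")]
        disp = (tables["ago"][["z_nm", "y_nm", "x_nm"]].to_numpy()
                - ago_truth[["z_nm", "y_nm", "x_nm"]].to_numpy())
        np.testing.assert_allclose(disp.mean(axis=0), drift, atol=1e-9)

    def test_localization_noise_rms_is_calibrated(self):
        # per-axis σ = 30 nm ⇒ 3D RMS error 30·√3, Monte-Carlo over >1000 spots
        cfg = _cfg(loc_noise_nm=30.0, n_cells=30, seed=21)
        _, truth = sample_cell_population(cfg)
        tables = emit_spot_tables(truth, cfg)
        ago_truth = truth[truth.species.str.startswith("ago")]
        err = (tables["ago"][["z_nm", "y_nm", "x_nm"]].to_numpy()
               - ago_truth[["z_nm", "y_nm", "x_nm"]].to_numpy())
        rms = np.sqrt((np.linalg.norm(err, axis=1) ** 2).mean())
        assert len(err) > 1000
        assert abs(rms - 30.0 * np.sqrt(3)) < 0.1 * 30.0 * np.sqrt(3)

    def test_output_schema_matches_detector_output(self):
        from silencescope.types import SPOT_COLUMNS
        cfg = _cfg()
        _, truth = sample_cell_population(cfg)
        tables = emit_spot_tables(truth, cfg)
        for table in tables.values():
            assert list(table.columns)[: len(SPOT_COLUMNS)] == SPOT_COLUMNS


class TestRenderField:
    def test_single_spot_argmax_at_true_position(self, noiseless_render_config):
        cfg = noiseless_render_config
        geoms, truth = sample_cell_population(cfg)
        truth = truth[truth.species == "reporter_mRNA"].iloc[:1]
        stacks = render_field(truth, geoms, cfg, channels=("mrna",))
        vox = np.unravel_index(np.argmax(stacks["mrna"].voxels),
                               stacks["mrna"].shape)
        true_vox = truth[["z_nm", "y_nm", "x_nm"]].to_numpy()[0] / [200, 107.5, 107.5] - 0.5
        assert np.all(np.abs(np.array(vox) - true_vox) <= 1.0)

    def test_noiseless_integrated_signal_equals_intensity(self, noiseless_render_config):
        cfg = noiseless_render_config
        geoms, truth = sample_cell_population(cfg)
        truth = truth[truth.species == "reporter_mRNA"].iloc[:1]
        stacks = render_field(truth, geoms, cfg, channels=("mrna",))
        total = stacks["mrna"].voxels.sum()
        expected = truth.intensity.iloc[0] * cfg.render_intensity_scale
        assert abs(total / expected - 1.0) < 0.01

    def test_seed_changes_noise_not_truth(self, small_render_config):
        cfg1 = small_render_config
        d = cfg1.to_dict()
        d["seed"] = cfg1.seed  # identical truth seed; vary only via from_dict
        geoms, truth = sample_cell_population(cfg1)
        s1 = render_field(truth, geoms, cfg1, channels=("mrna",))
        d2 = cfg1.to_dict()
        d2["seed"] = cfg1.seed + 1
        cfg2 = SimulationConfig.from_dict(d2)
        s2 = render_field(truth, geoms, cfg2, channels=("mrna",))
        assert not np.array_equal(s1["mrna"].voxels, s2["mrna"].voxels)

    def test_out_of_field_spot_warns_and_clips(self, noiseless_render_config):
        cfg = noiseless_render_config
        geoms, _ = sample_cell_population(cfg)
        truth = pd.DataFrame({
            "spot_id": [0], "cell_id": [0], "species": ["reporter_mRNA"],
            "z_nm": [1e6], "y_nm": [1e6], "x_nm": [1e6], "intensity": [1.0],
            "compartment": ["cytoplasmic"], "linked_mrna_id": [np.nan],
            "ribosome_count": [np.nan], "translated": [False], "risc_bound": [False]})
        with pytest.warns(UserWarning, match="outside the field"):
            stacks = render_field(truth, geoms, cfg, channels=("mrna",))
        assert stacks["mrna"].voxels.sum() == 0.0


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path):
        cfg = _cfg(drift_nm={"ago": (50.0, -30.0, 20.0)})
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.to_dict() == cfg.to_dict()
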