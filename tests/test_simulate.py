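"""Tests of the synthetic experiment generator: Brownian statistics,
photophysics, observation model and fiducial sets."""

import numpy as np
import pandas as pd
import pytest

from dimertrack import (
    AffineTransform2D,
    SimulationConfig,
    apply_observation_model,
    heterodimer_condition,
    make_fiducial_set,
    simulate_receptor_truth,
)
from dimertrack.errors import ConfigurationError, IdentifiabilityError

from conftest import noiseless_overrides


def frozen_config(**kw):
    base = dict(
        seed=0, density=0.05, complex_mix={"monomer_a": 1.0},
        immobile_fraction=0.0, bond_jitter_sigma=0.0, loc_error_sigma=0.0,
    )
    base.update(noiseless_overrides())
    base.update(kw)
    return SimulationConfig(**base)


class TestReceptorTruth:
    def test_zero_diffusion_zero_jitter_positions_constant(self):
        cfg = frozen_config(d_free=0.0, d_dimer=0.0, d_oligomer=0.0)
        truth = simulate_receptor_truth(cfg)
        assert truth.n_particles > 0
        assert np.all(truth.positions == truth.positions[:, :1, :])

    def test_brownian_step_variance_matches_closed_form(self):
        # ~10^4 steps of free 2D diffusion: E[step²] = 4·D·Δt
        cfg = frozen_config(seed=3, field_size_um=100.0, density=70 / 1e4,
                            d_free=0.1)
        truth = simulate_receptor_truth(cfg)
        steps = np.diff(truth.positions, axis=1) / 1000.0  # µm
        sq = np.sum(steps**2, axis=-1).ravel()
        expected = 4 * 0.1 * cfg.frame_interval
        se = sq.std() / np.sqrt(sq.size)
        assert sq.size >= 10_000
        assert abs(sq.mean() - expected) < 3 * se

    def test_heterodimer_members_coincide_at_zero_jitter(self):
        cfg = frozen_config(complex_mix={"heterodimer_ab": 1.0}, density=0.02)
        truth = simulate_receptor_truth(cfg)
        for cid, grp in truth.particles.groupby("complex_id"):
            pos = truth.positions[grp["particle_id"].to_numpy()]
            assert np.allclose(pos[0], pos[1])

    def test_complex_members_move_rigidly(self):
        # member displacements equal the centre displacement up to bond jitter
        cfg = frozen_config(
            complex_mix={"heterodimer_ab": 1.0}, density=0.02,
            bond_jitter_sigma=5.0, d_dimer=0.07,
        )
        truth = simulate_receptor_truth(cfg)
        for cid, grp in truth.particles.groupby("complex_id"):
            pos = truth.positions[grp["particle_id"].to_numpy()]
            diff = np.diff(pos, axis=1)
            spread = np.abs(diff[0] - diff[1])
            # each axis difference is N(0, 2·jitter²) per frame; bound at 6 sd
            assert np.percentile(spread, 99) < 6 * 5.0 * np.sqrt(2)

    def test_immobile_class_does_not_move(self):
        cfg = frozen_config(immobile_fraction=1.0, d_free=0.2)
        truth = simulate_receptor_truth(cfg)
        assert set(truth.particles["mobility"]) == {"immobile"}
        assert np.all(truth.positions == truth.positions[:, :1, :])

    def test_positions_stay_in_field(self):
        cfg = frozen_config(field_size_um=2.0, density=5.0, d_free=0.3, seed=9)
        truth = simulate_receptor_truth(cfg)
        assert truth.positions.min() >= 0.0
        assert truth.positions.max() <= cfg.field_size_nm

    @pytest.mark.parametrize(
        "bad",
        [
            {"complex_mix": {"monomer_a": 0.5}},                   # sums to 0.5
            {"complex_mix": {"monomer_a": 1.5, "monomer_b": -0.5}},
            {"field_size_um": 0.0},
            {"frame_interval": -1.0},
            {"detect_prob": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            frozen_config(**bad).validate()


class TestObservationModel:
    def test_noiseless_identity_returns_true_positions(self):
        cfg = frozen_config(seed=5)
        truth = simulate_receptor_truth(cfg)
        locs_a, locs_b, id_map = apply_observation_model(truth, cfg)
        assert len(locs_b) == 0  # monomer-A only
        assert len(locs_a) == truth.n_particles * cfg.n_frames
        got = locs_a.sort_values(["frame", "x_nm"])[["x_nm", "y_nm"]].to_numpy()
        want = truth.positions.reshape(-1, 2)
        order = np.lexsort((want[:, 0],
                            np.tile(np.arange(cfg.n_frames), truth.n_particles)))
        assert np.allclose(got, want[order])

    def test_detect_prob_zero_gives_empty_tables(self):
        cfg = frozen_config(detect_prob=0.0)
        truth = simulate_receptor_truth(cfg)
        locs_a, locs_b, _ = apply_observation_model(truth, cfg)
        assert len(locs_a) == 0 and len(locs_b) == 0

    def test_bleaching_matches_truncated_geometric_mean(self):
        # mean emitting frames E[K] = (1 - (1-p)^n)/p for bleach hazard p
        cfg = frozen_config(seed=11, field_size_um=100.0, density=1e4 / 1e4,
                            bleach_prob=0.02, d_free=0.0)
        truth = simulate_receptor_truth(cfg)
        apply_observation_model(truth, cfg)
        k = truth.emitting.sum(axis=1)
        p, n = 0.02, cfg.n_frames
        expected = (1 - (1 - p) ** n) / p
        se = k.std() / np.sqrt(k.size)
        assert abs(k.mean() - expected) < 3 * se

    def test_chromatic_transform_applied_to_channel_b_only(self):
        t = AffineTransform2D.translation(120.0, -80.0)
        cfg = frozen_config(
            complex_mix={"heterodimer_ab": 1.0}, density=0.02,
            chromatic_transform=t,
        )
        truth = simulate_receptor_truth(cfg)
        locs_a, locs_b, _ = apply_observation_model(truth, cfg)
        a = locs_a.sort_values(["frame", "x_nm"])[["x_nm", "y_nm"]].to_numpy()
        b = locs_b.sort_values(["frame", "x_nm"])[["x_nm", "y_nm"]].to_numpy()
        # members coincide at zero jitter, so B = A + offset exactly
        assert np.allclose(b - a, [120.0, -80.0])

    def test_hexamer_intensity_is_sixfold_monomer(self):
        cfg = frozen_config(
            complex_mix={"monomer_b": 0.5, "hexamer_b6": 0.5}, density=0.1,
            intensity_cv=0.0, seed=2,
        )
        truth = simulate_receptor_truth(cfg)
        _, locs_b, id_map = apply_observation_model(truth, cfg)
        bmap = id_map[id_map["channel"] == "B"]
        inten = locs_b["intensity"].to_numpy()
        hexa = inten[bmap["complex_type"].to_numpy() == "hexamer_b6"]
        mono = inten[bmap["complex_type"].to_numpy() == "monomer_b"]
        assert np.allclose(hexa, 6 * cfg.photons_mean)
        assert np.allclose(mono, cfg.photons_mean)

    def test_identity_map_rows_align_with_tables(self):
        cfg = SimulationConfig(seed=8)
        truth = simulate_receptor_truth(cfg)
        locs_a, locs_b, id_map = apply_observation_model(truth, cfg)
        for channel, table in (("A", locs_a), ("B", locs_b)):
            sub = id_map[id_map["channel"] == channel]
            assert len(sub) == len(table)
            assert np.array_equal(
                sub["frame"].to_numpy(), table["frame"].to_numpy()
            )

    def test_determinism_same_seed_identical_outputs(self):
        cfg = SimulationConfig(seed=13)
        out1 = apply_observation_model(simulate_receptor_truth(cfg), cfg)
        out2 = apply_observation_model(simulate_receptor_truth(cfg), cfg)
        for a, b in zip(out1, out2):
            pd.testing.assert_frame_equal(a, b)


class TestFiducials:
    def test_identity_transform_zero_noise_tables_identical(self):
        fa, fb = make_fiducial_set(AffineTransform2D.identity(), 10, 0.0, seed=1)
        assert np.allclose(fa[["x_nm", "y_nm"]], fb[["x_nm", "y_nm"]])

    def test_pure_translation(self):
        t = AffineTransform2D.translation(100.0, -50.0)
        fa, fb = make_fiducial_set(t, 10, 0.0, seed=1)
        delta = fb[["x_nm", "y_nm"]].to_numpy() - fa[["x_nm", "y_nm"]].to_numpy()
        assert np.allclose(delta, [100.0, -50.0])

    def test_too_few_markers_rejected(self):
        with pytest.raises(IdentifiabilityError):
            make_fiducial_set(AffineTransform2D.identity(), 2, 0.0, seed=1)


class TestHeterodimerCondition:
    def test_particle_density_held_constant(self):
        # per-channel particle density = density · (mix_mono + mix_dimer)
        for p in (0.0, 0.25, 0.8):
            ov = heterodimer_condition(p, particle_density=0.12)
            mix = ov["complex_mix"]
            per_channel = ov["density"] * (mix["monomer_a"] + mix["heterodimer_ab"])
            assert per_channel == pytest.approx(0.12)
            assert sum(mix.values()) == pytest.approx(1.0)

    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValueError):
            heterodimer_condition(1.2)
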