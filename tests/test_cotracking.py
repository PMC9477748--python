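"""Two-colour co-localization, co-trajectory building and dimer calling."""

import numpy as np
import pandas as pd
import pytest

from dimertrack import (
    AffineTransform2D,
    DimerCallParams,
    SimulationConfig,
    Trajectory,
    analyze_cell,
    build_cotrajectories,
    call_dimers,
    colocalize_frame,
    colocalize_tables,
    simulate_cell,
)
from dimertrack.cotrack import MATCH_COLUMNS, relative_dimerization
from dimertrack.track import assignment_objective, filter_immobile, link_trajectories, tracks_to_table

from conftest import noiseless_overrides


class TestColocalizeFrame:
    def test_separation_beyond_cutoff_not_matched(self):
        assert colocalize_frame([[0.0, 0.0]], [[0.0, 150.0]], 100.0) == []

    def test_single_admissible_pair(self):
        a, b = np.array([[0.0, 0.0]]), np.array([[0.0, 50.0]])
        assert colocalize_frame(a, b, 100.0) == [(0, 0)]
        matches = colocalize_tables(
            pd.DataFrame({"frame": [0], "x_nm": [0.0], "y_nm": [0.0]}),
            pd.DataFrame({"frame": [0], "x_nm": [0.0], "y_nm": [50.0]}),
            100.0,
        )
        assert matches["separation_nm"].iloc[0] == pytest.approx(50.0)
        assert matches["mid_y_nm"].iloc[0] == pytest.approx(25.0)

    def test_competition_resolved_like_brute_force(self):
        # B at y=60 can pair with A1 (60 nm) or A2 (70 nm): nearest wins
        a = np.array([[0.0, 0.0], [0.0, 130.0]])
        b = np.array([[0.0, 60.0]])
        links = colocalize_frame(a, b, 100.0)
        assert links == [(0, 0)]
        both = [[(0, 0)], [(1, 0)]]
        costs = [assignment_objective(a, b, l, 100.0) for l in both]
        assert costs[0] == min(costs)


class TestCoTrajectories:
    def test_persistent_heterodimer_yields_one_full_cotrajectory(self):
        cfg = SimulationConfig(
            seed=1, density=1 / 400.0, complex_mix={"heterodimer_ab": 1.0},
            immobile_fraction=0.0, loc_error_sigma=10.0,
            **noiseless_overrides(),
        )
        sim = simulate_cell(cfg)
        matches = colocalize_tables(sim["locs_a"], sim["locs_b"], 100.0)
        cotrajs = build_cotrajectories(matches)
        assert len(cotrajs) == 1
        assert cotrajs[0].n_matched == 150

    def test_brief_encounter_not_called_dimer(self):
        # two monomers crossing: no >= 10-frame co-trajectory
        rows_a = pd.DataFrame(
            {"frame": range(30), "x_nm": np.linspace(0, 2900, 30), "y_nm": 0.0}
        )
        rows_b = pd.DataFrame(
            {"frame": range(30), "x_nm": np.linspace(2900, 0, 30), "y_nm": 50.0}
        )
        matches = colocalize_tables(rows_a, rows_b, 100.0)
        dimers = call_dimers(build_cotrajectories(matches))
        assert dimers == []

    def test_empty_match_stream_empty_output(self):
        assert build_cotrajectories(pd.DataFrame(columns=MATCH_COLUMNS)) == []

    def test_gap_frames_not_counted_in_n_matched(self):
        frames = [0, 1, 2, 3, 4, 6, 7, 8, 9, 10]  # frame 5 missing
        matches = pd.DataFrame(
            {
                "frame": frames,
                "a_x_nm": 0.0, "a_y_nm": 0.0, "b_x_nm": 0.0, "b_y_nm": 10.0,
                "separation_nm": 10.0, "mid_x_nm": 0.0, "mid_y_nm": 5.0,
                "a_intensity": 1.0, "b_intensity": 1.0, "a_traj": 0, "b_traj": 0,
            }
        )
        cotrajs = build_cotrajectories(matches)
        assert len(cotrajs) == 1
        assert cotrajs[0].n_matched == 10  # not 11 (lifetime)


class TestDimerCalls:
    def test_ten_frame_persistence_threshold(self):
        def cotraj_with(n):
            frames = np.arange(n)
            rec = pd.DataFrame(
                {
                    "frame": frames, "a_x_nm": 0.0, "a_y_nm": 0.0,
                    "b_x_nm": 0.0, "b_y_nm": 10.0, "separation_nm": 10.0,
                    "mid_x_nm": 0.0, "mid_y_nm": 5.0,
                    "a_intensity": 1.0, "b_intensity": 1.0,
                    "a_traj": 0, "b_traj": 0,
                }
            )
            from dimertrack import CoTrajectory

            return CoTrajectory(0, rec)

        cotrajs = [cotraj_with(12), cotraj_with(9), cotraj_with(10)]
        assert len(call_dimers(cotrajs)) == 2
        assert call_dimers([cotraj_with(9)]) == []
        assert call_dimers([]) == []


def _track(tid, n=20, channel="A"):
    return Trajectory(tid, channel, np.arange(n), np.zeros((n, 2)) + tid * 1000.0)


class TestRelativeDimerization:
    def test_no_dimers_gives_zero(self):
        a = [_track(i, 30) for i in range(30)]
        b = [_track(i, 30, "B") for i in range(40)]
        assert relative_dimerization([], a, b) == 0.0

    def test_fully_paired_population_saturates_at_one(self):
        cfg = SimulationConfig(
            seed=2, density=20 / 400.0, complex_mix={"heterodimer_ab": 1.0},
            immobile_fraction=0.0, loc_error_sigma=10.0,
            **noiseless_overrides(),
        )
        sim = simulate_cell(cfg)
        res, _ = analyze_cell(
            sim["locs_a"], sim["locs_b"], AffineTransform2D.identity(), seed=2
        )
        assert res.relative_dimerization == pytest.approx(1.0, abs=0.101)

    def test_missing_when_a_channel_has_no_tracks(self):
        a = [_track(0, 30)]
        assert relative_dimerization([], a, []) is None
        assert relative_dimerization([], [], []) is None

    def test_monotone_in_ground_truth_proportion(self):
        from dimertrack import heterodimer_condition
        from dimertrack.pipeline import run_recovery_experiment

        table = run_recovery_experiment(
            [heterodimer_condition(0.1), heterodimer_condition(0.3)],
            n_cells=3, seed=31,
        )
        est = table["dimer_fraction_mean"].to_numpy()
        assert est[1] > est[0]


class TestGeometricInvariance:
    def _fraction(self, locs_a, locs_b, cutoff=100.0):
        mob_a, _ = filter_immobile(link_trajectories(locs_a))
        mob_b, _ = filter_immobile(link_trajectories(locs_b))
        matches = colocalize_tables(
            tracks_to_table(mob_a), tracks_to_table(mob_b), cutoff
        )
        dimers = call_dimers(build_cotrajectories(matches))
        return relative_dimerization(dimers, mob_a, mob_b)

    def test_fraction_invariant_under_rotation_and_translation(self, hetero_cell):
        cfg, sim = hetero_cell
        base = self._fraction(sim["locs_a"], sim["locs_b"])
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([5000.0, -2000.0])

        def moved(locs):
            out = locs.copy()
            xy = out[["x_nm", "y_nm"]].to_numpy() @ rot.T + shift
            out["x_nm"], out["y_nm"] = xy[:, 0], xy[:, 1]
            return out

        assert self._fraction(moved(sim["locs_a"]), moved(sim["locs_b"])) == base

    def test_fraction_monotone_in_cutoff_and_zero_at_zero(self, hetero_cell):
        cfg, sim = hetero_cell
        fractions = [
            self._fraction(sim["locs_a"], sim["locs_b"], cutoff)
            for cutoff in (1e-9, 50.0, 100.0, 200.0)
        ]
        assert fractions[0] == 0.0
        assert all(f2 >= f1 for f1, f2 in zip(fractions, fractions[1:]))
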