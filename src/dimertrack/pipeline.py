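"""End-to-end orchestration: simulate → register → track → co-track →
quantify → report, as reproducible seeded runs.

A single global seed is expanded into independent per-cell substreams with
``numpy.random.SeedSequence(seed, spawn_key=(condition_index, cell_index))``
so cells are statistically independent but every run with the same
configuration and seed is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DimerCallParams, DynamicsParams, SimulationConfig, TrackingParams
from .cotrack import (
    build_cotrajectories,
    call_dimers,
    colocalize_tables,
    cotrajectories_to_table,
    count_dimer_pairs,
    qualifying_tracks,
    relative_dimerization,
)
from .dynamics import (
    compute_msd,
    fit_diffusion,
    mobility_fractions,
    monomer_reference_intensity,
    oligomer_fraction,
    pool_msd,
)
from .errors import AnalysisError, ConfigurationError
from .io import write_json, write_localizations
from .register import AffineTransform2D, apply_affine, estimate_affine
from .simulate import apply_observation_model, make_fiducial_set, simulate_receptor_truth
from .stats import CellResult, compile_report
from .track import filter_immobile, link_trajectories, tracks_to_table

logger = logging.getLogger("dimertrack")

__all__ = [
    "RunConfig",
    "simulate_cell",
    "analyze_cell",
    "run_pipeline",
    "run_recovery_experiment",
    "trace_dimer_complexes",
]

#: complex states counted as higher-order in ground-truth audits
HIGHER_ORDER_TYPES = frozenset({"ternary_aabb", "hexamer_b6"})


def trace_dimer_complexes(
    dimers, locs_a: pd.DataFrame, id_map: pd.DataFrame
) -> list[tuple[int, str]]:
    """Trace dimer co-trajectories back to their ground-truth complexes.

    Uses the simulator's identity map: each dimer's channel-A localizations
    (whose coordinates are unchanged by registration) are looked up by
    (frame, x, y) and the modal complex wins.  Returns one
    (complex_id, complex_type) per dimer; (-1, "false_positive") when no
    true-emitter localization participates.  Simulation audit only — real
    data has no identity map.
    """
    amap = id_map[id_map["channel"] == "A"]
    xs = locs_a["x_nm"].to_numpy(float)
    ys = locs_a["y_nm"].to_numpy(float)
    fs = locs_a["frame"].to_numpy(int)
    key_of = {}
    for row, cid, ctype in zip(
        amap["row"].to_numpy(int),
        amap["complex_id"].to_numpy(int),
        amap["complex_type"].to_numpy(object),
    ):
        key = (int(fs[row]), round(float(xs[row]), 4), round(float(ys[row]), 4))
        key_of[key] = (int(cid), str(ctype))
    out = []
    for dimer in dimers:
        votes: dict[tuple[int, str], int] = {}
        rec = dimer.records
        for frame, x, y in zip(rec["frame"], rec["a_x_nm"], rec["a_y_nm"]):
            hit = key_of.get((int(frame), round(float(x), 4), round(float(y), 4)))
            if hit is not None and hit[0] >= 0:
                votes[hit] = votes.get(hit, 0) + 1
        if votes:
            out.append(max(votes.items(), key=lambda kv: (kv[1], -kv[0][0]))[0])
        else:
            out.append((-1, "false_positive"))
    return out


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulate mode).

    ``conditions`` maps a condition label to a dict of SimulationConfig
    field overrides (e.g. different complex mixes for ± ligand).
    """

    conditions: dict[str, dict] = field(default_factory=lambda: {"default": {}})
    n_cells: int = 10
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    dimer: DimerCallParams = field(default_factory=DimerCallParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    n_fiducials: int = 50
    fiducial_noise_sigma: float = 3.0
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if not self.conditions:
            raise ConfigurationError("at least one condition required")
        self.sim.validate()
        self.tracking.validate()
        self.dimer.validate()
        self.dynamics.validate()
        return self


def _cell_seed(seed: int, cond_index: int, cell_index: int) -> int:
    """Deterministic per-cell seed below 2^31."""
    ss = np.random.SeedSequence(seed, spawn_key=(cond_index, cell_index))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cell(
    config: SimulationConfig, cell_id: str = "cell000"
) -> dict:
    """Simulate one cell: ground truth plus observed localization tables.

    Channel-B coordinates are in the chromatic (channel-B camera) frame; the
    analysis must register them back into channel A.
    """
    truth = simulate_receptor_truth(config)
    locs_a, locs_b, id_map = apply_observation_model(truth, config, cell_id=cell_id)
    return {"truth": truth, "locs_a": locs_a, "locs_b": locs_b, "id_map": id_map}


def analyze_cell(
    locs_a: pd.DataFrame,
    locs_b: pd.DataFrame,
    transform: AffineTransform2D,
    tracking: TrackingParams | None = None,
    dimer: DimerCallParams | None = None,
    dynamics: DynamicsParams | None = None,
    frame_interval: float = 0.032,
    cell_id: str = "cell000",
    condition: str = "default",
    seed: int | None = None,
) -> tuple[CellResult, dict]:
    """Full single-cell analysis of two registered-to-be localization tables.

    Steps, in the published order: apply the B→A registration to channel B,
    link each channel into trajectories, filter immobile emitters, co-localize
    the mobile tracks frame by frame (100 nm cutoff), link matches into
    co-trajectories, call dimers (>= 10 co-diffusing frames), and derive the
    per-cell dimerization level, diffusion constants, immobile fraction and
    oligomer fraction.

    Returns the :class:`CellResult` and a dict of intermediates for audit.
    """
    tracking = (tracking or TrackingParams()).validate()
    dimer = (dimer or DimerCallParams()).validate()
    dynamics = (dynamics or DynamicsParams()).validate()

    locs_b_reg = apply_affine(locs_b, transform)
    tracks = {}
    mobile = {}
    immobile = {}
    for channel, locs in (("A", locs_a), ("B", locs_b_reg)):
        trajs = link_trajectories(locs, tracking.max_disp, tracking.max_gap)
        mob, imm = filter_immobile(trajs, tracking.rg_threshold, tracking.min_lifetime)
        tracks[channel] = trajs
        mobile[channel] = mob
        immobile[channel] = imm

    table_a = tracks_to_table(mobile["A"])
    table_b = tracks_to_table(mobile["B"])
    matches = colocalize_tables(table_a, table_b, dimer.cutoff_radius)
    cotrajs = build_cotrajectories(matches, dimer)
    dimers = call_dimers(cotrajs, dimer)

    rel_dim = relative_dimerization(
        dimers, mobile["A"], mobile["B"], dimer.min_track_lifetime
    )

    d_est = {}
    for channel in ("A", "B"):
        qual = qualifying_tracks(mobile[channel], dynamics.min_track_lifetime)
        if qual:
            try:
                pooled = pool_msd([compute_msd(t) for t in qual])
                d_est[channel] = fit_diffusion(
                    pooled, dynamics.fit_lags, frame_interval
                ).d_um2_s
            except AnalysisError:
                d_est[channel] = None
        else:
            d_est[channel] = None

    all_tracks = tracks["A"] + tracks["B"]
    imm_frac, _ = mobility_fractions(
        all_tracks, frame_interval, dynamics.d_immobile_threshold,
        dynamics.min_track_lifetime,
    )

    coloc_ids_a = {tid for c in cotrajs for tid in c.a_traj_ids}
    coloc_ids_b = {tid for c in cotrajs for tid in c.b_traj_ids}
    ref_a = monomer_reference_intensity(mobile["A"], coloc_ids_a)
    ref_b = monomer_reference_intensity(mobile["B"], coloc_ids_b)
    olig_frac = oligomer_fraction(dimers, ref_a, ref_b)

    result = CellResult(
        cell_id=cell_id,
        condition=condition,
        n_tracks_a=len(qualifying_tracks(mobile["A"], dimer.min_track_lifetime)),
        n_tracks_b=len(qualifying_tracks(mobile["B"], dimer.min_track_lifetime)),
        n_dimers=count_dimer_pairs(dimers),
        relative_dimerization=rel_dim,
        d_a_um2_s=d_est["A"],
        d_b_um2_s=d_est["B"],
        immobile_fraction=imm_frac,
        oligomer_fraction=olig_frac,
        seed=seed,
    )
    intermediates = {
        "tracks": tracks,
        "mobile": mobile,
        "immobile": immobile,
        "matches": matches,
        "cotrajectories": cotrajs,
        "dimers": dimers,
        "monomer_reference": {"A": ref_a, "B": ref_b},
    }
    return result, intermediates


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Simulate and analyze all cells of all conditions; compile the report.

    When ``outdir`` is given, all intermediates (localizations, estimated
    transform, trajectories, co-trajectories, per-cell table, report) are
    written there; a rerun with identical config and seed is bit-identical.
    """
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # channel registration calibrated once per run from simulated fiducials
    fid_a, fid_b = make_fiducial_set(
        config.sim.chromatic_transform,
        n_markers=config.n_fiducials,
        marker_noise_sigma=config.fiducial_noise_sigma,
        seed=_cell_seed(config.seed, 999, 0),
        field_size_nm=config.sim.field_size_nm,
    )
    transform, resid = estimate_affine(
        fid_a[["x_nm", "y_nm"]].to_numpy(), fid_b[["x_nm", "y_nm"]].to_numpy()
    )
    logger.info("registration residual RMS %.2f nm", resid)
    if out is not None:
        transform.to_json(out / "transform.json")

    cells: list[CellResult] = []
    for ci, (cond, overrides) in enumerate(config.conditions.items()):
        for k in range(config.n_cells):
            cell_id = f"{cond}_cell{k:03d}"
            seed = _cell_seed(config.seed, ci, k)
            sim_cfg = config.sim.replace(seed=seed, **overrides)
            try:
                sim = simulate_cell(sim_cfg, cell_id=cell_id)
                result, inter = analyze_cell(
                    sim["locs_a"], sim["locs_b"], transform,
                    config.tracking, config.dimer, config.dynamics,
                    frame_interval=sim_cfg.frame_interval,
                    cell_id=cell_id, condition=cond, seed=seed,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage failed for cell '{cell_id}' "
                    f"(condition '{cond}'): {exc}"
                ) from exc
            cells.append(result)
            if out is not None:
                write_localizations(sim["locs_a"], out / f"{cell_id}_locs_A.csv")
                write_localizations(sim["locs_b"], out / f"{cell_id}_locs_B.csv")
                tracks_to_table(
                    inter["mobile"]["A"] + inter["mobile"]["B"]
                ).to_csv(out / f"{cell_id}_tracks.csv", index=False,
                         float_format="%.2f", lineterminator="\n")
                cotrajectories_to_table(inter["cotrajectories"]).to_csv(
                    out / f"{cell_id}_cotracks.csv", index=False,
                    float_format="%.2f", lineterminator="\n",
                )

    report = compile_report(cells, seed=config.seed)
    report["registration_residual_rms_nm"] = resid
    if out is not None:
        write_json(report, out / "report.json")
        pd.DataFrame([c.to_dict() for c in cells]).to_csv(
            out / "cells.csv", index=False, lineterminator="\n"
        )
    return report


def run_recovery_experiment(
    grid: list[dict],
    n_cells: int = 10,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    tracking: TrackingParams | None = None,
    dimer: DimerCallParams | None = None,
    dynamics: DynamicsParams | None = None,
) -> pd.DataFrame:
    """Ground-truth vs estimate recovery over a grid of generator settings.

    Each grid point is a dict of SimulationConfig overrides.  All cells are
    simulated, analyzed blind to the truth, and summarized: mean/std of the
    per-cell relative dimerization, channel diffusion constants, immobile
    fraction and oligomer fraction, alongside the generating parameters.
    """
    if not grid:
        raise ConfigurationError("recovery grid must be non-empty")
    base = base_config or SimulationConfig()
    rows = []
    for gi, overrides in enumerate(grid):
        cfg0 = base.replace(**overrides)
        results = []
        for k in range(n_cells):
            cell_seed = _cell_seed(seed, gi, k)
            cfg = cfg0.replace(seed=cell_seed)
            sim = simulate_cell(cfg, cell_id=f"grid{gi}_cell{k:03d}")
            res, _ = analyze_cell(
                sim["locs_a"], sim["locs_b"],
                cfg.chromatic_transform.inverse(),
                tracking, dimer, dynamics,
                frame_interval=cfg.frame_interval,
                cell_id=f"grid{gi}_cell{k:03d}",
                condition=f"grid{gi}",
                seed=cell_seed,
            )
            results.append(res)

        def _agg(attr):
            vals = [getattr(r, attr) for r in results if getattr(r, attr) is not None]
            return (float(np.mean(vals)), float(np.std(vals)), len(vals)) if vals else (
                np.nan, np.nan, 0
            )

        row = {"grid_index": gi, **overrides}
        for attr, name in (
            ("relative_dimerization", "dimer_fraction"),
            ("d_a_um2_s", "d_a"),
            ("d_b_um2_s", "d_b"),
            ("immobile_fraction", "immobile_fraction"),
            ("oligomer_fraction", "oligomer_fraction"),
        ):
            mean, std, n = _agg(attr)
            row[f"{name}_mean"] = mean
            row[f"{name}_std"] = std
            row[f"{name}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows)
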