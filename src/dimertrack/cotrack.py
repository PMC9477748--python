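"""Two-colour co-localization, co-tracking and dimer quantification.

A physical receptor complex carrying one label of each colour appears as a
pair of localizations — one per channel — that stay within the
co-localization cutoff (default 100 nm) while diffusing together.  The
module matches localizations across channels frame by frame (optimal
one-to-one assignment within the cutoff), links the match midpoints over
time into co-trajectories, and calls a co-trajectory a dimer when it
contains at least ``min_codiffusion_frames`` (default 10) matched frames —
the persistence criterion that suppresses chance encounters of independently
diffusing molecules.

The per-cell relative dimerization level is the number of dimer
co-trajectories divided by min(qualifying A tracks, qualifying B tracks),
where qualifying tracks are mobile with lifetime > 10 frames; this
normalization makes a fully paired population read 1.0.  Raw counts are
always reported alongside so alternative normalizations can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DimerCallParams
from .track import Trajectory, link_frame_pair, link_points

__all__ = [
    "CoTrajectory",
    "colocalize_frame",
    "colocalize_tables",
    "build_cotrajectories",
    "call_dimers",
    "count_dimer_pairs",
    "relative_dimerization",
]

MATCH_COLUMNS = [
    "frame", "a_x_nm", "a_y_nm", "b_x_nm", "b_y_nm", "separation_nm",
    "mid_x_nm", "mid_y_nm", "a_intensity", "b_intensity", "a_traj", "b_traj",
]


@dataclass
class CoTrajectory:
    """A linked sequence of per-frame A–B matched pairs."""

    cotraj_id: int
    records: pd.DataFrame  # MATCH_COLUMNS, frames strictly increasing

    @property
    def n_matched(self) -> int:
        """Number of matched frames (gap frames are not counted)."""
        return len(self.records)

    @property
    def frames(self) -> np.ndarray:
        return self.records["frame"].to_numpy(dtype=int)

    @property
    def a_traj_ids(self) -> list[int]:
        return sorted(int(v) for v in self.records["a_traj"].unique() if v >= 0)

    @property
    def b_traj_ids(self) -> list[int]:
        return sorted(int(v) for v in self.records["b_traj"].unique() if v >= 0)

    def mean_intensity(self, channel: str) -> float:
        col = "a_intensity" if channel == "A" else "b_intensity"
        return float(self.records[col].mean())

    def midpoints(self) -> np.ndarray:
        return self.records[["mid_x_nm", "mid_y_nm"]].to_numpy(dtype=float)


def colocalize_frame(
    xy_a: np.ndarray, xy_b: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    """One-to-one A–B matches within ``cutoff`` nm in a single frame.

    Both inputs must already be registered into the channel-A coordinate
    frame.  The matching minimizes total squared separation among admissible
    pairs (Hungarian assignment on the thresholded distance matrix).
    """
    return link_frame_pair(xy_a, xy_b, cutoff)


def colocalize_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    cutoff: float = DimerCallParams.cutoff_radius,
) -> pd.DataFrame:
    """Frame-by-frame co-localization of two registered track tables.

    Parameters
    ----------
    table_a, table_b : per-channel tables with columns frame, x_nm, y_nm and
        optionally intensity and traj_id (as produced by
        :func:`dimertrack.track.tracks_to_table`).

    Returns
    -------
    DataFrame of matches (one row per matched pair per frame) with
    separations, midpoints, intensities and member trajectory ids (-1 when
    the input carries no ``traj_id`` column).
    """
    rows: list[dict] = []
    if len(table_a) == 0 or len(table_b) == 0:
        return pd.DataFrame(columns=MATCH_COLUMNS)
    ga = dict(tuple(table_a.groupby("frame", sort=True)))
    gb = dict(tuple(table_b.groupby("frame", sort=True)))
    for frame in sorted(set(ga) & set(gb)):
        sub_a, sub_b = ga[frame], gb[frame]
        xy_a = sub_a[["x_nm", "y_nm"]].to_numpy(dtype=float)
        xy_b = sub_b[["x_nm", "y_nm"]].to_numpy(dtype=float)
        for i, j in colocalize_frame(xy_a, xy_b, cutoff):
            a, b = xy_a[i], xy_b[j]
            rows.append(
                {
                    "frame": int(frame),
                    "a_x_nm": a[0], "a_y_nm": a[1],
                    "b_x_nm": b[0], "b_y_nm": b[1],
                    "separation_nm": float(np.hypot(*(a - b))),
                    "mid_x_nm": (a[0] + b[0]) / 2.0,
                    "mid_y_nm": (a[1] + b[1]) / 2.0,
                    "a_intensity": float(sub_a["intensity"].iloc[i])
                    if "intensity" in sub_a.columns else np.nan,
                    "b_intensity": float(sub_b["intensity"].iloc[j])
                    if "intensity" in sub_b.columns else np.nan,
                    "a_traj": int(sub_a["traj_id"].iloc[i])
                    if "traj_id" in sub_a.columns else -1,
                    "b_traj": int(sub_b["traj_id"].iloc[j])
                    if "traj_id" in sub_b.columns else -1,
                }
            )
    return pd.DataFrame(rows, columns=MATCH_COLUMNS)


def build_cotrajectories(
    matches: pd.DataFrame, params: DimerCallParams | None = None
) -> list[CoTrajectory]:
    """Link per-frame matches into co-trajectories.

    Match midpoints are tracked with the same linker used for single
    channels (``cotrack_max_disp``, ``cotrack_max_gap``).  ``n_matched``
    counts matched frames only; frames bridged by gap closing do not count
    towards the dimer persistence criterion.
    """
    params = (params or DimerCallParams()).validate()
    if len(matches) == 0:
        return []
    frames = matches["frame"].to_numpy(dtype=int)
    mid = matches[["mid_x_nm", "mid_y_nm"]].to_numpy(dtype=float)
    groups = link_points(frames, mid, params.cotrack_max_disp, params.cotrack_max_gap)
    groups.sort(key=lambda g: (frames[g[0]], mid[g[0], 0], mid[g[0], 1]))
    return [
        CoTrajectory(cid, matches.iloc[g].reset_index(drop=True))
        for cid, g in enumerate(groups)
    ]


def call_dimers(
    cotrajectories: list[CoTrajectory], params: DimerCallParams | None = None
) -> list[CoTrajectory]:
    """Dimer calls: co-trajectories co-diffusing for >= the frame minimum."""
    params = (params or DimerCallParams()).validate()
    return [c for c in cotrajectories if c.n_matched >= params.min_codiffusion_frames]


def count_dimer_pairs(dimers: list[CoTrajectory]) -> int:
    """Number of distinct dimerized molecule pairs among dimer calls.

    One physical A–B pair can fragment into several dimer-called
    co-trajectories (blinking, borderline separations); counting fragments
    would overstate — and at tight cutoffs even invert — the dimerization
    level.  Dimer-called co-trajectories sharing a member trajectory in
    either channel are therefore grouped (connected components of the
    member-track graph) and each group counts once; co-trajectories without
    resolvable member ids each count once.
    """
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        for n in (x, y):
            parent.setdefault(n, n)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    unresolved = 0
    for c in dimers:
        nodes = [("A", tid) for tid in c.a_traj_ids] + [
            ("B", tid) for tid in c.b_traj_ids
        ]
        if not nodes:
            unresolved += 1
            continue
        for n in nodes[1:]:
            union(nodes[0], n)
        parent.setdefault(nodes[0], nodes[0])
    components = {find(n) for n in parent}
    return len(components) + unresolved


def qualifying_tracks(
    mobile_tracks: list[Trajectory], min_lifetime: int = DimerCallParams.min_track_lifetime
) -> list[Trajectory]:
    """Mobile tracks entering the dimerization denominator (lifetime > cut)."""
    return [t for t in mobile_tracks if t.lifetime > min_lifetime]


def relative_dimerization(
    dimers: list[CoTrajectory],
    mobile_tracks_a: list[Trajectory],
    mobile_tracks_b: list[Trajectory],
    min_lifetime: int = DimerCallParams.min_track_lifetime,
) -> float | None:
    """Per-cell relative dimerization level.

    fraction = n_dimer_pairs / min(N_A, N_B), with dimer pairs deduplicated
    by member tracks (:func:`count_dimer_pairs`) and qualifying tracks
    mobile with lifetime > ``min_lifetime`` frames.  Returns ``None`` (a
    missing value, never 0) when either channel has no qualifying track;
    returns 0.0 when tracks exist but no dimer was called.
    """
    n_a = len(qualifying_tracks(mobile_tracks_a, min_lifetime))
    n_b = len(qualifying_tracks(mobile_tracks_b, min_lifetime))
    if n_a == 0 or n_b == 0:
        return None
    return count_dimer_pairs(dimers) / min(n_a, n_b)


def cotrajectories_to_table(cotrajectories: list[CoTrajectory]) -> pd.DataFrame:
    """Flatten co-trajectories for CSV export (audit trail)."""
    if not cotrajectories:
        return pd.DataFrame(columns=["cotraj_id", *MATCH_COLUMNS])
    parts = []
    for c in cotrajectories:
        rec = c.records.copy()
        rec.insert(0, "cotraj_id", c.cotraj_id)
        parts.append(rec)
    return pd.concat(parts, ignore_index=True)
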