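"""Single-channel trajectory linking and immobile-emitter filtering.

Frame-to-frame linking is a one-to-one assignment minimizing total squared
displacement, with links forbidden beyond a hard radius ``max_disp``.  It is
solved exactly with the Hungarian algorithm on a padded cost matrix in which
leaving a localization unlinked costs ``max_disp²`` (the classic
birth/death-augmented formulation).  Track ends are then joined to later
track starts when the gap is at most ``max_gap`` frames and the displacement
at most ``max_disp·√(gap+1)``.

Immobile emitters — receptors trapped in clathrin pits or adhering to the
substrate — are removed before any co-localization by thresholding the
trajectory radius of gyration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .config import TrackingParams

__all__ = [
    "Trajectory",
    "link_frame_pair",
    "assignment_objective",
    "link_points",
    "link_trajectories",
    "filter_immobile",
    "tracks_to_table",
]


@dataclass
class Trajectory:
    """One linked emitter: time-ordered localizations, possibly with gaps."""

    trajectory_id: int
    channel: str
    frames: np.ndarray            # (n_obs,) strictly increasing ints
    xy: np.ndarray                # (n_obs, 2) nm
    intensity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if self.intensity is None:
            self.intensity = np.zeros(len(self.frames))
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("trajectory frames must be strictly increasing")

    @property
    def n_obs(self) -> int:
        return len(self.frames)

    @property
    def lifetime(self) -> int:
        """Frames from first to last observation, inclusive."""
        return int(self.frames[-1] - self.frames[0] + 1) if self.n_obs else 0

    def radius_of_gyration(self) -> float:
        """RMS distance of the points from their centroid (nm)."""
        centred = self.xy - self.xy.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def link_frame_pair(
    xy0: np.ndarray, xy1: np.ndarray, max_disp: float
) -> list[tuple[int, int]]:
    """Optimal one-to-one links between two frames' localizations.

    Minimizes Σd² over chosen links plus ``max_disp²`` per unlinked
    localization, with links above ``max_disp`` forbidden.  Returns (i, j)
    index pairs sorted by (i, j); ties in cost are resolved deterministically
    by the Hungarian solver's fixed scan order.
    """
    xy0 = np.asarray(xy0, float).reshape(-1, 2)
    xy1 = np.asarray(xy1, float).reshape(-1, 2)
    n0, n1 = len(xy0), len(xy1)
    if n0 == 0 or n1 == 0:
        return []
    B = float(max_disp) ** 2
    d2 = cdist(xy0, xy1, "sqeuclidean")
    big = 1e6 * (B + 1.0)
    cost = np.full((n0 + n1, n0 + n1), big)
    cost[:n0, :n1] = np.where(d2 <= B, d2, big)
    cost[np.arange(n0), n1 + np.arange(n0)] = B  # death of a frame-0 point
    cost[n0 + np.arange(n1), np.arange(n1)] = B  # birth of a frame-1 point
    cost[n0:, n1:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return sorted(
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n0 and c < n1 and d2[r, c] <= B
    )


def assignment_objective(
    xy0: np.ndarray, xy1: np.ndarray, links: list[tuple[int, int]], max_disp: float
) -> float:
    """Total cost of a link set under the linking objective.

    Σd² over links + max_disp²·(#unlinked in frame 0 + #unlinked in frame 1).
    Used to compare the Hungarian solution against brute-force enumeration.
    """
    xy0 = np.asarray(xy0, float).reshape(-1, 2)
    xy1 = np.asarray(xy1, float).reshape(-1, 2)
    B = float(max_disp) ** 2
    total = sum(float(np.sum((xy0[i] - xy1[j]) ** 2)) for i, j in links)
    return total + B * (len(xy0) - len(links)) + B * (len(xy1) - len(links))


def link_points(
    frames: np.ndarray,
    xy: np.ndarray,
    max_disp: float,
    max_gap: int,
) -> list[np.ndarray]:
    """Core linker: group point observations into tracks.

    Parameters
    ----------
    frames, xy : parallel arrays of frame index and position (nm).
    max_disp : hard per-frame linking radius (nm).
    max_gap : maximum number of consecutive missing frames closable.

    Returns
    -------
    list of index arrays, one per track, each time-ordered; indices refer to
    the input arrays.  Every input point belongs to exactly one track.
    """
    frames = np.asarray(frames, dtype=int)
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if frames.size == 0:
        return []

    order = np.lexsort((xy[:, 1], xy[:, 0], frames))
    by_frame: dict[int, np.ndarray] = {
        int(f): order[frames[order] == f] for f in np.unique(frames)
    }
    frame_values = sorted(by_frame)

    segments: list[list[int]] = []
    open_segment: dict[int, int] = {}  # point index in previous frame -> segment
    prev_f: int | None = None
    for f in frame_values:
        cur = by_frame[f]
        new_open: dict[int, int] = {}
        if prev_f is not None and f == prev_f + 1 and open_segment:
            prev_idx = np.array(sorted(open_segment), dtype=int)
            links = link_frame_pair(xy[prev_idx], xy[cur], max_disp)
            linked_cur = set()
            for i, j in links:
                seg = open_segment[int(prev_idx[i])]
                segments[seg].append(int(cur[j]))
                new_open[int(cur[j])] = seg
                linked_cur.add(j)
            for j, idx in enumerate(cur):
                if j not in linked_cur:
                    new_open[int(idx)] = len(segments)
                    segments.append([int(idx)])
        else:
            for idx in cur:
                new_open[int(idx)] = len(segments)
                segments.append([int(idx)])
        open_segment = new_open
        prev_f = f

    if max_gap > 0 and len(segments) > 1:
        segments = _close_gaps(segments, frames, xy, max_disp, max_gap)
    return [np.asarray(s, dtype=int) for s in segments]


def _close_gaps(
    segments: list[list[int]],
    frames: np.ndarray,
    xy: np.ndarray,
    max_disp: float,
    max_gap: int,
) -> list[list[int]]:
    """Join segment ends to later segment starts (one assignment pass).

    Cost is squared displacement normalized by (gap+1); a pair is feasible
    when 1 ≤ gap ≤ max_gap and displacement ≤ max_disp·√(gap+1).
    """
    n = len(segments)
    end_f = np.array([frames[s[-1]] for s in segments])
    start_f = np.array([frames[s[0]] for s in segments])
    end_xy = np.array([xy[s[-1]] for s in segments])
    start_xy = np.array([xy[s[0]] for s in segments])

    B = float(max_disp) ** 2
    big = 1e6 * (B + 1.0)
    gap = start_f[None, :] - end_f[:, None] - 1
    d2 = cdist(end_xy, start_xy, "sqeuclidean")
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(gap >= 1, d2 / np.maximum(gap + 1.0, 1.0), np.inf)
    feasible = (gap >= 1) & (gap <= max_gap) & (norm <= B)
    if not feasible.any():
        return segments
    cost = np.full((2 * n, 2 * n), big)
    cost[:n, :n] = np.where(feasible, norm, big)
    cost[np.arange(n), n + np.arange(n)] = B
    cost[n + np.arange(n), np.arange(n)] = B
    cost[n:, n:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    successor = {
        int(r): int(c)
        for r, c in zip(rows, cols)
        if r < n and c < n and feasible[r, c]
    }
    has_predecessor = set(successor.values())
    merged: list[list[int]] = []
    for k in range(n):
        if k in has_predecessor:
            continue
        chain = list(segments[k])
        cur = k
        while cur in successor:
            cur = successor[cur]
            chain.extend(segments[cur])
        merged.append(chain)
    return merged


def link_trajectories(
    table: pd.DataFrame,
    max_disp: float = 500.0,
    max_gap: int = 1,
) -> list[Trajectory]:
    """Link a single-channel localization table into trajectories.

    Trajectory ids are assigned in order of (first frame, first x, first y)
    for determinism.
    """
    if max_disp <= 0 or max_gap < 0:
        raise ValueError("max_disp must be > 0 and max_gap >= 0")
    if len(table) == 0:
        return []
    channels = table["channel"].unique() if "channel" in table.columns else ["?"]
    if len(channels) > 1:
        raise ValueError("link_trajectories expects a single-channel table")
    channel = str(channels[0])

    frames = table["frame"].to_numpy(dtype=int)
    xy = table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    inten = (
        table["intensity"].to_numpy(dtype=float)
        if "intensity" in table.columns
        else np.zeros(len(table))
    )
    groups = link_points(frames, xy, max_disp, max_gap)
    groups.sort(key=lambda g: (frames[g[0]], xy[g[0], 0], xy[g[0], 1]))
    return [
        Trajectory(tid, channel, frames[g], xy[g], inten[g])
        for tid, g in enumerate(groups)
    ]


def filter_immobile(
    trajectories: list[Trajectory],
    rg_threshold: float = TrackingParams.rg_threshold,
    min_lifetime: int = TrackingParams.min_lifetime,
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Partition trajectories into (mobile, immobile).

    A trajectory is immobile when its lifetime is at least ``min_lifetime``
    frames and its radius of gyration is below ``rg_threshold`` nm.  Short
    tracks stay in the mobile partition (they are removed later by lifetime
    cuts).  Immobile tracks are excluded from all co-tracking and diffusion
    analysis downstream; both partitions are returned for audit.
    """
    if rg_threshold <= 0 or min_lifetime <= 0:
        raise ValueError("thresholds must be positive")
    mobile: list[Trajectory] = []
    immobile: list[Trajectory] = []
    for t in trajectories:
        if t.lifetime >= min_lifetime and t.radius_of_gyration() < rg_threshold:
            immobile.append(t)
        else:
            mobile.append(t)
    return mobile, immobile


def tracks_to_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories to a table (traj_id, channel, frame, x, y, int)."""
    if not trajectories:
        return pd.DataFrame(
            columns=["traj_id", "channel", "frame", "x_nm", "y_nm", "intensity"]
        )
    parts = [
        pd.DataFrame(
            {
                "traj_id": t.trajectory_id,
                "channel": t.channel,
                "frame": t.frames,
                "x_nm": t.xy[:, 0],
                "y_nm": t.xy[:, 1],
                "intensity": t.intensity,
            }
        )
        for t in trajectories
    ]
    return pd.concat(parts, ignore_index=True)
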