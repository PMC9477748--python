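"""Mean-squared-displacement analysis, diffusion constants, mobility and
intensity-based oligomer quantification.

For 2D Brownian motion the time-averaged MSD is linear in lag,
MSD(τ) = 4·D·τ·Δt + 4·σ_loc², so a weighted linear regression of the pooled
MSD over short lags yields the diffusion constant (slope) and the static
localization error (intercept).  Trajectories qualify for MSD analysis when
their lifetime exceeds 10 frames.

Complex stoichiometry is assessed from single-molecule intensities: the
per-channel label multiplicity of a co-diffusing complex is its mean
background-subtracted intensity divided by the per-cell monomer reference
(median intensity of mobile, non-co-localized tracks of the same channel),
rounded to the nearest integer.  A dimer-called complex with multiplicity
>= 2 in either channel is classified as a higher-order cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DynamicsParams
from .cotrack import CoTrajectory
from .errors import AnalysisError
from .track import Trajectory

__all__ = [
    "MsdCurve",
    "DiffusionEstimate",
    "compute_msd",
    "pool_msd",
    "fit_diffusion",
    "per_trajectory_diffusion",
    "mobility_fractions",
    "monomer_reference_intensity",
    "oligomer_fraction",
]


@dataclass
class MsdCurve:
    """Time-averaged MSD per integer frame lag, with pair counts."""

    lags: np.ndarray    # (n,) positive ints, increasing
    msd: np.ndarray     # (n,) nm²
    counts: np.ndarray  # (n,) displacement pairs contributing per lag

    def subset(self, lags: tuple[int, ...]) -> "MsdCurve":
        missing = sorted(set(lags) - set(self.lags.tolist()))
        if missing:
            raise AnalysisError(f"lags {missing} absent from MSD curve")
        mask = np.isin(self.lags, np.asarray(lags, dtype=int))
        return MsdCurve(self.lags[mask], self.msd[mask], self.counts[mask])


@dataclass
class DiffusionEstimate:
    """Diffusion constant from an MSD line fit."""

    d_um2_s: float                 # slope/4Δt, floored at 0
    loc_error_sigma_nm: float      # sqrt(intercept/4), intercept floored at 0
    fit_lags: tuple[int, ...]
    r_squared: float
    negative_slope: bool = False   # raw slope was negative (D truncated)


def compute_msd(trajectory: Trajectory | tuple[np.ndarray, np.ndarray]) -> MsdCurve:
    """Time-averaged MSD of one trajectory.

    For each lag τ the mean of ‖r(t+τ) − r(t)‖² over all observed pairs
    separated by exactly τ frames; gap frames contribute no pairs.
    """
    if isinstance(trajectory, Trajectory):
        frames, xy = trajectory.frames, trajectory.xy
    else:
        frames, xy = trajectory
        frames = np.asarray(frames, dtype=int)
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(frames)
    if n < 2:
        raise AnalysisError("need at least 2 observed frames for an MSD")
    dframe = frames[None, :] - frames[:, None]
    d2 = np.sum((xy[None, :, :] - xy[:, None, :]) ** 2, axis=-1)
    iu = np.triu_indices(n, k=1)
    lags_all = dframe[iu]
    d2_all = d2[iu]
    lags = np.unique(lags_all)
    msd = np.array([d2_all[lags_all == lag].mean() for lag in lags])
    counts = np.array([(lags_all == lag).sum() for lag in lags])
    return MsdCurve(lags.astype(int), msd, counts)


def pool_msd(curves: list[MsdCurve]) -> MsdCurve:
    """Pair-count-weighted pooling of per-trajectory MSD curves."""
    if not curves:
        raise AnalysisError("no MSD curves to pool")
    acc: dict[int, list[float]] = {}
    for c in curves:
        for lag, m, k in zip(c.lags, c.msd, c.counts):
            s = acc.setdefault(int(lag), [0.0, 0.0])
            s[0] += m * k
            s[1] += k
    lags = np.array(sorted(acc), dtype=int)
    msd = np.array([acc[int(l)][0] / acc[int(l)][1] for l in lags])
    counts = np.array([acc[int(l)][1] for l in lags])
    return MsdCurve(lags, msd, counts)


def fit_diffusion(
    pooled: MsdCurve,
    fit_lags: tuple[int, ...] = DynamicsParams.fit_lags,
    frame_interval: float = 0.032,
) -> DiffusionEstimate:
    """Weighted linear regression MSD(τ) = 4·D·τ·Δt + 4·σ².

    Weights are the pair counts per lag.  A negative slope is truncated to
    D = 0 and flagged; a negative intercept is floored at σ = 0.
    """
    sub = pooled.subset(tuple(fit_lags))
    x = sub.lags * frame_interval          # s
    y = sub.msd                            # nm²
    w = sub.counts.astype(float)
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    mean_w = np.average(y, weights=w)
    ss_res = float(np.sum(w * (y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum(w * (y - mean_w) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    negative = slope < 0
    d = max(slope, 0.0) / 4.0 / 1e6        # nm²/s -> µm²/s
    sigma = float(np.sqrt(max(intercept, 0.0) / 4.0))
    return DiffusionEstimate(
        d_um2_s=float(d),
        loc_error_sigma_nm=sigma,
        fit_lags=tuple(int(l) for l in fit_lags),
        r_squared=float(r2),
        negative_slope=bool(negative),
    )


def per_trajectory_diffusion(
    trajectory: Trajectory, frame_interval: float = 0.032
) -> float | None:
    """Single-trajectory D (µm²/s) from the MSD slope over lags 1–2.

    The two-point slope (MSD(2) − MSD(1))/Δt cancels the localization-error
    offset.  Returns None when a lag is missing (gappy short track); the
    value may be negative for immobile tracks — callers threshold, not
    truncate.
    """
    curve = compute_msd(trajectory)
    present = set(curve.lags.tolist())
    if not {1, 2} <= present:
        return None
    m = {int(l): v for l, v in zip(curve.lags, curve.msd)}
    slope = (m[2] - m[1]) / frame_interval
    return float(slope / 4.0 / 1e6)


def mobility_fractions(
    trajectories: list[Trajectory],
    frame_interval: float = 0.032,
    d_immobile_threshold: float = DynamicsParams.d_immobile_threshold,
    min_lifetime: int = DynamicsParams.min_track_lifetime,
) -> tuple[float | None, np.ndarray]:
    """Immobile fraction and the per-trajectory D list it derives from.

    Trajectories with lifetime > ``min_lifetime`` get a per-trajectory D from
    lags 1–2; the immobile fraction is the proportion with
    D < ``d_immobile_threshold`` (µm²/s).  Returns (None, empty) when no
    trajectory qualifies.
    """
    ds = [
        d
        for t in trajectories
        if t.lifetime > min_lifetime
        for d in [per_trajectory_diffusion(t, frame_interval)]
        if d is not None
    ]
    ds = np.asarray(ds, dtype=float)
    if ds.size == 0:
        return None, ds
    return float(np.mean(ds < d_immobile_threshold)), ds


def monomer_reference_intensity(
    mobile_tracks: list[Trajectory], colocalized_ids: set[int]
) -> float | None:
    """Per-cell monomer intensity reference for one channel.

    Median of the per-track mean intensities over mobile tracks that never
    entered a co-localized pair.  Returns None when no reference track
    exists (reported as a missing value upstream).
    """
    vals = [
        float(np.mean(t.intensity))
        for t in mobile_tracks
        if t.trajectory_id not in colocalized_ids and t.n_obs > 0
    ]
    if not vals:
        return None
    return float(np.median(vals))


def oligomer_fraction(
    dimers: list[CoTrajectory],
    monomer_reference_a: float | None,
    monomer_reference_b: float | None,
) -> float | None:
    """Fraction of dimer-called co-trajectories that are higher-order.

    A co-trajectory is higher-order when its rounded intensity multiplicity
    (mean intensity / monomer reference) is >= 2 in either channel.  Returns
    None when there are no dimers or no monomer reference.
    """
    if not dimers:
        return None
    if not monomer_reference_a or not monomer_reference_b:
        return None
    higher = 0
    for c in dimers:
        mult_a = round(c.mean_intensity("A") / monomer_reference_a)
        mult_b = round(c.mean_intensity("B") / monomer_reference_b)
        if mult_a >= 2 or mult_b >= 2:
            higher += 1
    return higher / len(dimers)
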