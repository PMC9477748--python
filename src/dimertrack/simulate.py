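"""Synthetic dual-colour single-molecule experiment generator.

Emulates TIRF movies of fluorescently labelled membrane receptors: complexes
(monomers, homo-/heterodimers, higher-order assemblies) diffuse on a 2D
membrane patch, carry sub-stoichiometric labels with blinking and
irreversible bleaching, and are observed through a localization model
(Gaussian localization error, chromatic offset for channel B, false
positives) or rendered into camera frames (integrated Gaussian PSF, Poisson
photons, gain and read noise).

Complex composition is static within a movie: the 4.8 s acquisitions probe
equilibrium dimerization levels, not binding kinetics, so no association or
dissociation events are simulated.

Coordinates are continuous nm with the origin at the field corner, x
rightward, y downward; pixel (row i, col j) has its centre at
((j+0.5)·px, (i+0.5)·px).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .config import (
    COMPLEX_DIFFUSION_CLASS,
    COMPLEX_SPECIES,
    SimulationConfig,
)
from .errors import IdentifiabilityError
from .io import LOC_COLUMNS
from .register import AffineTransform2D

__all__ = [
    "GroundTruth",
    "simulate_receptor_truth",
    "apply_observation_model",
    "render_movie",
    "make_fiducial_set",
    "heterodimer_condition",
]


def heterodimer_condition(
    p: float, particle_density: float = 0.12
) -> dict:
    """SimulationConfig overrides for a given heterodimer proportion.

    ``p`` is the ground-truth fraction of receptor particles (per channel)
    bound in A–B heterodimers; the remainder are monomers.  The per-channel
    particle density is held at ``particle_density`` (particles/µm²) across
    conditions — a heterodimer consumes one particle of each colour, so the
    complex density is (2−p)·particle_density.  Holding the particle density
    (not the complex density) fixed keeps the qualifying-track denominator
    constant across conditions, making the estimated relative dimerization
    proportional to ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("heterodimer proportion must lie in [0, 1]")
    total = 2.0 - p
    return {
        "density": total * particle_density,
        "complex_mix": {
            "monomer_a": (1.0 - p) / total,
            "monomer_b": (1.0 - p) / total,
            "heterodimer_ab": p / total,
        },
    }


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible substream ``stream`` of a master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class GroundTruth:
    """True per-particle states of one simulated cell.

    Attributes
    ----------
    particles : DataFrame with one row per protomer:
        particle_id, complex_id, complex_type, species (A|B),
        mobility (mobile|immobile), labeled (bool).
    positions : (n_particles, n_frames, 2) float array, true positions in nm.
    emitting : (n_particles, n_frames) bool array or None.
        Filled in by :func:`apply_observation_model` (labelled, currently in
        the ON state and not yet bleached).
    """

    particles: pd.DataFrame
    positions: np.ndarray
    n_frames: int
    field_size_nm: float
    emitting: np.ndarray | None = None

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-particle per-frame table (for CSV export)."""
        n_p, n_f = self.positions.shape[:2]
        pid = np.repeat(self.particles["particle_id"].to_numpy(), n_f)
        frame = np.tile(np.arange(n_f), n_p)
        out = pd.DataFrame(
            {
                "particle_id": pid,
                "frame": frame,
                "x_nm": self.positions[:, :, 0].ravel(),
                "y_nm": self.positions[:, :, 1].ravel(),
            }
        )
        if self.emitting is not None:
            out["emitting"] = self.emitting.ravel()
        return out


def _reflect(pos: np.ndarray, size: float) -> np.ndarray:
    """Fold coordinates into [0, size] (reflecting boundaries)."""
    period = 2.0 * size
    p = np.mod(pos, period)
    return np.where(p > size, period - p, p)


def simulate_receptor_truth(config: SimulationConfig) -> GroundTruth:
    """Generate true receptor-complex trajectories for one cell.

    Each complex centre performs 2D Brownian motion with per-axis per-step
    variance 2·D·Δt (D set by the complex's diffusion class, 0 for the
    immobile class) between reflecting boundaries; each member protomer sits
    at the centre plus independent per-frame Gaussian jitter of std
    ``bond_jitter_sigma`` per axis.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    size = config.field_size_nm
    n_frames = config.n_frames
    area = config.field_size_um**2

    n_complexes = int(round(config.density * area))
    mix_names = [k for k in COMPLEX_SPECIES if k in config.complex_mix]
    mix_p = np.array([config.complex_mix[k] for k in mix_names], dtype=float)
    mix_p = mix_p / mix_p.sum()
    types = rng.choice(len(mix_names), size=n_complexes, p=mix_p)
    type_names = np.array(mix_names, dtype=object)[types]
    mobile = rng.random(n_complexes) >= config.immobile_fraction

    # Brownian centres: per-axis step std in nm (D in µm²/s -> 1e6 nm²/s)
    d_class = config.d_for_class
    d_vals = np.array(
        [d_class[COMPLEX_DIFFUSION_CLASS[t]] for t in type_names], dtype=float
    )
    d_vals[~mobile] = 0.0
    step_std = np.sqrt(2.0 * d_vals * 1e6 * config.frame_interval)

    start = rng.uniform(0.0, size, size=(n_complexes, 2))
    steps = rng.standard_normal((n_complexes, n_frames - 1, 2)) * step_std[:, None, None]
    centres = np.empty((n_complexes, n_frames, 2))
    centres[:, 0] = start
    if n_frames > 1:
        centres[:, 1:] = start[:, None, :] + np.cumsum(steps, axis=1)
    centres = _reflect(centres, size)

    # expand complexes into member protomers
    members_per = np.array([len(COMPLEX_SPECIES[t]) for t in type_names])
    n_particles = int(members_per.sum())
    complex_of = np.repeat(np.arange(n_complexes), members_per)
    species = np.concatenate(
        [np.array(COMPLEX_SPECIES[t], dtype=object) for t in type_names]
    ) if n_complexes else np.array([], dtype=object)

    positions = centres[complex_of]
    if config.bond_jitter_sigma > 0 and n_particles:
        # bond jitter models protomer excursions about a shared complex
        # centre; a single-member complex IS its centre, so no jitter there
        multi = (members_per[complex_of] > 1)[:, None, None]
        positions = positions + multi * rng.standard_normal(
            (n_particles, n_frames, 2)
        ) * config.bond_jitter_sigma
        positions = _reflect(positions, size)

    label_p = np.where(species == "A", config.label_prob_a, config.label_prob_b)
    labeled = rng.random(n_particles) < label_p.astype(float)

    particles = pd.DataFrame(
        {
            "particle_id": np.arange(n_particles),
            "complex_id": complex_of,
            "complex_type": type_names[complex_of] if n_particles else [],
            "species": species,
            "mobility": np.where(mobile[complex_of], "mobile", "immobile")
            if n_particles
            else [],
            "labeled": labeled,
        }
    )
    return GroundTruth(
        particles=particles,
        positions=positions,
        n_frames=n_frames,
        field_size_nm=size,
    )


def _simulate_photophysics(
    labeled: np.ndarray, n_frames: int, config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-state blinking + irreversible bleaching Markov chain per label.

    Labels start ON in frame 0.  From ON: bleach with ``bleach_prob``, else
    switch off with ``blink_off_prob``.  From OFF: recover with
    ``blink_on_prob``.  Returns the (n_particles, n_frames) emitting mask.
    """
    n = labeled.size
    on = np.zeros((n, n_frames), dtype=bool)
    state_on = labeled.copy()
    bleached = np.zeros(n, dtype=bool)
    on[:, 0] = state_on
    for t in range(1, n_frames):
        u = rng.random(n)
        v = rng.random(n)
        alive_on = state_on & ~bleached
        newly_bleached = alive_on & (u < config.bleach_prob)
        bleached |= newly_bleached
        turn_off = alive_on & ~newly_bleached & (v < config.blink_off_prob)
        alive_off = labeled & ~state_on & ~bleached
        turn_on = alive_off & (u < config.blink_on_prob)
        state_on = (state_on & ~newly_bleached & ~turn_off) | turn_on
        on[:, t] = state_on & ~bleached
    return on & labeled[:, None]


def apply_observation_model(
    truth: GroundTruth, config: SimulationConfig, cell_id: str = "sim"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convert ground truth into per-channel localization tables.

    Emission follows the blink/bleach chain per labelled protomer.  Emitting
    protomers of the same complex and channel lie within the bond jitter —
    far below the diffraction limit — so they appear as one spot: their
    localizations are merged (intensity summed, position averaged) before a
    single localization-error draw.  Channel-B coordinates are passed through
    the chromatic transform; false positives are added uniformly.

    Returns
    -------
    (locs_a, locs_b, id_map)
        Localization tables in the standard schema, plus an identity map with
        one row per localization (columns: channel, row, frame, complex_id,
        complex_type, particle_ids, multiplicity, true_x_nm, true_y_nm,
        false_positive) where ``row`` indexes into the per-channel table.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    emitting = _simulate_photophysics(
        truth.particles["labeled"].to_numpy(), truth.n_frames, config, rng
    )
    truth.emitting = emitting

    p_idx, f_idx = np.nonzero(emitting)
    pos = truth.positions[p_idx, f_idx]
    inten = config.photons_mean * np.maximum(
        0.0, 1.0 + config.intensity_cv * rng.standard_normal(p_idx.size)
    )
    long = pd.DataFrame(
        {
            "particle_id": truth.particles["particle_id"].to_numpy()[p_idx],
            "complex_id": truth.particles["complex_id"].to_numpy()[p_idx],
            "complex_type": truth.particles["complex_type"].to_numpy()[p_idx],
            "channel": truth.particles["species"].to_numpy()[p_idx],
            "frame": f_idx,
            "x": pos[:, 0],
            "y": pos[:, 1],
            "intensity": inten,
        }
    )
    # merge co-complex emitters of one channel into single spots
    if len(long):
        keys = ["channel", "frame", "complex_id"]
        grp = long.groupby(keys, sort=True)
        grouped = grp.agg(
            complex_type=("complex_type", "first"),
            x=("x", "mean"),
            y=("y", "mean"),
            intensity=("intensity", "sum"),
            multiplicity=("particle_id", "size"),
            pid_min=("particle_id", "min"),
        ).reset_index()
        # id strings: cheap path for single-member spots (the vast majority)
        grouped["particle_ids"] = grouped["pid_min"].astype(int).astype(str)
        if (grouped["multiplicity"] > 1).any():
            sizes = grp["particle_id"].transform("size")
            joined = (
                long[sizes > 1]
                .groupby(keys, sort=True)["particle_id"]
                .agg(lambda s: "|".join(str(int(v)) for v in sorted(s)))
            )
            grouped = grouped.set_index(keys)
            grouped.loc[joined.index, "particle_ids"] = joined
            grouped = grouped.reset_index()
        grouped = grouped.drop(columns=["pid_min"])
    else:
        grouped = pd.DataFrame(
            columns=[
                "channel", "frame", "complex_id", "complex_type", "x", "y",
                "intensity", "multiplicity", "particle_ids",
            ]
        )

    detected = rng.random(len(grouped)) < config.detect_prob
    grouped = grouped.loc[detected].reset_index(drop=True)

    tables: dict[str, pd.DataFrame] = {}
    maps: dict[str, pd.DataFrame] = {}
    for channel in ("A", "B"):
        sub = grouped[grouped["channel"] == channel].reset_index(drop=True)
        xy = sub[["x", "y"]].to_numpy(dtype=float).reshape(-1, 2)
        if channel == "B":
            xy = config.chromatic_transform.apply(xy) if len(xy) else xy
        if config.loc_error_sigma > 0 and len(xy):
            xy = xy + rng.standard_normal(xy.shape) * config.loc_error_sigma

        # false positives: uniform over the observed field
        n_fp = rng.poisson(config.false_positive_rate * config.n_frames)
        fp_frames = np.sort(rng.integers(0, config.n_frames, size=n_fp))
        fp_xy = rng.uniform(0.0, truth.field_size_nm, size=(n_fp, 2))
        fp_inten = config.photons_mean * np.maximum(
            0.05, 1.0 + config.intensity_cv * rng.standard_normal(n_fp)
        )

        table = pd.DataFrame(
            {
                "cell_id": cell_id,
                "channel": channel,
                "frame": np.concatenate([sub["frame"].to_numpy(int), fp_frames]),
                "x_nm": np.concatenate([xy[:, 0], fp_xy[:, 0]]),
                "y_nm": np.concatenate([xy[:, 1], fp_xy[:, 1]]),
                "intensity": np.concatenate([sub["intensity"].to_numpy(), fp_inten]),
                "background": config.background_photons,
            }
        )
        id_map = pd.DataFrame(
            {
                "channel": channel,
                "frame": table["frame"].to_numpy(),
                "complex_id": np.concatenate(
                    [sub["complex_id"].to_numpy(int), np.full(n_fp, -1, dtype=int)]
                ),
                "complex_type": np.concatenate(
                    [sub["complex_type"].to_numpy(object),
                     np.full(n_fp, "false_positive", dtype=object)]
                ),
                "particle_ids": np.concatenate(
                    [sub["particle_ids"].to_numpy(object),
                     np.full(n_fp, "", dtype=object)]
                ),
                "multiplicity": np.concatenate(
                    [sub["multiplicity"].to_numpy(int), np.zeros(n_fp, dtype=int)]
                ),
                "true_x_nm": np.concatenate([sub["x"].to_numpy(), fp_xy[:, 0]]),
                "true_y_nm": np.concatenate([sub["y"].to_numpy(), fp_xy[:, 1]]),
                "false_positive": np.concatenate(
                    [np.zeros(len(sub), bool), np.ones(n_fp, bool)]
                ),
            }
        )
        order = np.lexsort(
            (table["y_nm"].to_numpy(), table["x_nm"].to_numpy(),
             table["frame"].to_numpy())
        )
        table = table.iloc[order].reset_index(drop=True)[LOC_COLUMNS]
        id_map = id_map.iloc[order].reset_index(drop=True)
        id_map.insert(1, "row", np.arange(len(id_map)))
        tables[channel] = table
        maps[channel] = id_map

    id_map_all = pd.concat([maps["A"], maps["B"]], ignore_index=True)
    return tables["A"], tables["B"], id_map_all


def _pixel_weights(coord: np.ndarray, edges: np.ndarray, sigma: float) -> np.ndarray:
    """Integrated-Gaussian weight of each pixel interval for a 1D coordinate."""
    z = (edges - coord) / (sigma * np.sqrt(2.0))
    cdf = 0.5 * (1.0 + special.erf(z))
    return np.diff(cdf)


def render_movie(
    localizations: pd.DataFrame,
    config: SimulationConfig,
    stream: int = 2,
) -> np.ndarray:
    """Render one channel's localizations into a 16-bit camera movie.

    Each emitter contributes an integrated 2D Gaussian PSF (std
    ``psf_sigma``); pixel photon counts are Poisson draws of signal +
    ``background_photons``, scaled by ``camera_gain`` with additive Gaussian
    read noise, rounded and clamped to the 16-bit range.  Emitters outside
    the field are silently clipped at the frame edge.

    Parameters
    ----------
    localizations : table with columns frame, x_nm, y_nm, intensity
        (intensity in expected photons per frame).
    stream : RNG substream index (use different values for the two channels
        so their noise is independent under one seed).
    """
    config.validate()
    rng = _rng(config.seed, stream)
    px = config.pixel_size
    n_px = int(np.ceil(config.field_size_nm / px))
    sigma = config.psf_sigma
    half = int(np.ceil(5.0 * sigma / px)) + 1
    movie = np.empty((config.n_frames, n_px, n_px), dtype=np.uint16)

    frames = localizations["frame"].to_numpy(int) if len(localizations) else np.array([], int)
    xs = localizations["x_nm"].to_numpy(float) if len(localizations) else np.array([])
    ys = localizations["y_nm"].to_numpy(float) if len(localizations) else np.array([])
    photons = (
        localizations["intensity"].to_numpy(float) if len(localizations) else np.array([])
    )

    for f in range(config.n_frames):
        mu = np.full((n_px, n_px), config.background_photons, dtype=float)
        for k in np.nonzero(frames == f)[0]:
            cx, cy = xs[k], ys[k]
            j0 = max(0, int(cx / px) - half)
            j1 = min(n_px, int(cx / px) + half + 1)
            i0 = max(0, int(cy / px) - half)
            i1 = min(n_px, int(cy / px) + half + 1)
            if j0 >= j1 or i0 >= i1:
                continue  # emitter entirely outside the frame
            wx = _pixel_weights(cx, np.arange(j0, j1 + 1) * px, sigma)
            wy = _pixel_weights(cy, np.arange(i0, i1 + 1) * px, sigma)
            mu[i0:i1, j0:j1] += photons[k] * np.outer(wy, wx)
        counts = rng.poisson(mu).astype(float)
        img = config.camera_gain * counts
        if config.read_noise > 0:
            img = img + rng.standard_normal(img.shape) * config.read_noise
        movie[f] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return movie


def make_fiducial_set(
    transform: AffineTransform2D,
    n_markers: int = 50,
    marker_noise_sigma: float = 3.0,
    seed: int = 0,
    field_size_nm: float = 20000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a paired fiducial-marker calibration set.

    Channel-A marker positions are uniform over the field; channel-B
    positions are ``transform(A)`` plus isotropic Gaussian noise of std
    ``marker_noise_sigma`` (nm), emulating the localization error of bright
    fiducial beads imaged in both channels.
    """
    if n_markers < 3:
        raise IdentifiabilityError("need >= 3 fiducial markers for an affine fit")
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.0, field_size_nm, size=(n_markers, 2))
    b = transform.apply(a)
    if marker_noise_sigma > 0:
        b = b + rng.standard_normal(b.shape) * marker_noise_sigma

    def _table(xy: np.ndarray, channel: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": "fiducial",
                "channel": channel,
                "frame": 0,
                "x_nm": xy[:, 0],
                "y_nm": xy[:, 1],
                "intensity": 10000.0,
                "background": 0.0,
            }
        )[LOC_COLUMNS]

    return _table(a, "A"), _table(b, "B")
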