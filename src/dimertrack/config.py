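"""Configuration dataclasses for simulation and analysis.

All lengths are nm unless a field name says otherwise (``field_size_um``),
times are seconds, diffusion constants µm²/s, probabilities per frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .register import AffineTransform2D

__all__ = [
    "COMPLEX_SPECIES",
    "SimulationConfig",
    "TrackingParams",
    "DimerCallParams",
    "DynamicsParams",
]

#: Protomer composition of each complex state.  "A"/"B" are the two spectral
#: channels of the labels.  The hexamer is a 6:6-style array of six B-labelled
#: protomers sharing one centre, so a fully labelled hexamer carries 6x the
#: monomer B-channel intensity (3x a BB homodimer).
COMPLEX_SPECIES: dict[str, tuple[str, ...]] = {
    "monomer_a": ("A",),
    "monomer_b": ("B",),
    "homodimer_aa": ("A", "A"),
    "homodimer_bb": ("B", "B"),
    "heterodimer_ab": ("A", "B"),
    "ternary_aabb": ("A", "A", "B", "B"),
    "hexamer_b6": ("B",) * 6,
}

#: Diffusion-constant class of each complex state.
COMPLEX_DIFFUSION_CLASS: dict[str, str] = {
    "monomer_a": "free",
    "monomer_b": "free",
    "homodimer_aa": "dimer",
    "homodimer_bb": "dimer",
    "heterodimer_ab": "dimer",
    "ternary_aabb": "oligomer",
    "hexamer_b6": "oligomer",
}


def _default_mix() -> dict[str, float]:
    return {"monomer_a": 0.4, "monomer_b": 0.4, "heterodimer_ab": 0.2}


def _default_chromatic() -> AffineTransform2D:
    # representative dual-view splitter offset: translation + 0.1% scale
    return AffineTransform2D(np.eye(2) * 1.001, np.array([120.0, -80.0]))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dual-colour TIRF experiment.

    The defaults emulate the acquisition regime of the live-cell receptor
    dimerization measurements: 150-frame movies at 32 ms/frame, single-
    molecule surface densities, Brownian mobility in the 0.01–0.3 µm²/s
    range with an immobile subpopulation, sub-stoichiometric labelling,
    blinking/bleaching and 10–30 nm localization error.
    """

    field_size_um: float = 20.0
    n_frames: int = 150
    frame_interval: float = 0.032
    #: complexes per µm² of membrane (all states combined)
    density: float = 0.2
    complex_mix: dict[str, float] = field(default_factory=_default_mix)
    d_free: float = 0.10
    d_dimer: float = 0.07
    d_oligomer: float = 0.05
    immobile_fraction: float = 0.1
    #: per-axis std of each protomer's excursion around its complex centre
    bond_jitter_sigma: float = 10.0
    label_prob_a: float = 0.8
    label_prob_b: float = 0.8
    detect_prob: float = 0.9
    blink_off_prob: float = 0.05
    blink_on_prob: float = 0.5
    bleach_prob: float = 0.003
    loc_error_sigma: float = 15.0
    #: coefficient of variation of per-frame single-label intensity
    intensity_cv: float = 0.2
    #: expected spurious localizations per frame per channel (whole field)
    false_positive_rate: float = 0.5
    #: map from true (channel-A) coordinates to the channel-B camera frame
    chromatic_transform: AffineTransform2D = field(default_factory=_default_chromatic)
    # rendering parameters
    photons_mean: float = 2000.0
    psf_sigma: float = 150.0
    pixel_size: float = 100.0
    camera_gain: float = 2.0
    read_noise: float = 1.5
    background_photons: float = 10.0
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def field_size_nm(self) -> float:
        return self.field_size_um * 1000.0

    @property
    def d_for_class(self) -> dict[str, float]:
        return {"free": self.d_free, "dimer": self.d_dimer, "oligomer": self.d_oligomer}

    def validate(self) -> "SimulationConfig":
        if self.field_size_um <= 0:
            raise ConfigurationError("field_size_um must be > 0")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.density < 0:
            raise ConfigurationError("density must be >= 0")
        unknown = set(self.complex_mix) - set(COMPLEX_SPECIES)
        if unknown:
            raise ConfigurationError(f"unknown complex states: {sorted(unknown)}")
        props = np.array(list(self.complex_mix.values()), dtype=float)
        if len(props) == 0 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-6:
            raise ConfigurationError(
                "complex_mix proportions must be >= 0 and sum to 1"
            )
        for name in (
            "immobile_fraction", "label_prob_a", "label_prob_b", "detect_prob",
            "blink_off_prob", "blink_on_prob", "bleach_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("d_free", "d_dimer", "d_oligomer", "bond_jitter_sigma",
                     "loc_error_sigma", "intensity_cv", "false_positive_rate",
                     "photons_mean", "psf_sigma", "pixel_size", "camera_gain",
                     "read_noise", "background_photons"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        return self

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **kwargs).validate()

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromatic_transform"] = self.chromatic_transform.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "chromatic_transform" in d and not isinstance(
            d["chromatic_transform"], AffineTransform2D
        ):
            d["chromatic_transform"] = AffineTransform2D.from_dict(
                d["chromatic_transform"]
            )
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class TrackingParams:
    """Single-channel linking and immobile-filter parameters."""

    max_disp: float = 500.0      # nm, hard linking radius per frame
    max_gap: int = 1             # frames closable by gap closing
    rg_threshold: float = 75.0   # nm, radius-of-gyration immobile cutoff
    min_lifetime: int = 10       # frames, minimum lifetime for immobile call

    def validate(self) -> "TrackingParams":
        if self.max_disp <= 0 or self.rg_threshold <= 0 or self.min_lifetime <= 0:
            raise ConfigurationError("tracking thresholds must be positive")
        if self.max_gap < 0:
            raise ConfigurationError("max_gap must be >= 0")
        return self


@dataclass
class DimerCallParams:
    """Two-colour co-localization and dimer-calling parameters.

    The defaults are the published procedure constants: 100 nm cutoff radius
    and >= 10 co-diffusing frames for a dimer call.
    """

    cutoff_radius: float = 100.0
    min_codiffusion_frames: int = 10
    cotrack_max_disp: float = 500.0
    cotrack_max_gap: int = 1
    #: qualifying single-colour tracks must have lifetime strictly above this
    min_track_lifetime: int = 10

    def validate(self) -> "DimerCallParams":
        if self.cutoff_radius <= 0:
            raise ConfigurationError("cutoff_radius must be > 0")
        if self.min_codiffusion_frames < 1:
            raise ConfigurationError("min_codiffusion_frames must be >= 1")
        if self.cotrack_max_disp <= 0 or self.cotrack_max_gap < 0:
            raise ConfigurationError("co-tracking linker parameters invalid")
        return self


@dataclass
class DynamicsParams:
    """MSD / diffusion analysis parameters."""

    fit_lags: tuple[int, ...] = (1, 2, 3, 4, 5)
    d_immobile_threshold: float = 0.01  # µm²/s
    min_track_lifetime: int = 10        # frames, strict lower bound

    def validate(self) -> "DynamicsParams":
        if len(self.fit_lags) < 2:
            raise ConfigurationError("need >= 2 fit lags")
        if any(l < 1 for l in self.fit_lags):
            raise ConfigurationError("fit lags must be >= 1")
        return self
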