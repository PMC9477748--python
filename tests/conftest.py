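import numpy as np
import pytest

from dimertrack import AffineTransform2D, SimulationConfig, simulate_cell


def noiseless_overrides(**extra):
    """Generator settings that switch off photophysics and registration."""
    base = dict(
        label_prob_a=1.0, label_prob_b=1.0, detect_prob=1.0,
        blink_off_prob=0.0, bleach_prob=0.0, false_positive_rate=0.0,
        chromatic_transform=AffineTransform2D.identity(),
    )
    base.update(extra)
    return base


@pytest.fixture(scope="session")
def hetero_cell():
    """One simulated cell rich in heterodimers, noiseless photophysics."""
    cfg = SimulationConfig(
        seed=42, density=0.2,
        complex_mix={"monomer_a": 0.3, "monomer_b": 0.3, "heterodimer_ab": 0.4},
        immobile_fraction=0.0,
        **noiseless_overrides(),
    )
    return cfg, simulate_cell(cfg)


def localization_complex_map(locs, id_map, channel):
    """(frame, x, y) -> (complex_id, complex_type) lookup for one channel."""
    sub = id_map[id_map["channel"] == channel]
    xs = locs["x_nm"].to_numpy(float)
    ys = locs["y_nm"].to_numpy(float)
    fs = locs["frame"].to_numpy(int)
    return {
        (int(fs[r]), round(float(xs[r]), 4), round(float(ys[r]), 4)): (int(c), str(t))
        for r, c, t in zip(
            sub["row"].to_numpy(int),
            sub["complex_id"].to_numpy(int),
            sub["complex_type"].to_numpy(object),
        )
    }
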