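import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glusense.simulate import ScenarioConfig

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def scenario() -> ScenarioConfig:
    return ScenarioConfig(seed=7)


@pytest.fixture
def glusor_truth() -> dict:
    """Published sensor characteristics used as simulation truths."""
    return {"Rmin": 1.0, "Rmax": 7.46, "Kd_uM": 60.68, "hill_p": 1.0}


def brute_force_distribution(atom_vectors) -> np.ndarray:
    """Independent oracle: per-atom isotope-state enumeration.

    Accumulates P(total mass shift) by walking atoms one at a time and
    branching over each atom's isotope states — no FFT/convolve primitives.
    """
    probs = {0: 1.0}
    for vec in atom_vectors:
        nxt: dict[int, float] = {}
        for shift, p in probs.items():
            for i, pi in enumerate(vec):
                if pi == 0.0:
                    continue
                nxt[shift + i] = nxt.get(shift + i, 0.0) + p * pi
        probs = nxt
    out = np.zeros(max(probs) + 1)
    for shift, p in probs.items():
        out[shift] = p
    return out
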