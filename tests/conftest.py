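import numpy as np
import pytest

from mihawk.epochs import EEGEpoch
from mihawk.synth import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def separable_dataset():
    """Strongly separable synthetic MI epochs (shared across tests)."""
    cfg = SynthConfig(erd_depth=0.8, snr_db=10.0, seed=7)
    return generate_dataset(cfg, 40), cfg


@pytest.fixture
def small_epoch(rng):
    return EEGEpoch(data=rng.standard_normal((3, 512)), fs=250.0,
                    label="left_hand", channel_names=["C3", "Cz", "C4"])


class ScriptedRng:
    """Deterministic stand-in for a Generator: returns scripted values.

    ``uniform`` pops from ``uniforms``; ``standard_normal`` pops from
    ``normals`` (scalars are broadcast to the requested size).
    """

    def __init__(self, uniforms=(), normals=()):
        self.uniforms = list(uniforms)
        self.normals = list(normals)

    def _pop(self, queue, size):
        val = queue.pop(0)
        if size is None:
            return val
        shape = size if isinstance(size, tuple) else (size,)
        return np.broadcast_to(np.asarray(val, dtype=float), shape).copy()

    def uniform(self, low=0.0, high=1.0, size=None):
        u = self._pop(self.uniforms, size)
        return low + u * (high - low)

    def standard_normal(self, size=None):
        return self._pop(self.normals, size)


@pytest.fixture
def scripted_rng():
    return ScriptedRng
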