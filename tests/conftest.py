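import numpy as np
import pytest

from ecgresnet.record_io import AamiClass, BeatAnnotation, EcgRecord
from ecgresnet.synthetic_ecg import NoiseConfig, RhythmConfig, generate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_record():
    """A 10-second two-channel record with five annotated beats."""
    rng = np.random.default_rng(7)
    sig = 0.5 * np.sin(np.linspace(0, 40 * np.pi, 3600))
    signal = np.vstack([sig, 0.3 * rng.standard_normal(3600)])
    record = EcgRecord("T01", 360.0, signal, ["MLII", "V5"])
    annotations = [
        BeatAnnotation.from_symbol(i, s)
        for i, s in [(300, "N"), (900, "V"), (1500, "N"), (2400, "A"), (3300, "N")]
    ]
    return record, annotations


@pytest.fixture
def synthetic_clean():
    """A 30-second noise-free synthetic record."""
    return generate_record(
        rhythm=RhythmConfig(duration=30.0, seed=11),
        noise=NoiseConfig.silent(),
    )
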