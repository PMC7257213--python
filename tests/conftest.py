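import numpy as np
import pytest

from aneucad.config import PipelineConfig
from aneucad.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def test_cfg():
    return PipelineConfig.test_scale()


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic 64^3 phantom (volume, labels, record)."""
    return generate_phantom(PhantomSpec(rng_seed=3))


@pytest.fixture(scope="session")
def segmented_phantom(phantom_case, test_cfg):
    """Phantom plus the full step-one output (shared; read-only)."""
    from aneucad import detect

    vol, lab, rec = phantom_case
    pre = detect.preprocess_volume(vol, test_cfg)
    stripped, vessel_mask, model, mesh, voi = detect.segment_stage(pre, test_cfg)
    return {
        "vol": vol,
        "lab": lab,
        "rec": rec,
        "pre": pre,
        "stripped": stripped,
        "vessel_mask": vessel_mask,
        "model": model,
        "mesh": mesh,
        "voi": voi,
    }
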