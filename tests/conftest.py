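import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_session():
    """Small deterministic synthetic session shared by read-only tests."""
    from prepcirc.synth import Connection, GenConfig, UnitSpec, generate_session

    cfg = GenConfig(
        n_trials=8,
        photo_fraction=0.4,
        roster=[
            UnitSpec("t1", "ALM", "type1"),
            UnitSpec("t3", "ALM", "type3"),
            UnitSpec("pc0", "CRUS1", "pc",
                     tuning={"kind": "linear", "a": 40.0, "b": 0.2}, suppression=0.3),
            UnitSpec("dn0", "DN", "dn", baseline=25.0, amp=10.0),
            UnitSpec("cf0", "CRUS1", "cf", baseline=1.0, fwhm_ms=0.8),
        ],
        connections=[Connection("pc0", "dn0", 0.5)],
    )
    session, truth, _ = generate_session(cfg, seed=7, with_waveforms=True)
    return session, truth, cfg
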