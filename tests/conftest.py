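from dataclasses import replace

import numpy as np
import pytest

from hflpol.synthetic import SimConfig

#: Map from (meridian, offset sign) to the manifest scan key.
SCAN_KEYS = {("horizontal", 1): "h_plus", ("horizontal", -1): "h_minus",
             ("vertical", 1): "v_plus", ("vertical", -1): "v_minus"}


def scans_dict(bundle) -> dict:
    """Re-shape a SubjectBundle's scans like a manifest entry for the stages."""
    return {SCAN_KEYS[k]: {"meta": s.meta, "anterior": s.anterior,
                           "posterior": s.posterior, "os_band": s.os_band}
            for k, s in bundle.scans.items()}


@pytest.fixture(scope="session")
def base_cfg() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def noiseless_cfg() -> SimConfig:
    return replace(SimConfig(), noise_sd=0.0, trace_jitter_px=0.0,
                   corneal_between_subject_sd=0.0)


@pytest.fixture(scope="session")
def fixed_map_noiseless(noiseless_cfg):
    from hflpol.synthetic import simulate_retardation_map
    return simulate_retardation_map(noiseless_cfg, "fixed", 0)


@pytest.fixture(scope="session")
def variable_map_noiseless(noiseless_cfg):
    from hflpol.synthetic import simulate_retardation_map
    return simulate_retardation_map(noiseless_cfg, "variable", 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
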