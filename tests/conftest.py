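"""Shared fixtures: one small noiseless and one small noisy synthetic study."""

from __future__ import annotations

import pytest

from mirkd.pipeline import run_study
from mirkd.simulate import SimulationConfig, build_reference


def small_config(seed: int = 11) -> SimulationConfig:
    return SimulationConfig(seed=seed, n_pairs=3, n_loci=12, library_size=500)


@pytest.fixture(scope="session")
def reference():
    return build_reference(small_config())


@pytest.fixture(scope="session")
def noiseless_study(tmp_path_factory):
    cfg = small_config().noiseless()
    out = run_study(cfg, tmp_path_factory.mktemp("noiseless"))
    out["config"] = cfg
    return out


@pytest.fixture(scope="session")
def noisy_study(tmp_path_factory):
    cfg = small_config(seed=13)
    out = run_study(cfg, tmp_path_factory.mktemp("noisy"))
    out["config"] = cfg
    return out
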