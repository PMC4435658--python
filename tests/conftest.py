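import numpy as np
import pandas as pd
import pytest

from tvcm import BasisSpec, TermSpec, VCMSpec
from tvcm.synthetic import generate, preset


def small_spec(cfg, k=8, family="binomial", response="smoker"):
    """Model spec with all covariates constant, small basis for speed."""
    return VCMSpec(
        response=response,
        family=family,
        terms=tuple(TermSpec(c.name, "constant", c.reference)
                    for c in cfg.covariates),
        modifier="wave",
        basis=BasisSpec(n_basis=k, degree=3, domain=(1.0, float(cfg.n_waves))),
        penalty_order=2,
    )


@pytest.fixture(scope="session")
def bench_config():
    return preset("bench-small", monthly_n=60)


@pytest.fixture(scope="session")
def bench_data(bench_config):
    return generate(bench_config, seed=42)


@pytest.fixture(scope="session")
def bench_spec(bench_config):
    return small_spec(bench_config)


@pytest.fixture(scope="session")
def null_config():
    return preset("bench-null", monthly_n=60)


@pytest.fixture(scope="session")
def null_data(null_config):
    return generate(null_config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gaussian_frame():
    """Small continuous-response table with a binary group and smooth trend."""
    rng = np.random.default_rng(3)
    n_waves, per = 40, 12
    wave = np.repeat(np.arange(1, n_waves + 1), per)
    group = rng.choice(["a", "b"], size=wave.size)
    u = (wave - 1) / (n_waves - 1)
    y = (
        0.5
        + 1.2 * (group == "b")
        + np.sin(2 * np.pi * u) * (group == "b")
        - 0.8 * np.sin(2 * np.pi * u) * (group == "a")
        + rng.normal(0, 0.5, wave.size)
    )
    return pd.DataFrame({"wave": wave.astype(float), "group": group, "y": y})
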