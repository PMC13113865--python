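import numpy as np
import pytest

from psmcfnr import (
    SampleMeta,
    ScaledTrajectory,
    ScalingParams,
)
from psmcfnr.synthetic import DemographyScenario, generate_trajectory


@pytest.fixture
def scaling_params():
    return ScalingParams(mu=2.5e-8, gen_time=25.0, bin_size=100.0)


@pytest.fixture
def step_trajectory():
    """Two-segment step: Ne 10,000 from 0, Ne 20,000 from 100 kya."""
    return ScaledTrajectory(
        np.array([0.0, 1.0e5]),
        np.array([1.0e4, 2.0e4]),
        SampleMeta("step", 20.0),
    )


@pytest.fixture
def bottleneck_trajectory():
    return generate_trajectory(DemographyScenario("bottleneck"), seed=11)


@pytest.fixture
def psmc_text():
    """A minimal three-round PSMC output with records to skip."""
    return (
        "CC\tcomment line\n"
        "MM\tis_decoding:0\n"
        "RD\t0\n"
        "TR\t0.04\t0.0002\n"
        "RS\t0\t0\t1.0\t0\t0\n"
        "RS\t1\t0.1\t1.5\t0\t0\n"
        "PA\t-1 0\n"
        "//\n"
        "RD\t1\n"
        "TR\t0.045\t0.0002\n"
        "RS\t0\t0\t1.0\t0\t0\n"
        "RS\t1\t0.1\t1.8\t0\t0\n"
        "//\n"
        "RD\t2\n"
        "TR\t0.05\t0.0002\n"
        "RS\t0\t0\t1.0\t0\t0\n"
        "RS\t1\t0.1\t2.0\t0\t0\n"
        "//\n"
    )


@pytest.fixture
def psmc_file(tmp_path, psmc_text):
    path = tmp_path / "sample.psmc"
    path.write_text(psmc_text)
    return path
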