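import numpy as np
import pytest

from pursuitkit.trajectories import (
    SumOfSinesSpec,
    AxisSines,
    SumOfSinesTrajectory,
    default_paths,
    make_trajectory,
)


@pytest.fixture(scope="session")
def paths():
    return default_paths()


@pytest.fixture(scope="session")
def ss_traj(paths):
    """Analytic sum-of-sines trajectory for path 2."""
    return SumOfSinesTrajectory(paths[2])


@pytest.fixture(scope="session")
def cs_traj(paths):
    return make_trajectory(paths[2], "cs")


@pytest.fixture
def circle_spec():
    """Equal-amplitude quadrature pair: a circle, already constant speed."""
    return SumOfSinesSpec(
        period=4.5,
        x=AxisSines(a1=8.0, phi1=np.pi / 2, k=2, a2=0.0, phi2=0.0),
        y=AxisSines(a1=8.0, phi1=0.0, k=2, a2=0.0, phi2=0.0),
    )


@pytest.fixture
def single_axis_spec():
    """Pure fundamental sinusoid along x (10 deg amplitude)."""
    return SumOfSinesSpec(
        period=4.5,
        x=AxisSines(a1=10.0, phi1=0.0, k=2, a2=0.0, phi2=0.0),
        y=AxisSines(a1=0.0, phi1=0.0, k=2, a2=0.0, phi2=0.0),
    )
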