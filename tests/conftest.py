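import numpy as np
import pytest

import flysteer as fs


@pytest.fixture(scope="session")
def turning_session():
    """20-s noise-free session with one right and one left commanded bout."""
    schedule = (
        fs.CommandedBout(onset=4.0, duration=0.5, direction="right", magnitude=100.0, forward_delta=-3.0),
        fs.CommandedBout(onset=9.0, duration=0.45, direction="left", magnitude=80.0, forward_delta=3.0),
    )
    cfg = fs.SimulationConfig(duration=20.0, seed=7, turn_schedule=schedule)
    return fs.simulate_walking(cfg)


@pytest.fixture(scope="session")
def turning_kinematics(turning_session):
    frame, steps, cont = fs.leg_analysis(turning_session.tracked)
    return frame, steps, cont


@pytest.fixture(scope="session")
def quiet_session():
    """12-s noise-free session with no commanded turns."""
    return fs.simulate_walking(fs.SimulationConfig(duration=12.0, seed=11))
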