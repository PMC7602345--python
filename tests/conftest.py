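import numpy as np
import pytest

from burnsim.accuracy_stats import load_rater_study
from burnsim.hemodynamics import BurnSimulator
from burnsim.lund_browder import BodyRegion, LBChart, load_adult_chart
from burnsim.treatment import run_protocol


@pytest.fixture(scope="session")
def adult_chart():
    return load_adult_chart()


@pytest.fixture(scope="session")
def toy_chart():
    """Three-region chart with fractions 0.5 / 0.3 / 0.2 for hand arithmetic."""
    return LBChart(
        regions=(
            BodyRegion("torso", 0.5),
            BodyRegion("legs", 0.3),
            BodyRegion("arms", 0.2),
        ),
        age_band="toy",
    )


@pytest.fixture(scope="session")
def rater_records():
    return load_rater_study()


@pytest.fixture(scope="session")
def simulator():
    return BurnSimulator()


@pytest.fixture(scope="session")
def untreated_runs(simulator):
    """Untreated scenario time series keyed by TBSA percent."""
    return {
        0: simulator.run(0.0, 48.0),
        10: simulator.run(0.10, 24.0),
        25: simulator.run(0.25, 24.0),
        40: simulator.run(0.40, 24.0),
    }


@pytest.fixture(scope="session")
def treated_25(simulator):
    return run_protocol(25.0, 24.0, simulator=simulator)


def interp(df, col, hour):
    return float(np.interp(hour, df["time_h"], df[col]))
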