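import numpy as np
import pandas as pd
import pytest

import oxytherm as ox


def cone_curve(radius_m: float = 100.0, zmax: float = 10.0, dz: float = 0.1,
               **kwargs) -> ox.HypsographicCurve:
    """Inverted cone: apex at zmax. A(z) = pi R^2 (1 - z/zmax)^2."""
    z = np.round(np.arange(0.0, zmax + dz / 2, dz), 6)
    areas = np.pi * radius_m**2 * (1.0 - z / zmax) ** 2
    return ox.HypsographicCurve(z, areas, **kwargs)


def bowl_curve(radius_m: float = 10.0, dz: float = 0.1, **kwargs) -> ox.HypsographicCurve:
    """Hemispherical bowl of radius R (zmax = R). A(z) = pi (R^2 - z^2)."""
    z = np.round(np.arange(0.0, radius_m + dz / 2, dz), 6)
    areas = np.pi * (radius_m**2 - z**2)
    return ox.HypsographicCurve(z, areas, **kwargs)


@pytest.fixture(scope="session")
def lake_curve():
    return ox.lake658_like_hypsography()


@pytest.fixture(scope="session")
def study_fields(lake_curve):
    """The default study-year scenario: full season of fields + ground truth."""
    return ox.simulate_fields(ox.LakeScenario(), curve=lake_curve)


@pytest.fixture(scope="session")
def study_budgets(study_fields):
    t_daily = ox.daily_mean(study_fields.t_hourly)
    budgets = ox.compute_budgets(t_daily, study_fields.do_daily, study_fields.curve)
    return t_daily, budgets


@pytest.fixture(scope="session")
def summer_fields(lake_curve):
    """A short mid-summer scenario for telemetry-scale tests."""
    sc = ox.LakeScenario(
        start_date="2015-07-01",
        phases=[ox.PhaseSpec("moderate", 6, 0.30, 0.20),
                ox.PhaseSpec("high", 6, 0.08, 0.03)],
    )
    return ox.simulate_fields(sc, curve=lake_curve)
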