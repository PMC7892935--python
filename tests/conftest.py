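"""Shared fixtures: reference-condition simulations are session-scoped."""
import pytest

from injeradry import (
    INJERA_COMPOSITION,
    AirState,
    DryingConditions,
    SampleGeometry,
    SolverSettings,
    simulate,
)


def reference_conditions(T_air: float, u_air: float, rh: float,
                         **overrides) -> DryingConditions:
    return DryingConditions(air=AirState(T_air=T_air, u_air=u_air, RH=rh),
                            **overrides)


@pytest.fixture(scope="session")
def composition():
    return INJERA_COMPOSITION


@pytest.fixture(scope="session")
def curve_333(composition):
    """Simulated drying curve at 333.15 K, 0.5 m/s, RH 11 % (defaults)."""
    return simulate(composition, SampleGeometry(),
                    reference_conditions(333.15, 0.5, 11.0))


@pytest.fixture(scope="session")
def curve_323(composition):
    """Simulated drying curve at 323.15 K, 0.5 m/s, RH 15.7 %."""
    return simulate(composition, SampleGeometry(),
                    reference_conditions(323.15, 0.5, 15.7))


@pytest.fixture(scope="session")
def default_settings():
    return SolverSettings()
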