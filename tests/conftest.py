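import pytest

from ionex import (
    Condition,
    ExchangeReaction,
    GeometryContext,
    ModelSpec,
    SurfaceSite,
    load_scenario,
)
from ionex.scenarios import COMPONENTS, SIMULATION_GEOMETRY


@pytest.fixture(scope="session")
def sim_geometry() -> GeometryContext:
    """Idealized loading: 100 m^2/L, so gamma (umol/m^2) = 10 * mmol/L."""
    return SIMULATION_GEOMETRY


@pytest.fixture(scope="session")
def goethite_geometry() -> GeometryContext:
    return GeometryContext(surface_area=29.50, solids_conc=3.43)


def single_site_cl_model(pk: float = -8.0, gamma_max: float = 2.0) -> ModelSpec:
    """One site, one chloride coadsorption reaction SOH + H+ + Cl- <=> SOH2Cl."""
    return ModelSpec(
        sites=[SurfaceSite(name="S", gamma_max=gamma_max)],
        components=COMPONENTS,
        surface_reactions=[
            ExchangeReaction(site="S", n_soh=1, consumed={"H": 1, "Cl": 1},
                             product="SOH2Cl", occupancy=1, pK=pk)
        ],
        geometry=SIMULATION_GEOMETRY,
    )


@pytest.fixture
def cl_model() -> ModelSpec:
    return single_site_cl_model()


@pytest.fixture(scope="session")
def fig2_fixed():
    return load_scenario("fig2_fixedCl")


@pytest.fixture(scope="session")
def fig2_free():
    return load_scenario("fig2_noCl")


def condition(ph: float, totals: dict, geometry=SIMULATION_GEOMETRY, cid: str = "c") -> Condition:
    return Condition(id=cid, pH=ph, totals=totals, geometry=geometry)
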