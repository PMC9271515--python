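import pytest

from trialaccess import (
    GridPoint,
    ImpedanceSpec,
    IncidenceTable,
    PopulationGrid,
    TrialSite,
)


@pytest.fixture
def unit_spec():
    """Impedance with a fixed 1 km floor so hand calculations are exact."""
    return ImpedanceSpec(beta=0.5, distance_floor_km=1.0)


@pytest.fixture
def toy_country():
    """Three populated points on the equator and one incidence entry."""
    grid = PopulationGrid(
        [
            GridPoint("a", 0.0, 0.0, 200_000, "Toy"),
            GridPoint("b", 0.0, 1.0, 100_000, "Toy"),
            GridPoint("c", 0.0, 2.0, 50_000, "Toy"),
        ],
        spacing_deg=1.0,
    )
    incidence = IncidenceTable({"Toy": 500.0})
    sites = [TrialSite("s1", 0.0, 0.0, 2019, 4, "Toy")]
    return grid, sites, incidence
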