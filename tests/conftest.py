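import numpy as np
import pandas as pd
import pytest

from reactionome import SampleTable, TemperatureGrid, default_grid


@pytest.fixture(scope="session")
def grid() -> TemperatureGrid:
    return default_grid()


@pytest.fixture(scope="session")
def full_grid() -> TemperatureGrid:
    """The 12-level grid with nothing excluded."""
    return TemperatureGrid(tuple(np.arange(12) * 3.5))


def make_samples(grid: TemperatureGrid,
                 species=("A_carolinensis", "A_picea")) -> SampleTable:
    rows = [
        {"sample_id": f"{sp}_{t:04.1f}", "species": sp, "temperature": t}
        for sp in species for t in grid.temperatures
    ]
    return SampleTable(pd.DataFrame(rows), grid=grid)


@pytest.fixture(scope="session")
def samples(grid) -> SampleTable:
    """2 species × 12 temperatures, 7 °C flagged non-retained."""
    return make_samples(grid)


@pytest.fixture(scope="session")
def design_y(samples):
    """Factory: log-expression over retained samples from per-species
    quadratics (a0, a1, a2) for reference species A and for species B."""
    rows = samples.retained_rows

    def build(poly_a, poly_b=None):
        if poly_b is None:
            poly_b = poly_a
        labels = samples.species_labels
        t = rows["temperature"].to_numpy()
        is_b = (rows["species"] == labels[1]).to_numpy()
        ya = poly_a[0] + poly_a[1] * t + poly_a[2] * t * t
        yb = poly_b[0] + poly_b[1] * t + poly_b[2] * t * t
        return np.where(is_b, yb, ya)

    return build
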