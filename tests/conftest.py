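import numpy as np
import pytest

from picomass import CantileverModel, CellMechanicalModel


@pytest.fixture
def hela_cell() -> CellMechanicalModel:
    """Population-average HeLa-like cell: 3.14 ng, 14.4 kHz, Q 0.3."""
    return CellMechanicalModel.from_modal(3.14e-12, 14.4e3, 0.3)


@pytest.fixture
def cantilever_75k() -> CantileverModel:
    """A 75 kHz lever of the 60-80 kHz class, liquid Q ~ 3."""
    return CantileverModel(spring_constant=8.0, eigenfrequency=75e3, quality_factor=3.0)


@pytest.fixture
def stiff_cantilever_75k(hela_cell) -> CantileverModel:
    """75 kHz lever with mass ratio 1e-3 against the HeLa cell and Q 100
    (the regime where the sweep pipeline matches the closed form)."""
    m_cant = hela_cell.mass / 1e-3
    k = (2 * np.pi * 75e3) ** 2 * m_cant
    return CantileverModel(spring_constant=k, eigenfrequency=75e3, quality_factor=100.0)
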