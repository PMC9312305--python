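import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cylbrachy import (
    CylinderApplicator, DwellPosition, SourceSpec,
    generate_dwell_positions, generate_reference_lines,
)


@pytest.fixture(scope="session")
def unit_point():
    return SourceSpec.unit_kernel("point")


@pytest.fixture(scope="session")
def unit_line():
    return SourceSpec.unit_kernel("line", active_length=0.35)


@pytest.fixture(scope="session")
def ir192():
    return SourceSpec.generic_ir192()


@pytest.fixture(scope="session")
def origin_dwell():
    return DwellPosition(index=0, position=np.zeros(3), orientation=np.array([0.0, 0.0, 1.0]))


@pytest.fixture(scope="session")
def cyl3():
    return CylinderApplicator(diameter=3.0)


@pytest.fixture(scope="session")
def cyl3_dwells(cyl3):
    return generate_dwell_positions(cyl3)


@pytest.fixture(scope="session")
def cyl3_refs(cyl3):
    return generate_reference_lines(cyl3)
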