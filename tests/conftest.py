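import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from molboolean.design import assembled_circle, load_design_oligos
from molboolean.simulate import GeometryConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: compact geometry for unit tests (small cells, small frames)
SMALL_GEOMETRY = GeometryConfig(
    shape=(256, 256),
    nucleus_radius_px=(8.0, 10.0),
    cyto_scale=(1.8, 2.2),
    membrane_width_px=2,
)


@pytest.fixture(scope="session")
def oligos():
    return load_design_oligos()


@pytest.fixture(scope="session")
def circle(oligos):
    return assembled_circle(oligos)


@pytest.fixture(scope="session")
def arms(oligos):
    return {"A": oligos["arm_A"], "B": oligos["arm_B"]}


@pytest.fixture(scope="session")
def tags(oligos):
    return {"A": oligos["tag_A"], "B": oligos["tag_B"]}


def molecules_frame(classes, cell_id=1):
    """Minimal molecule table for event-model tests (positions at origin)."""
    return pd.DataFrame(
        {
            "molecule_id": np.arange(len(classes)),
            "cell_id": cell_id,
            "mol_class": classes,
            "compartment": "cytoplasm",
            "x_nm": 0.0,
            "y_nm": 0.0,
        }
    )
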