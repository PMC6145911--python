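import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from osteoscreen.model import PlateLayout, Role, WellAnnotation
from osteoscreen.simulate import SimulationConfig


@pytest.fixture
def small_sim_config():
    """Scaled-down simulation: few cells, small fields, fast to render."""
    return SimulationConfig(
        baseline_cells_per_well=120,
        n_fields=2,
        field_shape=(256, 256),
        read_noise_sd=2.0,
        spot_intensity_cv=0.10,
        noise_cv=0.05,
        n_replicates=1,
        seed=42,
    )


@pytest.fixture
def mini_layout():
    """Six-well layout: 2 NT, 2 library genes, kif11, mock."""
    return PlateLayout(
        plate_id="mini",
        wells={
            "A1": WellAnnotation(Role.NON_TARGETING),
            "A2": WellAnnotation(Role.NON_TARGETING),
            "B1": WellAnnotation(Role.LIBRARY, "GeneA"),
            "B2": WellAnnotation(Role.LIBRARY, "GeneB"),
            "C1": WellAnnotation(Role.KIF11_CONTROL, "Kif11"),
            "C2": WellAnnotation(Role.MOCK),
        },
    )


def disk_image(shape, centers, radius, amplitude, background=0.0):
    """Plain rasterized disks (no edge taper) for operator unit tests."""
    img = np.full(shape, float(background))
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] += amplitude
    return img


@pytest.fixture
def make_disk_image():
    return disk_image
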