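import numpy as np
import pytest

from beadsim import labware, synth


@pytest.fixture(scope="session")
def deck():
    return labware.default_deck()


@pytest.fixture()
def clean_camera():
    """Noise-free, blur-free camera: renders are exact disk images."""
    return synth.CameraModel(noise_sigma=0.0, blur_radius=0, seed=0)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0


@pytest.fixture(scope="session")
def opentrons_style_plate_doc():
    """A 2x3 plate in the Opentrons-flavoured dialect, built programmatically."""
    pitch = 9.0
    wells = {}
    ordering = []
    y_dim = 85.48
    for c in range(3):
        col = []
        for r in range(2):
            name = f"{'AB'[r]}{c + 1}"
            col.append(name)
            wells[name] = {
                "x": 14.38 + c * pitch,
                # source dialect measures y upward from the front edge
                "y": y_dim - (11.24 + r * pitch),
                "z": 3.55,
                "depth": 10.67,
                "totalLiquidVolume": 360,
                "diameter": 6.86,
            }
        ordering.append(col)
    return {
        "metadata": {"displayName": "toy 6-well plate", "displayCategory": "wellPlate"},
        "parameters": {"loadName": "toy_6_wellplate"},
        "ordering": ordering,
        "wells": wells,
        "dimensions": {"xDimension": 127.76, "yDimension": y_dim, "zDimension": 14.22},
        "namespace": "custom",
    }
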