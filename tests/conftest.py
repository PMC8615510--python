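import warnings

import numpy as np
import pytest

from tecquant import synthetic as sd

STUDY_DOSES = [0, 0.1, 0.25, 0.5, 1, 2.5, 5, 10]


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Generator/fit warnings (clipped branches, unit-weight fallback) are
    part of the tested contracts; keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def histology_bimodal():
    """A section with round parenchymal and elongated stromal cells."""
    spec = sd.SyntheticHistologySpec(
        seed=11, shape=(384, 384),
        n_cells={"parenchymal": 50, "stromal": 50},
    )
    rgb, comp, truth = sd.make_histology(spec)
    return spec, rgb, comp, truth


@pytest.fixture(scope="session")
def vessel_tree():
    spec = sd.SyntheticVesselSpec(seed=0)
    rgb, truth = sd.make_vessels(spec)
    return spec, rgb, truth


def ellipse_polygon_circularity(axis_ratio: float, n: int = 20000) -> float:
    """Brute-force hull circularity of an ellipse by dense polygonal
    perimeter sampling (independent of the analytic formula)."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = axis_ratio * np.cos(t), np.sin(t)
    # shoelace area and polygonal perimeter
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    perim = np.sum(np.hypot(np.diff(np.append(x, x[0])), np.diff(np.append(y, y[0]))))
    return float(4 * np.pi * area / perim**2)
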