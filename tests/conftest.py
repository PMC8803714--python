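"""Shared fixtures: phantoms are expensive, so suites are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import promisequant as pq
from promisequant.phantom import LesionSpec, SuiteVariability


@pytest.fixture(scope="session")
def lesion_phantom():
    """One default phantom with a bone and a lymph lesion (fixed seed)."""
    lesions = [
        LesionSpec(center_mm=(130, 190, 30), diameter_mm=14, peak_suv=7.0, compartment="bone"),
        LesionSpec(center_mm=(250, 140, 160), diameter_mm=14, peak_suv=6.0, compartment="lymph"),
    ]
    spec = pq.default_spec(seed=1, lesions=lesions)
    return pq.make_phantom(spec)


@pytest.fixture(scope="session")
def quiet_phantom():
    """A default phantom with no lesions (fixed seed)."""
    return pq.make_phantom(pq.default_spec(seed=2))


@pytest.fixture(scope="session")
def liver_phantoms():
    """Twenty phantoms with clean liver SUV 6.0 and the (0.3, 0.5) artifact slab."""
    return [pq.make_phantom(pq.default_spec(seed=100 + i)) for i in range(20)]


@pytest.fixture(scope="session")
def isolated_lesion_phantoms():
    """Isolated 10 mm lesions at 5:1 contrast over soft tissue, three replicates."""
    out = []
    for seed in range(3):
        lesions = [
            LesionSpec(center_mm=(250, 140, 160), diameter_mm=10, peak_suv=4.0,
                       compartment="lymph"),
            LesionSpec(center_mm=(130, 120, 200), diameter_mm=10, peak_suv=4.0,
                       compartment="lymph"),
        ]
        out.append(pq.make_phantom(pq.default_spec(seed=seed, lesions=lesions)))
    return out


@pytest.fixture(scope="session")
def adjacent_hot_phantom():
    """A 2:1-contrast lesion ~9 mm anterior of the bladder surface."""
    les = LesionSpec(center_mm=(192, 125, 90), diameter_mm=12, peak_suv=1.7,
                     compartment="lymph")
    return pq.make_phantom(pq.default_spec(seed=10, lesions=[les]))


@pytest.fixture(scope="session")
def reference_suite_50():
    """Fifty lesion-free phantoms with across-patient reference variability."""
    var = SuiteVariability(
        n_bone_lesions=(0, 0), n_lymph_lesions=(0, 0), n_prostate_lesions=(0, 0)
    )
    return pq.phantom_suite(50, var, seed=7)


def realized_max_seed(suv, mask) -> tuple[int, int, int]:
    """Index of the hottest voxel inside a ground-truth lesion mask."""
    flat = np.where(mask, suv.data, -np.inf)
    return tuple(int(i) for i in np.unravel_index(int(flat.argmax()), suv.data.shape))
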