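import numpy as np
import pytest

from sdar3d import (
    Compound,
    SyntheticSpec,
    build_fingerprint,
    build_occupancy_matrix,
    generate_synthetic_dataset,
)


@pytest.fixture
def toy3():
    """Three collinear carbons at 0/1.5/3.0 Å with shifts 10/20/30 ppm."""
    return Compound(
        id="toy3",
        element_symbols=("C", "C", "C"),
        coordinates=[[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [3.0, 0.0, 0.0]],
        carbon_shifts=(10.0, 20.0, 30.0),
        activity=None,
    )


@pytest.fixture(scope="session")
def synth_small():
    """50 compounds, 3 classes, mild noise — shared across modules."""
    spec = SyntheticSpec(n_compounds=50, noise_sd=0.2, seed=11)
    compounds, y, truth = generate_synthetic_dataset(spec)
    fps = [build_fingerprint(c) for c in compounds]
    return compounds, fps, y, truth


@pytest.fixture(scope="session")
def synth_clean():
    """Noise-free study-sized dataset with the planted linear signal."""
    spec = SyntheticSpec(noise_sd=0.0, seed=7)
    compounds, y, truth = generate_synthetic_dataset(spec)
    fps = [build_fingerprint(c) for c in compounds]
    occ = build_occupancy_matrix(fps, truth.grid)
    return compounds, fps, occ, y, truth


def random_compound(rng: np.random.Generator, n_carbons: int) -> Compound:
    """Random rigid skeleton for property tests."""
    coords = rng.uniform(0, 8.0, (n_carbons, 3))
    # nudge apart any coincident points so distances stay positive
    for i in range(1, n_carbons):
        while np.any(np.linalg.norm(coords[:i] - coords[i], axis=1) < 1e-6):
            coords[i] = rng.uniform(0, 8.0, 3)
    shifts = tuple(rng.uniform(0.0, 200.0, n_carbons))
    return Compound(
        id=f"rand{n_carbons}",
        element_symbols=("C",) * n_carbons,
        coordinates=coords,
        carbon_shifts=shifts,
    )
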