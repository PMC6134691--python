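import numpy as np
import pytest

from shapesearch.library_builder import prepare_model
from shapesearch.synthetic_shapes import ShapeSpec, make_density


@pytest.fixture(scope="session")
def dumbbell_map():
    return make_density(ShapeSpec("dumbbell", (11.0, 34.0, 5.0), name="dumbbell"))


@pytest.fixture(scope="session")
def lblock_map():
    return make_density(ShapeSpec("L_block", (26.0, 12.0, 12.0), name="lblock"))


@pytest.fixture(scope="session")
def compact_dumbbell_map():
    """A dumbbell whose content fits well inside the correlation mask."""
    return make_density(ShapeSpec("dumbbell", (6.0, 17.0, 3.0), name="small_dumbbell"))


@pytest.fixture(scope="session")
def compact_lblock_map():
    """A compact asymmetric L-block: unambiguous rotation/mirror recovery."""
    return make_density(ShapeSpec("L_block", (14.0, 7.0, 7.0), name="small_lblock"))


@pytest.fixture(scope="session")
def gaussian_blob_map():
    """An analytic Gaussian blob (sigma 6 A) centered at (3, -2, 0)."""
    ax = (np.arange(100) + 0.5) - 50.0
    xs, ys, zs = np.meshgrid(ax, ax, ax, indexing="ij")
    grid = np.exp(-((xs - 3.0) ** 2 + (ys + 2.0) ** 2 + zs**2) / (2 * 6.0**2))
    from shapesearch.volumes import DensityMap

    return DensityMap(grid=grid, origin=np.full(3, -50.0), name="blob")


@pytest.fixture(scope="session")
def resized_spheres():
    """Spheres r=10 / r=20 with radius-proportional soft edges, through the
    full normalize -> fit -> volume -> resize -> refit pipeline (K=5)."""
    out = {}
    for r, edge in ((10.0, 1.0), (20.0, 2.0)):
        m = make_density(ShapeSpec("sphere", (r,), soft_edge=edge, name=f"sphere{int(r)}"))
        resized, gmm, v_old = prepare_model(m, K=5, seed=0)
        out[int(r)] = {"input": m, "resized": resized, "gmm": gmm, "v_old": v_old}
    return out
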