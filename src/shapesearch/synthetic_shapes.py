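"""Parametric synthetic density maps emulating low-resolution EM volumes.

Each shape is the indicator function of a solid (sphere, ellipsoid,
cylinder, dumbbell, L-block or bullet) evaluated on the 100 A working
grid, smoothed by a Gaussian soft edge and optionally degraded with
clamped additive noise.  Generation is fully deterministic for a fixed
seed, so every pipeline stage can be tested without external data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from shapesearch.errors import OutOfBoxError
from shapesearch.volumes import BOX_SIZE, DensityMap

KINDS = ("sphere", "ellipsoid", "cylinder", "dumbbell", "L_block", "bullet")


@dataclass
class ShapeSpec:
    """Recipe for one synthetic map.

    ``size`` holds kind-specific parameters in Angstrom:

    - sphere: (radius,)
    - ellipsoid: (a, b, c) semi-axes
    - cylinder: (radius, length)
    - dumbbell: (lobe_radius, separation, neck_radius)
    - L_block: (arm_length, arm_width, arm_thickness)
    - bullet: (radius, length) -- cylinder capped by a hemisphere
    """

    kind: str
    size: tuple[float, ...]
    orientation: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))
    soft_edge: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        if any(s <= 0 for s in self.size):
            raise ValueError("all size parameters must be positive")
        q = np.asarray(self.orientation, dtype=np.float64).reshape(4)
        self.orientation = q / np.linalg.norm(q)

    @property
    def extent(self) -> float:
        """Diameter of the bounding sphere of the solid, Angstrom."""
        s = self.size
        if self.kind == "sphere":
            return 2 * s[0]
        if self.kind == "ellipsoid":
            return 2 * max(s)
        if self.kind == "cylinder":
            return 2 * np.hypot(s[0], s[1] / 2)
        if self.kind == "dumbbell":
            return s[1] + 2 * s[0]
        if self.kind == "L_block":
            return 2 * np.sqrt(2) * s[0]
        if self.kind == "bullet":
            return 2 * np.hypot(s[0], (s[1] + s[0]) / 2 + s[0] / 2)
        raise AssertionError


def _indicator(kind: str, size, pts: np.ndarray) -> np.ndarray:
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    if kind == "sphere":
        (r,) = size
        return x**2 + y**2 + z**2 <= r**2
    if kind == "ellipsoid":
        a, b, c = size
        return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    if kind == "cylinder":
        r, length = size
        return (x**2 + y**2 <= r**2) & (np.abs(z) <= length / 2)
    if kind == "dumbbell":
        r, sep, neck = size
        lobes = (x**2 + y**2 + (np.abs(z) - sep / 2) ** 2) <= r**2
        bar = (x**2 + y**2 <= neck**2) & (np.abs(z) <= sep / 2)
        return lobes | bar
    if kind == "L_block":
        arm, width, thick = size
        a1 = (np.abs(x) <= thick / 2) & (y >= -width / 2) & (y <= arm) & (np.abs(z) <= width / 2)
        a2 = (np.abs(x) <= thick / 2) & (z >= -width / 2) & (z <= arm) & (np.abs(y) <= width / 2)
        return a1 | a2
    if kind == "bullet":
        r, length = size
        # centered so the solid spans [-(l/2 + r/2), l/2 + r/2] along z
        zc = z + r / 2
        body = (x**2 + y**2 <= r**2) & (zc >= -length / 2) & (zc <= length / 2)
        cap = (x**2 + y**2 + (zc - length / 2) ** 2) <= r**2
        return body | cap
    raise AssertionError(kind)


def make_density(spec: ShapeSpec, box: int = BOX_SIZE, spacing: float = 1.0) -> DensityMap:
    """Render a shape spec into a density map on the working grid.

    Raises
    ------
    OutOfBoxError
        If the solid (plus its soft edge) does not fit inside the box.
    """
    if spec.extent + 4 * spec.soft_edge > box * spacing:
        raise OutOfBoxError(
            f"{spec.kind} with extent {spec.extent:.1f} A does not fit in the "
            f"{box * spacing:.0f} A box"
        )
    ax = (np.arange(box) + 0.5) * spacing - box * spacing / 2.0
    xs, ys, zs = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xs, ys, zs], axis=-1)
    # rotate sampling coordinates by the inverse orientation (exact rotation)
    R = Rotation.from_quat(spec.orientation).as_matrix()
    pts = pts @ R  # equivalent to R.T applied to each point
    grid = _indicator(spec.kind, spec.size, pts).astype(np.float64)
    if spec.soft_edge > 0:
        grid = ndimage.gaussian_filter(grid, sigma=spec.soft_edge / spacing)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        grid = grid + rng.normal(0.0, spec.noise_sd * grid.max(), size=grid.shape)
        grid = np.clip(grid, 0.0, None)
    name = spec.name or f"{spec.kind}_{spec.seed}"
    return DensityMap(
        grid=grid,
        spacing=np.full(3, spacing),
        origin=np.full(3, -box * spacing / 2.0),
        name=name,
    )


def _family_spec(kind: str, rng: np.random.Generator, jitter: float, index: int) -> ShapeSpec:
    def j(v):
        return v * (1.0 + jitter * rng.uniform(-1.0, 1.0))

    # The working pipeline normalizes particle volume, so within-family
    # variation must change *shape* (parameter ratios), not just scale;
    # "sphere" members are therefore independently jittered near-spherical
    # ellipsoids rather than pure spheres (which would all collapse to one
    # shape after resizing).
    base = {
        "sphere": lambda: (j(16.0), j(16.0), j(16.0)),
        "ellipsoid": lambda: (j(24.0), j(14.0), j(10.0)),
        "cylinder": lambda: (j(10.0), j(48.0)),
        "dumbbell": lambda: (j(11.0), j(34.0), j(5.0)),
        "L_block": lambda: (j(22.0), j(11.0), j(11.0)),
        "bullet": lambda: (j(12.0), j(34.0)),
    }[kind]
    quat = Rotation.random(random_state=rng).as_quat()
    return ShapeSpec(
        kind="ellipsoid" if kind == "sphere" else kind,
        size=base(),
        orientation=quat,
        seed=int(rng.integers(0, 2**31 - 1)),
        name=f"{kind}_{index:03d}",
    )


def make_fixture_library(
    n_models: int,
    n_families: int,
    seed: int = 0,
    jitter: float = 0.08,
    noise_sd: float = 0.0,
) -> list[tuple[DensityMap, str]]:
    """Generate labelled fixture maps, round-robin over shape families.

    Returns a list of (map, family label).  ``jitter`` scales the relative
    parameter perturbation within a family; a fixed seed reproduces the
    library exactly.
    """
    if not n_models >= n_families >= 2:
        raise ValueError("need n_models >= n_families >= 2")
    if n_families > len(KINDS):
        raise ValueError(f"at most {len(KINDS)} families available")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_models):
        kind = KINDS[i % n_families]
        spec = _family_spec(kind, rng, jitter, i)
        if noise_sd > 0:
            spec.noise_sd = noise_sd
        out.append((make_density(spec), kind))
    return out


def write_fixture_library(models, out_dir) -> None:
    """Write fixture maps as MRC plus a labels TSV (CLI helper)."""
    from shapesearch.volumes import save_density_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "labels.tsv", "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t")
        wr.writerow(["model_id", "family", "path"])
        for dmap, family in models:
            path = out / f"{dmap.name}.mrc"
            save_density_map(dmap, path)
            wr.writerow([dmap.name, family, path.name])
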