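"""Quasi-uniform projection image generation from density maps.

View directions are vertices of a subdivided icosahedron (oriented with a
vertex at the +z pole) restricted to the upper hemisphere, pruned to the
requested count by deterministic farthest-point selection.  Each projection
rotates the map so the view axis becomes +z, integrates along z and
resamples the 100 x 100 A field of view to 64 x 64 pixels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from shapesearch import mrcio
from shapesearch.errors import DegenerateProjectionError
from shapesearch.volumes import BOX_SIZE

#: Output image side in pixels.
IMAGE_SIZE = 64
#: Pixel size of projection images (100 A box over 64 px).
PIXEL_SIZE = BOX_SIZE / IMAGE_SIZE


@dataclass(frozen=True)
class ProjectionDirection:
    """A unit view axis in the upper hemisphere, with a stable integer id."""

    vector: tuple[float, float, float]
    id: int = 0

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vector, dtype=np.float64)


@dataclass
class ProjectionImage:
    """A 64 x 64 nonnegative projection image tagged with its provenance."""

    pixels: np.ndarray
    pixel_size: float = PIXEL_SIZE
    model: str = ""
    direction_id: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(
                f"projection images must be {IMAGE_SIZE}x{IMAGE_SIZE}, "
                f"got {self.pixels.shape}"
            )


@dataclass
class ImageStack:
    """An ordered list of projection images with a per-model index."""

    images: list[ProjectionImage] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i) -> ProjectionImage:
        return self.images[i]

    def __iter__(self):
        return iter(self.images)

    def append(self, image: ProjectionImage) -> None:
        self.images.append(image)

    def extend(self, other: "ImageStack") -> None:
        self.images.extend(other.images)

    @property
    def model_ids(self) -> list[str]:
        return [im.model for im in self.images]

    def model_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for im in self.images:
            counts[im.model] = counts.get(im.model, 0) + 1
        return counts

    def as_array(self) -> np.ndarray:
        """All pixels as an (N, 64, 64) array."""
        return np.stack([im.pixels for im in self.images])

    # -- persistence: MRC stack + TSV metadata table -----------------------

    def save(self, stack_path, table_path, directions=None) -> None:
        arr = self.as_array()  # (N, 64, 64) -> sections along z
        mrcio.write_mrc(stack_path, arr.transpose(1, 2, 0), self.images[0].pixel_size)
        dir_map = {d.id: d.as_array() for d in directions} if directions else {}
        with open(table_path, "w", newline="") as fh:
            wr = csv.writer(fh, delimiter="\t")
            wr.writerow(["image_index", "model_id", "direction_id", "dir_x", "dir_y", "dir_z"])
            for i, im in enumerate(self.images):
                v = dir_map.get(im.direction_id, (np.nan, np.nan, np.nan))
                wr.writerow(
                    [i, im.model, im.direction_id, f"{v[0]:.9g}", f"{v[1]:.9g}", f"{v[2]:.9g}"]
                )

    @classmethod
    def load(cls, stack_path, table_path) -> "ImageStack":
        grid, spacing, _ = mrcio.read_mrc(stack_path)
        arr = grid.transpose(2, 0, 1)  # (N, 64, 64)
        stack = cls()
        with open(table_path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        if len(rows) != len(arr):
            raise ValueError(
                f"stack has {len(arr)} images but table has {len(rows)} rows"
            )
        for row, pix in zip(rows, arr):
            stack.append(
                ProjectionImage(
                    pixels=pix,
                    pixel_size=float(spacing[0]),
                    model=row["model_id"],
                    direction_id=int(row["direction_id"]),
                )
            )
        return stack


# ---------------------------------------------------------------------------
# direction sampling


def _icosahedron() -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Icosahedron with vertices at the +/-z poles and two 5-rings."""
    verts = [np.array([0.0, 0.0, 1.0])]
    z = 1.0 / np.sqrt(5.0)
    rho = 2.0 / np.sqrt(5.0)
    for k in range(5):  # upper ring
        a = 2.0 * np.pi * k / 5.0
        verts.append(np.array([rho * np.cos(a), rho * np.sin(a), z]))
    for k in range(5):  # lower ring, offset by 36 degrees
        a = 2.0 * np.pi * k / 5.0 + np.pi / 5.0
        verts.append(np.array([rho * np.cos(a), rho * np.sin(a), -z]))
    verts.append(np.array([0.0, 0.0, -1.0]))
    faces = []
    for k in range(5):
        k1 = (k + 1) % 5
        faces.append((0, 1 + k, 1 + k1))
        faces.append((1 + k, 6 + k, 1 + k1))
        faces.append((1 + k1, 6 + k, 6 + k1))
        faces.append((6 + k, 11, 6 + k1))
    return np.stack(verts), faces


def _subdivide(verts: np.ndarray, faces, level: int) -> np.ndarray:
    """Split every edge into ``level`` segments and project onto the sphere."""
    if level <= 1:
        return verts
    seen: dict[tuple, np.ndarray] = {}

    def add(p):
        key = tuple(np.round(p, 9))
        if key not in seen:
            seen[key] = p
        return seen[key]

    for v in verts:
        add(v)
    for a, b, c in faces:
        va, vb, vc = verts[a], verts[b], verts[c]
        for i in range(level + 1):
            for j in range(level + 1 - i):
                k = level - i - j
                p = (i * va + j * vb + k * vc) / level
                add(p / np.linalg.norm(p))
    return np.stack(list(seen.values()))


def _upper_hemisphere(verts: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Keep z > 0 plus one of each antipodal pair on the equator."""
    keep = []
    for v in verts:
        if v[2] > eps:
            keep.append(v)
        elif abs(v[2]) <= eps:
            if v[0] > eps or (abs(v[0]) <= eps and v[1] > eps):
                keep.append(np.array([v[0], v[1], 0.0]))
    return np.stack(keep)


def sample_directions(n_target: int) -> list[ProjectionDirection]:
    """Quasi-uniform view directions on the upper hemisphere.

    The icosahedron subdivision level is the smallest giving at least
    ``n_target`` hemisphere vertices; the vertex set is then pruned to
    exactly ``n_target`` by farthest-point selection seeded at (0, 0, 1).
    Deterministic: two calls yield identical lists.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    base_verts, faces = _icosahedron()
    level = 1
    while True:
        verts = _upper_hemisphere(_subdivide(base_verts, faces, level))
        if len(verts) >= n_target:
            break
        level += 1

    # canonical ordering before selection so ties break deterministically
    order = np.lexsort((verts[:, 1], verts[:, 0], -verts[:, 2]))
    verts = verts[order]

    pole = np.array([0.0, 0.0, 1.0])
    start = int(np.argmax(verts @ pole))
    chosen = [start]
    # min angular distance to the chosen set (cosine: larger = closer)
    max_cos = verts @ verts[start]
    for _ in range(1, n_target):
        cand = int(np.argmin(max_cos))
        chosen.append(cand)
        max_cos = np.maximum(max_cos, verts @ verts[cand])

    out = []
    for i, idx in enumerate(chosen):
        v = verts[idx] / np.linalg.norm(verts[idx])
        out.append(ProjectionDirection(vector=(float(v[0]), float(v[1]), float(v[2])), id=i))
    return out


# ---------------------------------------------------------------------------
# projection


def _rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Proper rotation matrix R with R @ direction = +z (deterministic roll)."""
    z = np.array([0.0, 0.0, 1.0])
    d = direction / np.linalg.norm(direction)
    c = float(d @ z)
    axis = np.cross(d, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return Rotation.from_rotvec([np.pi, 0.0, 0.0]).as_matrix()
    axis = axis / s
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(axis * angle).as_matrix()


def _presample(dmap, image_size: int) -> tuple[np.ndarray, float]:
    """Resample a cubic map to image_size^3; returns (grid, spacing)."""
    grid = np.asarray(dmap.grid, dtype=np.float64)
    n = grid.shape[0]
    if grid.shape != (n, n, n):
        raise ValueError("project_map expects a cubic (grid-normalized) map")
    if n == image_size:
        return grid, float(dmap.spacing[0])
    # voxel-center-consistent resampling: output center (o + 0.5) * s - 0.5
    s = n / image_size
    small = ndimage.affine_transform(
        grid,
        np.diag(np.full(3, s)),
        offset=np.full(3, 0.5 * s - 0.5),
        output_shape=(image_size,) * 3,
        order=3,
        mode="constant",
        cval=0.0,
    )
    return np.clip(small, 0.0, None), float(dmap.spacing[0]) * s


def _project_prefiltered(
    coeffs: np.ndarray, spacing: float, direction: ProjectionDirection, model: str
) -> ProjectionImage:
    """Rotate spline coefficients so the view axis maps to +z and integrate.

    Pixel values carry the per-pixel mass (density * A^3), so the pixel sum
    approximates the total map mass; differences across directions reflect
    only rotation interpolation loss.
    """
    R = _rotation_to_z(direction.as_array())
    n = coeffs.shape[0]
    center = (np.asarray(coeffs.shape, dtype=np.float64) - 1.0) / 2.0
    # affine_transform: output[o] = input[M @ o + offset]; sample input at R^-1 o
    M = R.T
    offset = center - M @ center
    rot = ndimage.affine_transform(
        coeffs, M, offset=offset, order=3, mode="constant", cval=0.0, prefilter=False
    )
    rot = np.clip(rot, 0.0, None)
    img = rot.sum(axis=2) * spacing**3
    return ProjectionImage(
        pixels=img, pixel_size=spacing, model=model, direction_id=direction.id
    )


def project_map(dmap, direction: ProjectionDirection, image_size: int = IMAGE_SIZE) -> ProjectionImage:
    """Project a grid-normalized map along a view direction.

    The map is resampled to ``image_size`` voxels per side (cubic spline),
    rotated so the view axis maps to +z, and summed along z; the 100 A box
    thus yields 64 x 64 images with a 1.5625 A pixel.  Pixel values are
    scaled so the pixel sum matches the total map mass within interpolation
    error.
    """
    grid = np.asarray(dmap.grid, dtype=np.float64)
    if grid.size == 0 or grid.sum() <= 0:
        raise DegenerateProjectionError(f"map {dmap.name!r} is empty")
    small, spacing = _presample(dmap, image_size)
    coeffs = ndimage.spline_filter(small, order=3)
    return _project_prefiltered(coeffs, spacing, direction, dmap.name)


def build_projection_set(dmap, n_images: int = 91, image_size: int = IMAGE_SIZE) -> ImageStack:
    """One projection per sampled direction, tagged with model and direction ids.

    The resampling and spline prefilter are shared across directions, which
    is what makes 91-image sets affordable.
    """
    grid = np.asarray(dmap.grid, dtype=np.float64)
    if grid.size == 0 or grid.sum() <= 0:
        raise DegenerateProjectionError(f"map {dmap.name!r} is empty")
    dirs = sample_directions(n_images)
    small, spacing = _presample(dmap, image_size)
    coeffs = ndimage.spline_filter(small, order=3)
    stack = ImageStack()
    for d in dirs:
        stack.append(_project_prefiltered(coeffs, spacing, d, dmap.name))
    return stack
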