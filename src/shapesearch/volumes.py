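"""Density map handling: I/O, grid normalization and common-volume resizing.

All maps are eventually brought to the common working geometry of a cubic
100-voxel grid at 1 A spacing, and then rescaled so that their particle
content occupies the reference volume of 50^3 A^3.  The linear rescale is

    D_new = D_old * D_ref / V_old**(1/3)

where ``V_old`` is the particle volume estimated from a Gaussian-mixture
representation of the map (95%-mass isodensity volume by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from shapesearch import mrcio
from shapesearch.errors import (
    DegenerateMapError,
    ImplausibleVolumeError,
    NumericalDegeneracyError,
)

logger = logging.getLogger(__name__)

#: Side of the common working box in Angstrom (and voxels at 1 A spacing).
BOX_SIZE = 100
#: Reference linear dimension of the common particle volume, Angstrom.
D_REF = 50.0


@dataclass
class DensityMap:
    """A 3D nonnegative scalar field on a regular grid.

    Attributes
    ----------
    grid : ndarray, shape (nx, ny, nz)
        Densities, indexed ``grid[ix, iy, iz]``.
    spacing : ndarray, shape (3,)
        Voxel spacing in Angstrom per axis (isotropic after normalization).
    origin : ndarray, shape (3,)
        Physical position of the grid corner; voxel centers are at
        ``origin + (i + 0.5) * spacing``.
    name : str
        Identifier of the source model.
    """

    grid: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    name: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64).copy()

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def total_mass(self) -> float:
        """Integral of the density over the grid, in density * A^3 units."""
        return float(self.grid.sum() * self.voxel_volume)

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates of all voxel centers, shape (n_voxels, 3)."""
        axes = [
            self.origin[d] + (np.arange(self.grid.shape[d]) + 0.5) * self.spacing[d]
            for d in range(3)
        ]
        xs, ys, zs = np.meshgrid(*axes, indexing="ij")
        return np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)


@dataclass
class ResizeSpec:
    """Parameters of the common-volume rescale.

    ``d_old`` is the current cubic axis dimension, ``d_ref`` the reference
    linear dimension, ``v_old`` the estimated particle volume (all Angstrom
    based).
    """

    v_old: float
    d_old: float = float(BOX_SIZE)
    d_ref: float = D_REF

    def __post_init__(self):
        if self.d_old <= 0 or self.d_ref <= 0:
            raise ValueError("d_old and d_ref must be positive")
        if self.v_old <= 0:
            raise ValueError("v_old must be positive")


def load_density_map(path, name: str | None = None) -> DensityMap:
    """Read an MRC file into a :class:`DensityMap`, clamping negatives to 0."""
    grid, spacing, origin = mrcio.read_mrc(path)
    grid = np.clip(grid, 0.0, None)
    if name is None:
        name = str(path)
    return DensityMap(grid=grid, spacing=spacing, origin=origin, name=name)


def save_density_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC2014 mode 2."""
    mrcio.write_mrc(path, dmap.grid, dmap.spacing, dmap.origin)


def normalize_grid(dmap: DensityMap, box: int = BOX_SIZE, spacing: float = 1.0) -> DensityMap:
    """Resample a map onto the common cubic grid (100^3 voxels at 1 A).

    The physical center of the input extent is mapped to the center of the
    output box; values are interpolated with a cubic spline and negatives
    introduced by spline ringing are clamped to 0.  Because the physical
    geometry is unchanged, the integral of the density (total mass) is
    preserved up to interpolation error (< 1% for smooth maps that fit in
    the box).

    Raises
    ------
    DegenerateMapError
        If the map has no mass.
    """
    if dmap.grid.size == 0 or dmap.grid.sum() <= 0:
        raise DegenerateMapError(f"map {dmap.name!r} has zero total mass")

    shape = np.asarray(dmap.grid.shape, dtype=np.float64)
    already = (
        dmap.grid.shape == (box, box, box)
        and np.allclose(dmap.spacing, spacing, atol=1e-12)
    )
    if already:
        return replace(dmap, grid=dmap.grid.copy())

    in_center = dmap.origin + shape * dmap.spacing / 2.0
    out_origin = in_center - box * spacing / 2.0

    # Physical coordinate of output voxel center -> fractional input index.
    ax = [
        (out_origin[d] + (np.arange(box) + 0.5) * spacing - dmap.origin[d])
        / dmap.spacing[d]
        - 0.5
        for d in range(3)
    ]
    ix, iy, iz = np.meshgrid(*ax, indexing="ij")
    out = ndimage.map_coordinates(
        dmap.grid, [ix, iy, iz], order=3, mode="constant", cval=0.0
    )
    out = np.clip(out, 0.0, None)
    if out.sum() <= 0:
        raise DegenerateMapError(f"map {dmap.name!r} lost all mass in normalization")
    return DensityMap(
        grid=out,
        spacing=np.full(3, spacing),
        origin=out_origin,
        name=dmap.name,
    )


def rescale_axis_dimension(spec: ResizeSpec) -> float:
    """New axis dimension ``D_new = D_old * D_ref / V_old**(1/3)``."""
    return spec.d_old * spec.d_ref / spec.v_old ** (1.0 / 3.0)


def resize_to_common_volume(
    dmap: DensityMap, v_old: float, spec: ResizeSpec | None = None
) -> DensityMap:
    """Rescale the particle content of a grid-normalized map to ~50^3 A^3.

    The map is scaled about its box center by the linear factor
    ``D_new / D_old``; density values are divided by the cube of the factor
    so the total mass is preserved.  Content that would fall outside the box
    after upscaling is cropped symmetrically (with a logged warning).

    Raises
    ------
    ImplausibleVolumeError
        If ``D_new`` would exceed 4 * ``D_old``.
    """
    if spec is None:
        spec = ResizeSpec(v_old=v_old)
    elif spec.v_old != v_old:
        spec = replace(spec, v_old=v_old)
    d_new = rescale_axis_dimension(spec)
    if d_new > 4.0 * spec.d_old:
        raise ImplausibleVolumeError(
            f"map {dmap.name!r}: D_new = {d_new:.1f} A exceeds 4 x D_old = "
            f"{4 * spec.d_old:.1f} A (estimated volume {v_old:.1f} A^3 implausibly small)"
        )
    s = d_new / spec.d_old

    shape = np.asarray(dmap.grid.shape, dtype=np.float64)
    center = (shape - 1.0) / 2.0
    # output index -> input index: scale about the box center by 1/s
    matrix = np.diag(np.full(3, 1.0 / s))
    offset = center - center / s
    mass_before = dmap.grid.sum()
    out = ndimage.affine_transform(
        dmap.grid, matrix, offset=offset, order=3, mode="constant", cval=0.0
    )
    out = np.clip(out, 0.0, None) / s**3
    mass_after = out.sum()
    if mass_after < 0.99 * mass_before:
        logger.warning(
            "map %r: %.1f%% of mass cropped at the box boundary during x%.2f upscale",
            dmap.name,
            100.0 * (1.0 - mass_after / mass_before),
            s,
        )
    return replace(dmap, grid=out)


def estimate_volume(gmm, mass_fraction: float = 0.95, spacing: float = 1.0) -> float:
    """Particle volume of a Gaussian mixture: the 95%-mass isodensity volume.

    The mixture density is evaluated on a regular grid (1 A by default)
    covering all components out to ~5 sigma; voxels are sorted by density
    (descending) and accumulated until ``mass_fraction`` of the total grid
    mass is enclosed.  The returned volume is that voxel count times the
    voxel volume.

    Notes
    -----
    This definition is threshold-free and scale-covariant.  It stands in
    for the (unpublished) volume read out of automatically constructed
    mixture models by existing fitting software.
    """
    if not 0.0 < mass_fraction < 1.0:
        raise ValueError("mass_fraction must be in (0, 1)")
    means = gmm.means
    covs = gmm.covariances
    eigvals = np.linalg.eigvalsh(covs)
    if np.any(eigvals[:, 0] <= 0):
        raise NumericalDegeneracyError(
            f"mixture {getattr(gmm, 'name', '')!r} has a singular covariance"
        )
    sigma_max = np.sqrt(eigvals[:, -1])
    lo = (means - 5.0 * sigma_max[:, None]).min(axis=0)
    hi = (means + 5.0 * sigma_max[:, None]).max(axis=0)
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    dens = gmm.density(pts)
    dens_sorted = np.sort(dens)[::-1]
    csum = np.cumsum(dens_sorted)
    total = csum[-1]
    if total <= 0:
        raise NumericalDegeneracyError("mixture density sums to zero on the grid")
    count = int(np.searchsorted(csum, mass_fraction * total) + 1)
    return count * spacing**3
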