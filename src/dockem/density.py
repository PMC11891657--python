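"""Cryo-EM density grids: MRC I/O, simulated density, and correlation scoring.

A map of nominal resolution R (A) is simulated from an atomic model by
placing on each atom an isotropic Gaussian kernel of width w = 2.4 + 0.8 R,

    rho_c(g) = sum_i m_i (pi/w)^3 exp(-(pi/w)^2 |x_i - x_g|^2),

evaluated at voxel centers with continuous atom coordinates. Goodness of
fit between a model-simulated map and an experimental map is the Pearson
correlation (CC) over a shared voxel set. The docking arena is a cubic
"local map" cut from the full grid around the binding site; it is a view,
never a resample, so voxel values and world coordinates are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import (
    GeometryError,
    LatticeMismatchError,
    ParameterError,
    ParseError,
    UnsupportedFormatError,
)

__all__ = [
    "CC",
    "DensityGrid",
    "LocalMap",
    "read_mrc",
    "write_mrc",
    "simulate_density",
    "compute_cc",
    "extract_local_map",
    "ligand_region_cc",
    "kernel_width",
]

#: header float slot (1-based MRC word in the 25..49 "extra" space) used to
#: carry the nominal resolution in maps written by this package
_RESOLUTION_HEADER_WORD = 49


def kernel_width(resolution: float) -> float:
    """Gaussian kernel width w = 2.4 + 0.8 R for nominal resolution R (A)."""
    if resolution <= 0:
        raise ParameterError("map resolution must be positive")
    return 2.4 + 0.8 * resolution


class CC(float):
    """A correlation coefficient that remembers whether it was degenerate.

    When either voxel vector has zero variance the correlation is undefined;
    by convention the value is 0 (worst score for the map-fit energy term
    1 - CC among non-negative correlations) and ``degenerate`` is True, so
    sampling can continue when a pose drifts out of the map.
    """

    degenerate: bool

    def __new__(cls, value: float, degenerate: bool = False):
        obj = super().__new__(cls, value)
        obj.degenerate = degenerate
        return obj


@dataclass
class DensityGrid:
    """A 3-D density map on an isotropic orthogonal voxel lattice.

    ``values`` is indexed ``[ix, iy, iz]``; the world coordinate of voxel
    ``(i, j, k)`` center is ``origin + spacing * (i, j, k)``.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: float
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError("density values must be a 3-D array")
        if self.spacing <= 0:
            raise ParameterError("voxel spacing must be positive")
        if self.resolution is not None and self.resolution <= 0:
            raise ParameterError("map resolution must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_vol(self) -> int:
        return int(self.values.size)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.values.shape[axis])

    def voxel_centers(self) -> np.ndarray:
        """(N_vol, 3) world coordinates of all voxel centers (C order)."""
        axes = [self.axis_coords(i) for i in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Min/max voxel-center coordinates."""
        hi = self.origin + self.spacing * (np.array(self.values.shape) - 1)
        return self.origin.copy(), hi


@dataclass
class LocalMap:
    """A cubic sub-region of a parent grid: the docking arena.

    ``values`` is a numpy view into the parent array (bit-identical values),
    sliced at ``start_index``. ``center`` is the requested cube center c_0
    and ``edge`` the requested edge length; the cube is clipped to the
    parent bounds.
    """

    parent: DensityGrid
    center: np.ndarray
    edge: float
    start_index: tuple[int, int, int]
    values: np.ndarray
    _voxel_centers: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def spacing(self) -> float:
        return self.parent.spacing

    @property
    def resolution(self) -> float | None:
        return self.parent.resolution

    @property
    def origin(self) -> np.ndarray:
        return self.parent.origin + self.parent.spacing * np.asarray(self.start_index)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_vol(self) -> int:
        return int(self.values.size)

    def voxel_centers(self) -> np.ndarray:
        if self._voxel_centers is None:
            axes = [self.origin[i] + self.spacing * np.arange(self.values.shape[i])
                    for i in range(3)]
            gx, gy, gz = np.meshgrid(*axes, indexing="ij")
            self._voxel_centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        return self._voxel_centers

    def cube_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Geometric bounds of the requested (unclipped) cube."""
        half = self.edge / 2.0
        return self.center - half, self.center + half


# --- MRC I/O -------------------------------------------------------------

def read_mrc(path: str, resolution: float | None = None) -> DensityGrid:
    """Read an MRC/CCP4 2014 map (mode 2) into a :class:`DensityGrid`.

    Axis order is normalized so that the in-memory array is indexed x, y, z
    regardless of the MAPC/MAPR/MAPS permutation in the header. The origin
    is taken from the ORIGIN header words, falling back to NXSTART-style
    start offsets. A resolution stored by :func:`write_mrc` is recovered
    from its header slot; an explicit ``resolution`` argument wins.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot read MRC map {path!r}: {exc}") from exc
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise UnsupportedFormatError("non-orthogonal map cells are not supported")
    # capture origin/start before setup (setup may expand the grid)
    origin = np.array([m.header_float(w) for w in (50, 51, 52)], dtype=float)
    starts = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
    stored_res = float(m.header_float(_RESOLUTION_HEADER_WORD))
    m.setup(0.0)
    values = np.array(m.grid, copy=True, dtype=float)  # (nx, ny, nz) after setup
    spacings = np.array(m.grid.spacing, dtype=float)
    if spacings.max() - spacings.min() > 1e-4 * spacings.mean():
        raise UnsupportedFormatError(
            f"anisotropic voxel spacing {tuple(spacings)} is not supported; "
            "resample the map to an isotropic lattice first"
        )
    spacing = float(spacings.mean())
    if np.allclose(origin, 0.0) and not np.allclose(starts, 0.0):
        origin = starts * spacing
    res = resolution
    if res is None and stored_res > 0:
        res = stored_res
    return DensityGrid(values=values, origin=origin, spacing=spacing, resolution=res)


def write_mrc(grid: DensityGrid, path: str) -> None:
    """Write a mode-2 MRC/CCP4 map; records the resolution in the header."""
    nx_, ny_, nz_ = grid.dims
    g = gemmi.FloatGrid(nx_, ny_, nz_)
    np.asarray(g)[:] = grid.values.astype(np.float32)
    g.unit_cell = gemmi.UnitCell(
        nx_ * grid.spacing, ny_ * grid.spacing, nz_ * grid.spacing, 90, 90, 90
    )
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(val))
    if grid.resolution is not None:
        m.set_header_float(_RESOLUTION_HEADER_WORD, float(grid.resolution))
    m.write_ccp4_map(str(path))


# --- simulated density ---------------------------------------------------

def simulate_density(
    atoms,
    resolution: float,
    spacing: float,
    origin,
    dims,
    *,
    masses: np.ndarray | None = None,
    truncate: float = 1e-8,
) -> DensityGrid:
    """Render the Gaussian-kernel density of an atomic model on a grid.

    ``atoms`` is either an object with ``coords``/``masses`` attributes
    (Ligand, Protein), a list of Atom, or an (n, 3) coordinate array with
    ``masses`` given explicitly. Each kernel is truncated where it falls
    below ``truncate`` times its peak.
    """
    if spacing <= 0:
        raise ParameterError("voxel spacing must be positive")
    w = kernel_width(resolution)  # validates resolution
    coords, m = _coords_and_masses(atoms, masses)
    origin = np.asarray(origin, dtype=float)
    dims = tuple(int(d) for d in dims)
    values = np.zeros(dims, dtype=float)
    grid = DensityGrid(values=values, origin=origin, spacing=spacing, resolution=resolution)
    if len(coords) == 0:
        return grid
    k = math.pi / w
    peak = k ** 3
    r_cut = math.sqrt(-math.log(truncate)) / k
    axes = [grid.axis_coords(i) for i in range(3)]
    for xi, mi in zip(coords, m):
        # per-axis index window of the truncated kernel
        lo = [int(np.searchsorted(axes[a], xi[a] - r_cut, side="left")) for a in range(3)]
        hi = [int(np.searchsorted(axes[a], xi[a] + r_cut, side="right")) for a in range(3)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        d2 = (
            ((axes[0][lo[0]:hi[0]] - xi[0]) ** 2)[:, None, None]
            + ((axes[1][lo[1]:hi[1]] - xi[1]) ** 2)[None, :, None]
            + ((axes[2][lo[2]:hi[2]] - xi[2]) ** 2)[None, None, :]
        )
        values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += mi * peak * np.exp(-(k * k) * d2)
    return grid


def _coords_and_masses(atoms, masses):
    if hasattr(atoms, "coords") and hasattr(atoms, "masses"):
        return np.asarray(atoms.coords, dtype=float), np.asarray(atoms.masses, dtype=float)
    if isinstance(atoms, (list, tuple)) and atoms and hasattr(atoms[0], "coords"):
        coords = np.array([a.coords for a in atoms], dtype=float)
        m = np.array([a.mass for a in atoms], dtype=float)
        if np.any(~np.isfinite(m)):
            raise ParameterError("atoms passed to simulate_density lack masses")
        return coords, m
    coords = np.asarray(atoms, dtype=float).reshape(-1, 3)
    if masses is None:
        raise ParameterError("masses are required when passing raw coordinates")
    return coords, np.asarray(masses, dtype=float)


# --- correlation ---------------------------------------------------------

def _as_values_and_lattice(obj):
    if isinstance(obj, (DensityGrid, LocalMap)):
        return obj.values, (obj.origin, obj.spacing)
    return np.asarray(obj, dtype=float), None


def compute_cc(calc, exp) -> CC:
    """Pearson correlation between two density fields on the same lattice.

    Accepts :class:`DensityGrid`, :class:`LocalMap`, or raw arrays; when
    both carry geometry the lattices must agree. Returns :class:`CC`
    (0, flagged degenerate, if either field has zero variance).
    """
    a, lat_a = _as_values_and_lattice(calc)
    b, lat_b = _as_values_and_lattice(exp)
    if a.shape != b.shape:
        raise LatticeMismatchError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if lat_a is not None and lat_b is not None:
        (oa, sa), (ob, sb) = lat_a, lat_b
        if abs(sa - sb) > 1e-6 or np.any(np.abs(oa - ob) > 1e-6):
            raise LatticeMismatchError("grids are not sampled on the same voxel lattice")
    x = a.ravel().astype(float)
    y = b.ravel().astype(float)
    x = x - x.mean()
    y = y - y.mean()
    nx_ = float(np.dot(x, x))
    ny_ = float(np.dot(y, y))
    if nx_ <= 0.0 or ny_ <= 0.0:
        return CC(0.0, degenerate=True)
    return CC(float(np.dot(x, y) / math.sqrt(nx_ * ny_)))


def extract_local_map(grid: DensityGrid, center, edge: float) -> LocalMap:
    """Cut the cubic sub-region of ``grid`` centered at ``center``.

    The sub-array contains every voxel whose center lies within ``edge/2``
    of ``center`` along each axis, clipped to the grid bounds; it is a view
    into the parent values (no resampling).
    """
    center = np.asarray(center, dtype=float)
    if edge <= 0:
        raise GeometryError("local-map edge must be positive")
    lo_w, hi_w = grid.bounding_box()
    if np.any(center < lo_w - grid.spacing / 2) or np.any(center > hi_w + grid.spacing / 2):
        raise GeometryError(f"local-map center {center.tolist()} lies outside the grid")
    half = edge / 2.0
    eps = 1e-9 * max(1.0, edge)
    lo_idx, hi_idx = [], []
    for a in range(3):
        lo = math.ceil((center[a] - half - grid.origin[a]) / grid.spacing - eps)
        hi = math.floor((center[a] + half - grid.origin[a]) / grid.spacing + eps)
        lo = max(lo, 0)
        hi = min(hi, grid.values.shape[a] - 1)
        if hi < lo:
            raise GeometryError("local-map cube contains no voxels inside the grid")
        lo_idx.append(lo)
        hi_idx.append(hi)
    view = grid.values[lo_idx[0]:hi_idx[0] + 1,
                       lo_idx[1]:hi_idx[1] + 1,
                       lo_idx[2]:hi_idx[2] + 1]
    return LocalMap(parent=grid, center=center, edge=float(edge),
                    start_index=tuple(lo_idx), values=view)


def ligand_region_cc(
    pose,
    local: LocalMap,
    resolution: float | None = None,
    *,
    masses: np.ndarray | None = None,
) -> CC:
    """CC between a ligand pose and the local density map region.

    The pose is rendered with the Gaussian kernel on the local map's own
    lattice at the parent map's nominal resolution, then correlated against
    the experimental values of the region only.
    """
    res = resolution if resolution is not None else local.resolution
    if res is None:
        raise ParameterError("no resolution available for ligand_region_cc")
    calc = simulate_density(pose, res, local.spacing, local.origin, local.dims,
                            masses=masses)
    return compute_cc(calc.values, local.values)
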