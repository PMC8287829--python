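"""Voxelized atrial tissue patches and interstitial fibrosis texture.

The tissue is a regular grid of hexahedral elements.  Each element is either
a myocyte or a collagen deposit.  Conductivities are stored per element and
per principal direction (longitudinal along the fiber axis, transverse
otherwise); fibers run along +x throughout the patch.

Coordinate convention: z = 0 is the endocardial face (the catheter side);
z increases toward the epicardium.  Fibrotic infiltration grows downward
from the endocardium, i.e. it occupies elements whose center depth is at
most the requested transmural depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConvergenceError, ParameterError

# Baseline bidomain conductivities (S/m) for atrial working myocardium,
# longitudinal / transverse to the fiber axis.  Transverse values give a
# mild bulk anisotropy (conduction-velocity ratio ~1.45:1), typical of
# atrial tissue outside specialized tracts.
SIGMA_I_LONG = 0.17
SIGMA_I_TRANS = 0.08
SIGMA_E_LONG = 0.62
SIGMA_E_TRANS = 0.30

#: Extracellular conductivity assigned to collagen deposits (S/m).
SIGMA_COLLAGEN = 1e-6

#: Gap-junction remodeling inside the fibrotic region: longitudinal
#: conductivity reduced by 53 %, transverse increased 2.5-fold.
REMODEL_LONG = 0.47
REMODEL_TRANS = 2.5

MYOCYTE = 0
COLLAGEN = 1


@dataclass
class TissueGrid:
    """Labeled voxel grid with per-element conductivities.

    Arrays are indexed ``[ix, iy, iz]``; physical positions refer to element
    centers, e.g. ``x = (ix + 0.5) * spacing``.
    """

    nx: int
    ny: int
    nz: int
    spacing: float  # mm
    label: np.ndarray = field(repr=False)  # uint8, MYOCYTE/COLLAGEN
    sigma_i_long: np.ndarray = field(repr=False)
    sigma_i_trans: np.ndarray = field(repr=False)
    sigma_e_long: np.ndarray = field(repr=False)
    sigma_e_trans: np.ndarray = field(repr=False)
    fiber_direction: tuple = (1.0, 0.0, 0.0)

    @property
    def shape(self) -> tuple:
        return (self.nx, self.ny, self.nz)

    @property
    def n_elements(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def dims_mm(self) -> tuple:
        return (self.nx * self.spacing, self.ny * self.spacing, self.nz * self.spacing)

    @property
    def element_volume(self) -> float:
        """Element volume in mm^3."""
        return self.spacing ** 3

    def centers(self):
        """Element-center coordinate arrays (x, y, z), each of grid shape, mm."""
        s = self.spacing
        x = (np.arange(self.nx) + 0.5) * s
        y = (np.arange(self.ny) + 0.5) * s
        z = (np.arange(self.nz) + 0.5) * s
        return np.meshgrid(x, y, z, indexing="ij")

    def copy(self) -> "TissueGrid":
        return replace(
            self,
            label=self.label.copy(),
            sigma_i_long=self.sigma_i_long.copy(),
            sigma_i_trans=self.sigma_i_trans.copy(),
            sigma_e_long=self.sigma_e_long.copy(),
            sigma_e_trans=self.sigma_e_trans.copy(),
        )

    def validate(self) -> None:
        for name in ("sigma_i_long", "sigma_i_trans", "sigma_e_long", "sigma_e_trans"):
            if not np.all(getattr(self, name) > 0):
                raise ParameterError(f"{name} must be strictly positive everywhere")
        if self.spacing <= 0:
            raise ParameterError("spacing must be > 0")


@dataclass(frozen=True)
class FibrosisSpec:
    """Parameters of one fibrotic texture realization.

    density is the target collagen volume fraction inside the circular
    fibrotic region (down to ``transmural_depth``); collagen fiber lengths
    are drawn from N(fiber_length_mean, fiber_length_sd) and laid along the
    local fiber axis.
    """

    density: float
    transmural_depth: float  # mm, measured from the endocardium (z = 0)
    region_center: tuple  # (x, y) mm
    region_radius: float  # mm
    fiber_length_mean: float = 0.6  # mm
    fiber_length_sd: float = 0.2  # mm
    seed: int = 0

    def validate(self, grid: TissueGrid) -> None:
        if not 0.0 <= self.density < 1.0:
            raise ParameterError(f"density must be in [0, 1), got {self.density}")
        wall = grid.nz * grid.spacing
        if not 0.0 < self.transmural_depth <= wall + 1e-9:
            raise ParameterError(
                f"transmural_depth {self.transmural_depth} mm outside (0, {wall}] mm"
            )
        cx, cy = self.region_center
        lx, ly, _ = grid.dims_mm
        if (
            cx - self.region_radius < -1e-9
            or cy - self.region_radius < -1e-9
            or cx + self.region_radius > lx + 1e-9
            or cy + self.region_radius > ly + 1e-9
        ):
            raise ParameterError("fibrotic region does not fit inside the patch")


def build_tissue(dims_mm, spacing_mm: float) -> TissueGrid:
    """Build a homogeneous all-myocyte patch.

    Parameters
    ----------
    dims_mm : (lx, ly, lz) physical extent in mm.
    spacing_mm : element edge length in mm; must divide every dimension.
    """
    if spacing_mm <= 0:
        raise ParameterError("spacing must be > 0")
    counts = []
    for d in dims_mm:
        if d <= 0:
            raise ParameterError("dimensions must be > 0")
        n = d / spacing_mm
        if abs(n - round(n)) > 1e-6 * max(1.0, n):
            raise ParameterError(
                f"spacing {spacing_mm} mm does not divide dimension {d} mm"
            )
        counts.append(int(round(n)))
    nx, ny, nz = counts
    shape = (nx, ny, nz)
    return TissueGrid(
        nx=nx,
        ny=ny,
        nz=nz,
        spacing=spacing_mm,
        label=np.full(shape, MYOCYTE, dtype=np.uint8),
        sigma_i_long=np.full(shape, SIGMA_I_LONG),
        sigma_i_trans=np.full(shape, SIGMA_I_TRANS),
        sigma_e_long=np.full(shape, SIGMA_E_LONG),
        sigma_e_trans=np.full(shape, SIGMA_E_TRANS),
    )


def fibrotic_region_mask(grid: TissueGrid, spec: FibrosisSpec) -> np.ndarray:
    """Boolean mask of elements inside the circular region and shallower
    than the transmural depth (element-center convention)."""
    x, y, z = grid.centers()
    cx, cy = spec.region_center
    in_circle = (x - cx) ** 2 + (y - cy) ** 2 <= spec.region_radius ** 2
    in_depth = z <= spec.transmural_depth + 1e-9
    return in_circle & in_depth


def collagen_fraction(grid: TissueGrid, spec: FibrosisSpec) -> float:
    """Measured collagen volume fraction inside the fibrotic region."""
    mask = fibrotic_region_mask(grid, spec)
    return float(np.mean(grid.label[mask] == COLLAGEN))


def apply_fibrosis(
    grid: TissueGrid,
    spec: FibrosisSpec,
    rng: np.random.Generator | None = None,
    max_iter: int = 500_000,
) -> TissueGrid:
    """Lay collagen fibers into the patch until the target density is met.

    Fibers are straight runs of elements along the local fiber axis (+x);
    their lengths are drawn from the stated normal distribution and their
    positions uniformly at random inside the region (one z layer at a time,
    restricted to layers shallower than the transmural depth).  Placement
    stops when the achieved collagen volume fraction is within +-0.02 of the
    target.  Myocytes remaining inside the fibrotic volume get the
    gap-junction remodeling conductivity scaling.  Identical seeds yield
    identical textures.
    """
    spec.validate(grid)
    if spec.density == 0.0:
        return grid
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    out = grid.copy()
    mask = fibrotic_region_mask(out, spec)
    region_idx = np.argwhere(mask)
    n_region = len(region_idx)
    if n_region == 0:
        raise ParameterError("fibrotic region contains no elements")

    s = out.spacing
    label = out.label
    n_collagen = int(np.sum(label[mask] == COLLAGEN))
    target = spec.density
    tol = 0.02

    for _ in range(max_iter):
        frac = n_collagen / n_region
        if frac >= target - tol:
            break
        # pick a random seed element of the fiber inside the region
        j = rng.integers(n_region)
        ix, iy, iz = region_idx[j]
        length = max(rng.normal(spec.fiber_length_mean, spec.fiber_length_sd), s)
        n_run = max(int(round(length / s)), 1)
        i0 = ix - rng.integers(n_run)  # random offset so the seed lies anywhere on the fiber
        for di in range(n_run):
            i = i0 + di
            if i < 0 or i >= out.nx:
                continue
            if not mask[i, iy, iz]:
                continue
            if label[i, iy, iz] != COLLAGEN:
                label[i, iy, iz] = COLLAGEN
                n_collagen += 1
    else:
        raise ConvergenceError(
            f"fiber placement did not reach density {target} in {max_iter} iterations"
        )

    collagen = (label == COLLAGEN) & mask
    myo_in_region = mask & ~collagen

    # gap-junction remodeling of surviving myocytes in the fibrotic volume
    for name in ("sigma_i_long", "sigma_e_long"):
        arr = getattr(out, name)
        arr[myo_in_region] *= REMODEL_LONG
    for name in ("sigma_i_trans", "sigma_e_trans"):
        arr = getattr(out, name)
        arr[myo_in_region] *= REMODEL_TRANS

    # collagen: near-zero conductive extracellular medium, no intracellular space
    for name in ("sigma_i_long", "sigma_i_trans", "sigma_e_long", "sigma_e_trans"):
        getattr(out, name)[collagen] = SIGMA_COLLAGEN

    return out
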