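"""Catheter electrode layouts and the extracellular forward model.

The extracellular potential at an electrode is obtained from the
infinite-homogeneous-medium Green's function applied to the intracellular
source density:

    phi_e(r, t) = k / (4 pi sigma_b) * sum_j [-div(sigma_i grad Vm)]_j
                  * V_j * <1/|r - r_j|>_footprint

where V_j is the element volume and the distance is averaged over sample
points on the electrode footprint disc.  ``k`` is a fixed dimensionless
amplitude constant calibrated once so that control contact bipolar
electrograms have a peak-to-peak amplitude of ~2.25 mV; it is never changed
across conditions, so relative amplitude effects are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .ionic import IonicModel
from .propagation import (
    SimulationConfig,
    StimulusProtocol,
    VmField,
    integrate,
    source_face_arrays,
)
from .tissue import TissueGrid

#: Amplitude calibration constant of the Green's-function forward model.
#: Fixed once so that the mean control contact bipolar peak-to-peak
#: amplitude (both conduction velocities, all three pacing sites) is
#: ~2.25 mV; never changed across conditions.
DEFAULT_K = 0.4856

LAYOUT_NAMES = ("hd-grid", "lasso")


@dataclass
class CatheterLayout:
    """Electrode positions (mm) and bipole pairing of a mapping catheter.

    z <= 0 for every electrode: the catheter sits on or above the
    endocardial face (z = 0), never inside the tissue.
    """

    name: str
    positions: np.ndarray  # (n_electrodes, 3) mm
    bipoles: list  # list of (i, j) electrode index pairs
    footprint_radius: float = 0.5  # mm
    height: float = 0.0  # mm above the endocardium

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.height < 0:
            raise ParameterError("electrode height must be >= 0")
        if np.any(self.positions[:, 2] > 1e-9):
            raise ParameterError("electrodes must not be inside the tissue (z > 0)")
        for a, b in self.bipoles:
            if a == b:
                raise ParameterError("bipole pairs must reference distinct electrodes")

    @property
    def n_electrodes(self) -> int:
        return len(self.positions)

    def at_height(self, height: float) -> "CatheterLayout":
        """Same layout lifted to a new height above the endocardium."""
        if height < 0:
            raise ParameterError("electrode height must be >= 0")
        pos = self.positions.copy()
        pos[:, 2] = -height
        return CatheterLayout(
            name=self.name,
            positions=pos,
            bipoles=list(self.bipoles),
            footprint_radius=self.footprint_radius,
            height=height,
        )

    def footprint_points(self) -> np.ndarray:
        """(n_electrodes, 7, 3) sample points: center + hexagon on the rim."""
        ang = np.linspace(0.0, 2 * np.pi, 7)[:-1]
        ring = np.stack(
            [self.footprint_radius * np.cos(ang), self.footprint_radius * np.sin(ang),
             np.zeros(6)],
            axis=1,
        )
        offsets = np.vstack([np.zeros((1, 3)), ring])  # (7, 3)
        return self.positions[:, None, :] + offsets[None, :, :]


def hd_grid(
    center_xy, height: float = 0.0, spacing: float = 3.0, angle_deg: float = 30.0
) -> CatheterLayout:
    """4 x 4 grid catheter; bipoles along the four splines (12 bipoles).

    The grid is rotated by ``angle_deg`` about its center: the catheter
    orientation relative to the paced wavefront is arbitrary in practice,
    and an oblique default keeps bipole axes away from the degenerate
    exactly-parallel/perpendicular alignments with the plane waves.
    """
    cx, cy = center_xy
    off = (np.arange(4) - 1.5) * spacing
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    pos = []
    for ox in off:
        for oy in off:
            rx, ry = rot @ (ox, oy)
            pos.append((cx + rx, cy + ry, -height))
    bipoles = []
    for spline in range(4):
        for k in range(3):
            bipoles.append((4 * spline + k, 4 * spline + k + 1))
    return CatheterLayout("hd-grid", np.array(pos), bipoles, height=height)


def lasso(center_xy, height: float = 0.0) -> CatheterLayout:
    """20-pole circular catheter, alternating 2 mm intra-pair / 6 mm
    inter-pair arc spacing on an 80 mm circumference (10 bipoles)."""
    cx, cy = center_xy
    radius = 80.0 / (2 * np.pi)
    arcs = []
    for pair in range(10):
        arcs.extend([8.0 * pair, 8.0 * pair + 2.0])
    theta = np.asarray(arcs) / radius
    pos = np.stack(
        [cx + radius * np.cos(theta), cy + radius * np.sin(theta),
         np.full(20, -height)],
        axis=1,
    )
    bipoles = [(2 * p, 2 * p + 1) for p in range(10)]
    return CatheterLayout("lasso", pos, bipoles, height=height)


def make_layout(name: str, center_xy, height: float = 0.0) -> CatheterLayout:
    if name == "hd-grid":
        return hd_grid(center_xy, height=height)
    if name == "lasso":
        return lasso(center_xy, height=height)
    raise ParameterError(f"unknown catheter layout {name!r}")


def layout_weights(
    layout: CatheterLayout,
    grid: TissueGrid,
    config: SimulationConfig,
    k_const: float,
) -> np.ndarray:
    """Lead-field matrix W (n_electrodes, n_elements) such that
    phi_e = W @ stencil(Vm), with the sign of the source term folded in."""
    pts = layout.footprint_points()  # (nE, 7, 3)
    x, y, z = grid.centers()
    centers = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)  # (n_elem, 3)
    inv = np.zeros((layout.n_electrodes, centers.shape[0]))
    for e in range(layout.n_electrodes):
        d = np.linalg.norm(pts[e][:, None, :] - centers[None, :, :], axis=2)
        d = np.maximum(d, 0.5 * grid.spacing)  # guard near-contact singularity
        inv[e] = np.mean(1.0 / d, axis=0)
    vol = grid.element_volume
    return -k_const * vol / (4.0 * np.pi * config.sigma_b) * inv


@dataclass
class UnipolarTraces:
    """Unipolar electrograms (mV) at the output rate for one layout."""

    samples: np.ndarray  # (n_electrodes, n_samples)
    fs: float
    layout: CatheterLayout = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _source_frames(field: VmField, grid: TissueGrid, chunk: int = 256):
    """Yield (start, stencil) blocks of div(sigma_i grad Vm) frames."""
    sx, sy, sz = source_face_arrays(grid)
    vm = field.data  # (n_frames, nx, ny, nz), mV
    nx, ny, nz = grid.shape
    for start in range(0, vm.shape[0], chunk):
        u = np.asarray(vm[start : start + chunk], dtype=float)
        acc = np.zeros_like(u)
        acc[:, 1:] += sx[1:nx] * (u[:, :-1] - u[:, 1:])
        acc[:, :-1] += sx[1:nx] * (u[:, 1:] - u[:, :-1])
        acc[:, :, 1:] += sy[:, 1:ny] * (u[:, :, :-1] - u[:, :, 1:])
        acc[:, :, :-1] += sy[:, 1:ny] * (u[:, :, 1:] - u[:, :, :-1])
        acc[:, :, :, 1:] += sz[:, :, 1:nz] * (u[:, :, :, :-1] - u[:, :, :, 1:])
        acc[:, :, :, :-1] += sz[:, :, 1:nz] * (u[:, :, :, 1:] - u[:, :, :, :-1])
        yield start, acc.reshape(u.shape[0], -1)


def compute_unipolar_egms(
    field: VmField,
    grid: TissueGrid,
    layout: CatheterLayout,
    config: SimulationConfig,
    k_const: float | None = None,
) -> UnipolarTraces:
    """Green's-function forward solution from a stored transmembrane field."""
    if k_const is None:
        k_const = DEFAULT_K
    w = layout_weights(layout, grid, config, k_const)
    out = np.zeros((layout.n_electrodes, field.n_frames))
    for start, src in _source_frames(field, grid):
        out[:, start : start + src.shape[0]] = w @ src.T
    return UnipolarTraces(samples=out, fs=field.fs, layout=layout)


def simulate_unipolar(
    grid: TissueGrid,
    ionic: IonicModel,
    protocol: StimulusProtocol,
    config: SimulationConfig,
    layout: CatheterLayout,
    k_const: float | None = None,
    record_field: bool = False,
):
    """Run propagation and accumulate unipolar electrograms on the fly.

    Returns (UnipolarTraces, VmField | None).  The fused path avoids storing
    the full field when ``record_field`` is False.
    """
    if k_const is None:
        k_const = DEFAULT_K
    w = layout_weights(layout, grid, config, k_const) * ionic.v_amp
    egm, fld = integrate(
        grid, ionic, protocol, config, weights=w, record_field=record_field
    )
    return UnipolarTraces(samples=egm, fs=config.output_rate, layout=layout), fld


def calibrate_amplitude_constant(
    bipolar_p2p_mv: float, target_mv: float = 2.25, k_current: float | None = None
) -> float:
    """Linear rescale of k from a measured control bipolar p2p amplitude."""
    if bipolar_p2p_mv <= 0:
        raise ParameterError("measured p2p must be > 0")
    if k_current is None:
        k_current = DEFAULT_K
    return k_current * target_mv / bipolar_p2p_mv
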