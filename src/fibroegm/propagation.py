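"""Monodomain excitation propagation on the tissue grid.

The bidomain equations are reduced to a single reaction-diffusion PDE under
the equal-anisotropy assumption; the effective monodomain conductivity per
direction is the harmonic mean of the intracellular and extracellular
conductivities.  Collagen elements carry near-zero conductivity on both
sides and therefore act as diffusion barriers.  Integration is explicit
Euler on a finite-volume stencil with no-flux boundaries (numba kernels).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from . import _kernels
from .errors import CalibrationError, MeasurementError, ParameterError, StabilityError
from .ionic import IonicModel
from .tissue import TissueGrid, build_tissue

PACING_SITES = ("left-edge", "bottom-edge", "top-right-corner")


@dataclass(frozen=True)
class StimulusProtocol:
    """Transmembrane pacing protocol.

    A strip (or corner quadrant) of tissue receives a transmembrane current
    pulse of ``pulse_duration`` ms every ``bcl`` ms, ``n_beats`` times,
    starting at ``t_first`` ms.
    """

    site: str = "left-edge"
    bcl: float = 600.0  # ms
    n_beats: int = 4
    pulse_amplitude: float = 0.5  # normalized 1/ms, ~2x diastolic threshold
    pulse_duration: float = 2.0  # ms
    strip_width: float = 1.0  # mm
    corner_size: float = 3.0  # mm
    t_first: float = 5.0  # ms

    def validate(self) -> None:
        if self.n_beats < 1:
            raise ParameterError("n_beats must be >= 1")
        if not 0 < self.pulse_duration < self.bcl:
            raise ParameterError("pulse duration must lie in (0, bcl)")
        if self.site not in PACING_SITES:
            raise ParameterError(f"unknown pacing site {self.site!r}")

    def mask(self, grid: TissueGrid) -> np.ndarray:
        x, y, _ = grid.centers()
        lx, ly, _ = grid.dims_mm
        if self.site == "left-edge":
            return x <= self.strip_width
        if self.site == "bottom-edge":
            return y <= self.strip_width
        if self.site == "top-right-corner":
            return (x >= lx - self.corner_size) & (y >= ly - self.corner_size)
        raise ParameterError(f"unknown pacing site {self.site!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical and physical constants of a tissue run."""

    dt: float = 0.05  # ms
    output_rate: float = 2000.0  # Hz
    cm: float = 1.0  # uF/cm^2
    beta: float = 1400.0  # 1/cm, surface-to-volume ratio
    sigma_b: float = 0.7  # S/m, blood conductivity seen by the electrodes
    trace_length: float = 2.5  # s
    cond_scale: float = 1.0  # calibrated monodomain conductivity multiplier

    @property
    def out_every(self) -> int:
        step = 1000.0 / self.output_rate / self.dt
        n = int(round(step))
        if abs(step - n) > 1e-9 or n < 1:
            raise ParameterError("output_rate must be an integer multiple of 1/dt")
        return n

    @property
    def n_frames(self) -> int:
        return int(round(self.trace_length * self.output_rate))


@dataclass
class VmField:
    """Transmembrane voltage frames (mV) on the grid at the output rate."""

    data: np.ndarray  # float32 (n_frames, nx, ny, nz)
    fs: float  # Hz
    spacing: float  # mm

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def probe(self, ix: int, iy: int, iz: int) -> np.ndarray:
        return np.asarray(self.data[:, ix, iy, iz], dtype=float)


def _monodomain_diffusivity(grid: TissueGrid, config: SimulationConfig):
    """Per-element diffusivity (mm^2/ms) along x (longitudinal) and y/z."""
    # S/m == mS/mm; cm [uF/cm^2] -> uF/mm^2 is x0.01; beta [1/cm] -> 1/mm is x0.1
    denom = (config.beta * 0.1) * (config.cm * 0.01)
    sig_l = grid.sigma_i_long * grid.sigma_e_long / (grid.sigma_i_long + grid.sigma_e_long)
    sig_t = (
        grid.sigma_i_trans * grid.sigma_e_trans / (grid.sigma_i_trans + grid.sigma_e_trans)
    )
    d_l = config.cond_scale * sig_l / denom
    d_t = config.cond_scale * sig_t / denom
    return d_l, d_t


def _face_arrays(d_long, d_trans, spacing):
    """Harmonic-mean face conductances divided by spacing^2 (1/ms).

    Returned arrays have an extra leading entry per axis; index f[i] is the
    face between elements i-1 and i, with boundary faces left at zero.
    """
    nx, ny, nz = d_long.shape
    h2 = spacing * spacing

    def harm(a, b):
        return 2.0 * a * b / (a + b)

    fx = np.zeros((nx + 1, ny, nz))
    fy = np.zeros((nx, ny + 1, nz))
    fz = np.zeros((nx, ny, nz + 1))
    fx[1:nx] = harm(d_long[:-1], d_long[1:]) / h2
    fy[:, 1:ny] = harm(d_trans[:, :-1], d_trans[:, 1:]) / h2
    fz[:, :, 1:nz] = harm(d_trans[:, :, :-1], d_trans[:, :, 1:]) / h2
    # trim to kernel shapes (kernel indexes fx[i] for i in 1..nx-1 etc.)
    return fx[:nx], fy[:, :ny], fz[:, :, :nz]


def source_face_arrays(grid: TissueGrid):
    """Face conductances of the intracellular tensor (mS/mm / mm^2), used for
    the electrogram source term div(sigma_i grad Vm)."""
    return _face_arrays(grid.sigma_i_long, grid.sigma_i_trans, grid.spacing)


@lru_cache(maxsize=8)
def _prepaced_state(ionic: IonicModel, bcl: float):
    return ionic.prepace(bcl_ms=bcl)


def _check_stability(fx, fy, fz, dt):
    total = np.zeros(fx.shape[0:1] + fy.shape[1:2] + fz.shape[2:3])
    nx, ny, nz = total.shape
    total[1:] += fx[1:nx]
    total[:-1] += fx[1:nx]
    total[:, 1:] += fy[:, 1:ny]
    total[:, :-1] += fy[:, 1:ny]
    total[:, :, 1:] += fz[:, :, 1:nz]
    total[:, :, :-1] += fz[:, :, 1:nz]
    lam = dt * float(total.max())
    if lam > 1.0:
        raise StabilityError(
            f"dt = {dt} ms violates the explicit stability bound "
            f"(dt * max diffusion rate = {lam:.2f} > 1); reduce dt"
        )


def integrate(
    grid: TissueGrid,
    ionic: IonicModel,
    protocol: StimulusProtocol,
    config: SimulationConfig,
    weights: np.ndarray | None = None,
    record_field: bool = True,
):
    """Run the monodomain model.

    Returns (egm, field): ``egm`` is the lead-field projection of the
    intracellular source term at the output rate (None when no weights are
    given); ``field`` is a :class:`VmField` (None when not recorded).
    """
    protocol.validate()
    grid.validate()
    d_l, d_t = _monodomain_diffusivity(grid, config)
    fx, fy, fz = _face_arrays(d_l, d_t, grid.spacing)
    _check_stability(fx, fy, fz, config.dt)
    sx, sy, sz = source_face_arrays(grid)

    u0, h0 = _prepaced_state(ionic, protocol.bcl)
    u = np.full(grid.shape, u0, dtype=float)
    h = np.full(grid.shape, h0, dtype=float)

    stim_mask = protocol.mask(grid).astype(float)
    starts = np.array(
        [
            int(round((protocol.t_first + b * protocol.bcl) / config.dt))
            for b in range(protocol.n_beats)
        ],
        dtype=np.int64,
    )
    dur_steps = max(int(round(protocol.pulse_duration / config.dt)), 1)

    n_frames = config.n_frames
    n_steps = int(round(config.trace_length * 1000.0 / config.dt))
    if weights is None:
        weights = np.zeros((1, grid.n_elements))
        egm = np.zeros((1, n_frames))
        want_egm = False
    else:
        egm = np.zeros((weights.shape[0], n_frames))
        want_egm = True
    if record_field:
        field_data = np.empty((n_frames,) + grid.shape, dtype=np.float32)
    else:
        field_data = np.empty((1, 1, 1, 1), dtype=np.float32)

    status = _kernels.run_simulation(
        u,
        h,
        fx,
        fy,
        fz,
        sx,
        sy,
        sz,
        stim_mask,
        starts,
        dur_steps,
        protocol.pulse_amplitude,
        config.dt,
        n_steps,
        config.out_every,
        ionic.tau_in,
        ionic.tau_out,
        ionic.tau_open,
        ionic.tau_close,
        ionic.u_gate,
        np.ascontiguousarray(weights, dtype=float),
        egm,
        field_data,
        1 if record_field else 0,
    )
    if status != 0:
        raise StabilityError(
            f"transmembrane voltage left physiological bounds (dt = {config.dt} ms)"
        )

    field = None
    if record_field:
        field_data = ionic.to_mv(field_data).astype(np.float32)
        field = VmField(data=field_data, fs=config.output_rate, spacing=grid.spacing)
    return (egm if want_egm else None), field


def run_propagation(
    grid: TissueGrid,
    ionic: IonicModel,
    protocol: StimulusProtocol,
    config: SimulationConfig,
) -> VmField:
    """Monodomain run returning the transmembrane field at the output rate."""
    _, field = integrate(grid, ionic, protocol, config, weights=None, record_field=True)
    return field


def activation_time(vm: np.ndarray, fs: float, threshold_mv: float = -40.0) -> float:
    """Upstroke time (ms) of a single activation: the maximum-dVm/dt sample
    within the suprathreshold excursion, refined by quadratic interpolation.

    Raises MeasurementError unless exactly one activation is present.
    """
    vm = np.asarray(vm, dtype=float)
    above = vm > threshold_mv
    ups = np.flatnonzero(~above[:-1] & above[1:])
    if len(ups) == 0:
        raise MeasurementError("probe never activated")
    if len(ups) > 1:
        raise MeasurementError(f"probe activated {len(ups)} times, expected one")
    dv = np.diff(vm)
    i0 = int(ups[0])
    # search the steepest slope around the crossing
    lo = max(i0 - 10, 0)
    hi = min(i0 + 10, len(dv))
    i = lo + int(np.argmax(dv[lo:hi]))
    # quadratic refinement on the slope peak
    if 0 < i < len(dv) - 1:
        y0, y1, y2 = dv[i - 1], dv[i], dv[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-15 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return (i + 0.5 + delta) / fs * 1000.0


def measure_cv(field: VmField, probe_a, probe_b) -> float:
    """Plane-wave conduction velocity (cm/s) between two probe elements.

    Probes are (ix, iy, iz) element indices; each must activate exactly once.
    """
    ta = activation_time(field.probe(*probe_a), field.fs)
    tb = activation_time(field.probe(*probe_b), field.fs)
    dt_ms = abs(tb - ta)
    if dt_ms <= 1e-9:
        raise MeasurementError("zero activation-time delay between probes")
    dist_mm = field.spacing * float(
        np.linalg.norm(np.asarray(probe_a, dtype=float) - np.asarray(probe_b, dtype=float))
    )
    return dist_mm / dt_ms * 100.0  # mm/ms -> cm/s


def _strand_cv(ionic: IonicModel, config: SimulationConfig, scale: float,
               length_mm: float = 20.0, spacing: float = 0.25) -> float:
    grid = build_tissue((length_mm, spacing, spacing), spacing)
    cfg = replace(config, cond_scale=scale, trace_length=0.25, output_rate=2000.0)
    protocol = StimulusProtocol(site="left-edge", n_beats=1, t_first=2.0)
    field = run_propagation(grid, ionic, protocol, cfg)
    ia = int(round(0.3 * grid.nx))
    ib = int(round(0.8 * grid.nx)) - 1
    return measure_cv(field, (ia, 0, 0), (ib, 0, 0))


def calibrate_conductivity(
    target_cv_cm_s: float,
    ionic: IonicModel,
    config: SimulationConfig,
    tol: float = 0.02,
    max_iter: int = 12,
) -> float:
    """Find the monodomain conductivity scale reproducing a plane-wave CV.

    A 1-D strand is paced from one end and the scale is iterated with the
    square-root law CV ~ sqrt(scale) until the measured velocity is within
    ``tol`` (relative) of the target.  Returns the scale.
    """
    if target_cv_cm_s <= 0:
        raise ParameterError("target CV must be > 0")
    scale = config.cond_scale
    for _ in range(max_iter):
        try:
            cv = _strand_cv(ionic, config, scale)
        except MeasurementError as exc:
            raise CalibrationError(f"strand failed to propagate at scale {scale}") from exc
        except StabilityError as exc:
            raise CalibrationError(
                f"target {target_cv_cm_s} cm/s unreachable: scale {scale:.3g} "
                "exceeds the stable-integration bound"
            ) from exc
        if abs(cv - target_cv_cm_s) / target_cv_cm_s < tol:
            return scale
        scale *= (target_cv_cm_s / cv) ** 2
        if not 1e-4 < scale < 1e4:
            raise CalibrationError(
                f"conduction velocity {target_cv_cm_s} cm/s unreachable "
                f"(scale diverged to {scale:.2e})"
            )
    raise CalibrationError(
        f"calibration did not converge to {target_cv_cm_s} cm/s in {max_iter} iterations"
    )
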