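"""Numba inner loops of the monodomain solver and electrogram accumulation.

The solver is a finite-volume explicit Euler scheme on a regular grid with
per-face diffusivities (1/ms units: conductance already divided by the
squared spacing).  Boundary faces and collagen-adjacent faces carry zero
(near-zero) conductance, so no-flux boundaries and diffusion barriers fall
out of the same stencil.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _reaction(u, h, du, dh, tau_in, tau_out, tau_open, tau_close, u_gate):
    nx, ny, nz = u.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                uu = u[i, j, k]
                hh = h[i, j, k]
                du[i, j, k] += hh * uu * uu * (1.0 - uu) / tau_in - uu / tau_out
                if uu < u_gate:
                    dh[i, j, k] = (1.0 - hh) / tau_open
                else:
                    dh[i, j, k] = -hh / tau_close


@njit(cache=True)
def _weighted_laplacian(u, fx, fy, fz, out):
    """out[i,j,k] = sum over faces of f_face * (u_neighbor - u_center).

    fx has shape (nx+1, ny, nz) etc.; boundary faces must be zero.
    """
    nx, ny, nz = u.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = 0.0
                uc = u[i, j, k]
                if i > 0:
                    acc += fx[i, j, k] * (u[i - 1, j, k] - uc)
                if i < nx - 1:
                    acc += fx[i + 1, j, k] * (u[i + 1, j, k] - uc)
                if j > 0:
                    acc += fy[i, j, k] * (u[i, j - 1, k] - uc)
                if j < ny - 1:
                    acc += fy[i, j + 1, k] * (u[i, j + 1, k] - uc)
                if k > 0:
                    acc += fz[i, j, k] * (u[i, j, k - 1] - uc)
                if k < nz - 1:
                    acc += fz[i, j, k + 1] * (u[i, j, k + 1] - uc)
                out[i, j, k] = acc


@njit(cache=True)
def run_simulation(
    u,
    h,
    dx_face,
    dy_face,
    dz_face,
    sx_face,
    sy_face,
    sz_face,
    stim_mask,
    stim_starts,
    stim_dur_steps,
    stim_amp,
    dt,
    n_steps,
    out_every,
    tau_in,
    tau_out,
    tau_open,
    tau_close,
    u_gate,
    weights,
    egm_out,
    field_out,
    record_field,
):
    """Advance the monodomain model, sampling electrograms at output frames.

    weights: (n_electrodes, n_elements) lead-field matrix applied to the
    intracellular source density div(sigma_i grad Vm); egm_out has shape
    (n_electrodes, n_frames).  field_out (n_frames, nx, ny, nz) is filled
    when record_field is nonzero.  Returns 0 on success, 1 on blow-up.
    """
    nx, ny, nz = u.shape
    du = np.empty_like(u)
    dh = np.empty_like(u)
    src = np.empty(nx * ny * nz)
    n_frames = egm_out.shape[1]
    frame = 0
    n_stim = stim_starts.shape[0]
    for step in range(n_steps):
        if step % out_every == 0 and frame < n_frames:
            # intracellular source term at Vm scale is proportional to the
            # sigma_i-weighted Laplacian of u; amplitude scale folded into weights
            _weighted_laplacian(u, sx_face, sy_face, sz_face, du)
            src[:] = du.ravel()
            egm_out[:, frame] = weights @ src
            if record_field:
                for i in range(nx):
                    for j in range(ny):
                        for k in range(nz):
                            field_out[frame, i, j, k] = u[i, j, k]
            frame += 1
        # diffusion into du, then reaction added in place
        _weighted_laplacian(u, dx_face, dy_face, dz_face, du)
        _reaction(u, h, du, dh, tau_in, tau_out, tau_open, tau_close, u_gate)
        stim_on = False
        for s in range(n_stim):
            if stim_starts[s] <= step < stim_starts[s] + stim_dur_steps:
                stim_on = True
                break
        if stim_on:
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        u[i, j, k] += dt * (du[i, j, k] + stim_amp * stim_mask[i, j, k])
                        h[i, j, k] += dt * dh[i, j, k]
        else:
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        u[i, j, k] += dt * du[i, j, k]
                        h[i, j, k] += dt * dh[i, j, k]
        if step % 200 == 0:
            m = np.abs(u).max()
            if not np.isfinite(m) or m > 3.0:
                return 1
    return 0
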