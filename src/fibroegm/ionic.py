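"""Reduced atrial ionic kinetics.

A two-variable phenomenological membrane model (Mitchell-Schaeffer type)
drives excitation: a normalized voltage u in [0, 1] and a recovery gate h.

    du/dt = h * u^2 * (1 - u) / tau_in  -  u / tau_out  +  J_stim
    dh/dt = (1 - h) / tau_open   if u <  u_gate
          = -h / tau_close       if u >= u_gate

Physical membrane potential is an affine map Vm = v_rest + v_amp * u (mV).
Two parameter sets are provided: a control atrial variant with an action
potential duration near 200 ms and an AF-remodeled variant with a shortened
APD near 140 ms (electrical remodeling under persistent atrial
fibrillation shortens the atrial action potential).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class IonicModel:
    """Two-variable reduced membrane model (per-capacitance convention).

    The state vector is (u, h) with resting values (0, 1); time constants in
    ms.  ``i_ion`` follows the sign convention of the transmembrane current
    balance: du/dt = -i_ion + stimulus (the diffusion term is added by the
    tissue solver).
    """

    name: str
    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 150.0
    u_gate: float = 0.13
    v_rest: float = -80.0  # mV
    v_amp: float = 100.0  # mV

    state_names = ("u", "h")
    resting_state = (0.0, 1.0)

    def rates(self, u: float, h: float, j_stim: float = 0.0):
        """(du/dt, dh/dt) in 1/ms."""
        du = h * u * u * (1.0 - u) / self.tau_in - u / self.tau_out + j_stim
        dh = (1.0 - h) / self.tau_open if u < self.u_gate else -h / self.tau_close
        return du, dh

    def i_ion(self, u: float, h: float) -> float:
        """Total ionic current per unit capacitance (1/ms, normalized units)."""
        return -(h * u * u * (1.0 - u) / self.tau_in - u / self.tau_out)

    def to_mv(self, u: np.ndarray) -> np.ndarray:
        return self.v_rest + self.v_amp * np.asarray(u)

    # -- single-cell utilities -------------------------------------------------

    def step(self, u, h, dt, j_stim=0.0):
        du, dh = self.rates(u, h, j_stim)
        return u + dt * du, h + dt * dh

    def simulate_cell(
        self,
        duration_ms: float,
        dt: float = 0.02,
        stim_times=(1.0,),
        stim_duration: float = 2.0,
        stim_amplitude: float = 0.5,
        state=None,
    ):
        """Explicit-Euler single-cell run; returns (t, u, h) arrays."""
        n = int(round(duration_ms / dt))
        u, h = self.resting_state if state is None else state
        t = np.arange(n) * dt
        uu = np.empty(n)
        hh = np.empty(n)
        stim_times = np.asarray(stim_times, dtype=float)
        for i in range(n):
            ti = i * dt
            j = stim_amplitude if np.any(
                (ti >= stim_times) & (ti < stim_times + stim_duration)
            ) else 0.0
            uu[i], hh[i] = u, h
            u, h = self.step(u, h, dt, j)
        return t, uu, hh

    def prepace(
        self,
        bcl_ms: float = 600.0,
        max_beats: int = 100,
        dt: float = 0.02,
        tol: float = 1e-4,
    ):
        """Pace a single cell to its limit cycle and return the end-diastolic
        state, used to initialize tissue simulations.

        Stops early once the state sampled just before each stimulus changes
        by less than ``tol`` between consecutive beats.
        """
        u, h = self.resting_state
        prev = np.array([u, h])
        for _ in range(max_beats):
            _, uu, hh = self.simulate_cell(
                bcl_ms, dt=dt, stim_times=(1.0,), state=(u, h)
            )
            u, h = uu[-1], hh[-1]
            cur = np.array([u, h])
            if np.max(np.abs(cur - prev)) < tol:
                break
            prev = cur
        return float(u), float(h)

    def apd(self, dt: float = 0.02, threshold: float = 0.1) -> float:
        """Action potential duration (ms) at the given normalized threshold
        for a single suprathreshold stimulus from rest."""
        _, uu, _ = self.simulate_cell(600.0, dt=dt, stim_times=(1.0,))
        above = uu > threshold
        if not above.any():
            raise ParameterError("stimulus failed to elicit an action potential")
        idx = np.flatnonzero(above)
        return float((idx[-1] - idx[0]) * dt)


#: Control atrial variant (APD ~ 200 ms).
CONTROL = IonicModel(name="control", tau_close=100.0)

#: AF-remodeled variant: faster repolarization, APD ~ 140 ms.
AF_REMODELED = IonicModel(name="af-remodeled", tau_close=72.0, tau_out=5.2)


def get_ionic_model(name: str) -> IonicModel:
    try:
        return {"control": CONTROL, "af-remodeled": AF_REMODELED, "af": AF_REMODELED}[
            name
        ]
    except KeyError:
        raise ParameterError(f"unknown ionic model {name!r}") from None
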