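"""Deterministic signal generators for tests, demos, and clinical stand-ins.

``fixture_signals`` produces analytically known traces (sinusoid, white
noise, AR noise, biphasic wavelet trains with ground-truth activity
windows) and "control-substitute" electrograms: control simulations with
jittered conduction velocity (28-42 cm/s), noise level (15-25 dB), and
small electrode heights (0-0.5 mm) that emulate the role of clinically
recorded non-fibrotic signals.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .noise import ARModel, DEFAULT_CLINICAL_AR, generate_noise

FS = 2000.0

FIXTURE_KINDS = ("sinusoid", "white-noise", "ar-noise", "biphasic-train",
                 "control-substitute")


def biphasic_wavelet(width_ms: float = 20.0, amplitude_mv: float = 1.0,
                     fs: float = FS) -> np.ndarray:
    """Biphasic deflection (derivative-of-Gaussian) of the given support."""
    n = int(round(width_ms / 1000.0 * fs))
    t = np.linspace(-3.0, 3.0, n)
    w = -t * np.exp(-0.5 * t * t)
    return amplitude_mv * w / np.max(np.abs(w))


def fixture_signals(kind: str, params: dict | None = None,
                    rng: np.random.Generator | None = None):
    """Generate a fixture trace; deterministic under the supplied rng.

    Returns the trace for analytic kinds; ``biphasic-train`` returns
    (trace, truth_windows); ``control-substitute`` returns a feature-table
    DataFrame (see :func:`control_substitute_batch`).
    """
    params = dict(params or {})
    if rng is None:
        rng = np.random.default_rng(params.pop("seed", 0))
    if kind == "sinusoid":
        freq = params.get("freq_hz", 100.0)
        dur = params.get("duration_s", 2.5)
        amp = params.get("amplitude_mv", 1.0)
        fs = params.get("fs", FS)
        t = np.arange(int(round(dur * fs))) / fs
        return amp * np.sin(2 * np.pi * freq * t)
    if kind == "white-noise":
        n = int(params.get("n", int(2.5 * FS)))
        sigma = params.get("sigma_mv", 1.0)
        return rng.normal(0.0, sigma, size=n)
    if kind == "ar-noise":
        model = params.get("model", DEFAULT_CLINICAL_AR)
        if not isinstance(model, ARModel):
            raise ParameterError("params['model'] must be an ARModel")
        n = int(params.get("n", int(2.5 * FS)))
        return generate_noise(model, n, rng)
    if kind == "biphasic-train":
        return biphasic_train(
            n_wavelets=int(params.get("n_wavelets", 4)),
            duration_s=params.get("duration_s", 2.5),
            width_ms=params.get("width_ms", 20.0),
            amplitude_mv=params.get("amplitude_mv", 1.0),
            baseline_sigma_mv=params.get("baseline_sigma_mv", 0.01),
            fs=params.get("fs", FS),
            rng=rng,
        )
    if kind == "control-substitute":
        from .pipeline import StudyConfig, build_hybrid_dataset

        config = params.get("config", StudyConfig())
        seed = int(rng.integers(2**31))
        n_sims = int(params.get("n_sims", 1))
        from dataclasses import replace

        cfg = replace(config, densities=(), n_substitute_sims=n_sims)
        df = build_hybrid_dataset(cfg, seed=seed)
        return df[df.provenance == "control-substitute"]
    raise ParameterError(f"unknown fixture kind {kind!r}")


def biphasic_train(
    n_wavelets: int = 4,
    duration_s: float = 2.5,
    width_ms: float = 20.0,
    amplitude_mv: float = 1.0,
    baseline_sigma_mv: float = 0.01,
    fs: float = FS,
    rng: np.random.Generator | None = None,
):
    """Baseline noise plus evenly spaced biphasic wavelets.

    Returns (trace, truth) with truth a list of (start, end) sample windows
    covering each wavelet's support — the ground truth for activity
    detection tests.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(duration_s * fs))
    x = rng.normal(0.0, baseline_sigma_mv, size=n)
    w = biphasic_wavelet(width_ms, amplitude_mv, fs)
    onsets = np.linspace(0.15 * n, 0.85 * n, n_wavelets).astype(int)
    truth = []
    for o in onsets:
        x[o : o + len(w)] += w[: max(n - o, 0)]
        truth.append((int(o), int(o + len(w))))
    return x, truth
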