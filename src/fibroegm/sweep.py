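"""Electrode-height degradation sweeps and synthetic-map demonstrations.

Propagation is independent of the catheter height, so each substrate
condition is simulated once with the transmembrane field recorded; raising
the electrodes only changes the Green's-function lead field.  The sweep
re-derives electrograms and features at every height and scores a
contact-trained classifier against them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import SplitSpec, greedy_select, split, train_tree
from .electrodes import compute_unipolar_egms
from .features import FEATURE_NAMES
from .ionic import get_ionic_model
from .mapping import FibroticPatch, generate_synthetic_map, map_dice_report, predict_map
from .noise import DEFAULT_CLINICAL_AR
from .pipeline import (
    DENSITY_LABELS,
    SMOKE_CONFIG,
    StudyConfig,
    TRANSMURALITY_LABELS,
    _catheter,
    _trace_rows,
    calibrate_cv_scales,
)
from .propagation import integrate
from .tissue import FibrosisSpec, apply_fibrosis, build_tissue


def _simulate_condition_fields(config: StudyConfig, scales: dict, rng):
    """One recorded-field simulation per substrate condition.

    Returns a list of (meta, grid, field); control first, then every
    density x transmurality at one texture seed each.
    """
    ionic = get_ionic_model(config.ionic)
    grid0 = build_tissue(config.patch_mm, config.spacing_mm)
    cv = config.cvs[0]
    site = config.pacing_sites[0]
    cfg = config.sim_config(scales[cv])
    protocol = config.protocol(site)
    out = []
    _, field = integrate(grid0, ionic, protocol, cfg, record_field=True)
    out.append((
        dict(sim_id="ctrl", provenance="simulated", binary_label="non-fibrotic",
             density_class="none", transmurality_class="none",
             catheter=config.catheter, cv=cv, pacing_site=site,
             texture_seed=-1, height=0.0, snr_db=config.snr_db),
        grid0, field,
    ))
    for d in config.densities:
        for t in config.transmuralities:
            seed = int(rng.integers(2**31))
            spec = FibrosisSpec(
                density=d, transmural_depth=min(t, config.patch_mm[2]),
                region_center=config.center,
                region_radius=config.region_radius_mm, seed=seed,
            )
            grid = apply_fibrosis(grid0, spec)
            _, field = integrate(grid, ionic, protocol, cfg, record_field=True)
            out.append((
                dict(sim_id=f"fib-d{DENSITY_LABELS[d]}-t{TRANSMURALITY_LABELS[t]}",
                     provenance="simulated", binary_label="fibrotic",
                     density_class=DENSITY_LABELS[d],
                     transmurality_class=TRANSMURALITY_LABELS[t],
                     catheter=config.catheter, cv=cv, pacing_site=site,
                     texture_seed=seed, height=0.0, snr_db=config.snr_db),
                grid, field,
            ))
    return out


def _contact_reference_power(conditions, config):
    from .pipeline import reference_signal_power

    lay = _catheter(config, height=0.0)
    controls = []
    for meta, grid, field in conditions:
        if meta["binary_label"] == "non-fibrotic":
            uni = compute_unipolar_egms(field, grid, lay, config.sim_config())
            controls.append(uni.samples)
    return reference_signal_power(controls, fs=2000.0)


def _table_at_height(conditions, config, height, rng, noise_model,
                     signal_power=None):
    rows = []
    for meta, grid, field in conditions:
        lay = _catheter(config, height=height)
        uni = compute_unipolar_egms(field, grid, lay, config.sim_config())
        m = dict(meta)
        m["height"] = height
        rows += _trace_rows(uni.samples, uni.fs, lay, noise_model,
                            config.snr_db, rng, m, signal_power=signal_power)
    return pd.DataFrame(rows)


def run_height_sweep(
    config: StudyConfig = SMOKE_CONFIG,
    heights: tuple = (0.0, 0.5, 1.1, 2.0, 3.0, 4.1),
    seed: int = 7,
    task: str = "binary",
    n_train_reps: int = 3,
    noise_model=DEFAULT_CLINICAL_AR,
) -> pd.DataFrame:
    """Train at contact, evaluate at increasing electrode heights.

    Returns a (height_mm, accuracy) table.  ``n_train_reps`` independent
    noise realizations of the contact table enlarge the training pool.
    """
    if sorted(heights) != list(heights) or heights[0] != 0:
        raise ValueError("heights must be ascending and start at 0")
    rng = np.random.default_rng(seed)
    scales = calibrate_cv_scales(config)
    conditions = _simulate_condition_fields(config, scales, rng)
    ref_power = _contact_reference_power(conditions, config)

    contact = pd.concat(
        [_table_at_height(conditions, config, 0.0, rng, noise_model,
                          signal_power=ref_power)
         for _ in range(n_train_reps)],
        ignore_index=True,
    )
    train_set, val, _ = split(contact, SplitSpec(seed=seed), task)
    feats = greedy_select(train_set, val, task, seed=seed) or [FEATURE_NAMES[0]]
    model = train_tree(train_set, feats, task, seed=seed)

    from .classify import height_sweep as _sweep

    tables = {
        h: _table_at_height(conditions, config, h, rng, noise_model,
                            signal_power=ref_power)
        for h in heights
    }
    classes = sorted(contact[
        {"binary": "binary_label", "density": "density_class",
         "transmurality": "transmurality_class"}[task]].unique().tolist())
    return _sweep(model, tables, classes=classes)


def synthetic_map_demo(
    seed: int = 7,
    config: StudyConfig = SMOKE_CONFIG,
    grid_shape: tuple = (12, 12),
    noise_model=DEFAULT_CLINICAL_AR,
):
    """Planar synthetic substrate map scored against its own ground truth.

    A bipolar-trace library is simulated per condition; map points draw
    library traces for their local substrate.  A binary tree trained on the
    library features predicts each point, and the report carries
    truth-vs-voltage and truth-vs-prediction Dice indices.
    """
    rng = np.random.default_rng(seed)
    scales = calibrate_cv_scales(config)
    conditions = _simulate_condition_fields(config, scales, rng)
    ref_power = _contact_reference_power(conditions, config)

    library = {}
    table = pd.concat(
        [_table_at_height(conditions, config, 0.0, rng, noise_model,
                          signal_power=ref_power)
         for _ in range(3)],
        ignore_index=True,
    )
    from .processing import filter_unipolar, make_bipolar
    from .noise import add_noise

    for meta, grid, field in conditions:
        lay = _catheter(config, height=0.0)
        uni = compute_unipolar_egms(field, grid, lay, config.sim_config())
        key = (meta["binary_label"], meta["density_class"],
               meta["transmurality_class"])
        traces = []
        noisy = np.stack([
            filter_unipolar(
                add_noise(uni.samples[e], noise_model, config.snr_db, rng,
                          signal_power=ref_power),
                fs=uni.fs)
            for e in range(uni.samples.shape[0])
        ])
        for i, j in lay.bipoles:
            traces.append(make_bipolar(noisy[i], noisy[j], fs=uni.fs).samples)
        library.setdefault(key, []).extend(traces)

    def trace_factory(condition, rng_):
        pool = library.get(tuple(condition))
        if pool is None:  # nearest available condition (maps may ask for
            pool = library[  # densities the library does not carry)
                min(library, key=lambda k: (k[0] != condition[0]))]
        return pool[int(rng_.integers(len(pool)))]

    train_set, val, _ = split(table, SplitSpec(seed=seed), "binary")
    feats = greedy_select(train_set, val, "binary", seed=seed) or [FEATURE_NAMES[0]]
    model = train_tree(train_set, feats, "binary", seed=seed)

    fib_keys = [k for k in library if k[0] == "fibrotic"]
    patches = [
        FibroticPatch(center=(25.0, 25.0), radius=12.0,
                      density=fib_keys[0][1], transmurality=fib_keys[0][2])
    ]
    if len(fib_keys) > 1:
        patches.append(
            FibroticPatch(center=(60.0, 60.0), radius=10.0,
                          density=fib_keys[-1][1],
                          transmurality=fib_keys[-1][2]))
    substrate_map = generate_synthetic_map(
        patches, trace_factory, rng, extent_mm=(80.0, 80.0),
        grid_shape=grid_shape, map_id=f"demo-seed{seed}")
    predict_map(model, substrate_map)
    return substrate_map, map_dice_report(substrate_map)
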