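"""Plain-text I/O: traces, segment tables, feature tables, models, reports.

Traces are tab-separated text with a minimal commented header carrying the
schema version, sampling rate and units; columns are electrode (or bipole)
ids.  Feature and segment tables are CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .noise import ARModel

TRACE_SCHEMA = "fibroegm-trace-1"


def write_traces(path, samples: np.ndarray, fs: float, ids=None,
                 units: str = "mV") -> None:
    """Write (n_channels, n_samples) traces as delimited text."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n_ch = samples.shape[0]
    if ids is None:
        ids = [f"e{i}" for i in range(n_ch)]
    if len(ids) != n_ch:
        raise DataError("number of ids must match number of channels")
    header = (
        f"# schema={TRACE_SCHEMA}\n"
        f"# fs_hz={fs:g}\n"
        f"# units={units}\n"
        + "\t".join(ids)
    )
    np.savetxt(path, samples.T, delimiter="\t", header=header, comments="",
               fmt="%.6g")


def read_traces(path):
    """Read a trace file; returns (samples (n_channels, n), fs, ids)."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while lines[i].startswith("#"):
        key, _, val = lines[i][1:].strip().partition("=")
        meta[key.strip()] = val.strip()
        i += 1
    if meta.get("schema") != TRACE_SCHEMA:
        raise DataError(f"unrecognized trace schema in {path}")
    ids = lines[i].rstrip("\n").split("\t")
    data = np.loadtxt(lines[i + 1 :], delimiter="\t", ndmin=2)
    return data.T, float(meta["fs_hz"]), ids


def write_segments_table(path, rows) -> None:
    """Segment table CSV: trace id, start/end/duration ms, p2p mV."""
    pd.DataFrame(
        rows,
        columns=["trace_id", "start_ms", "end_ms", "duration_ms", "p2p_mv"],
    ).to_csv(path, index=False)


def read_segments_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ar_model(path, model: ARModel) -> None:
    Path(path).write_text(model.to_json())


def read_ar_model(path) -> ARModel:
    return ARModel.from_json(Path(path).read_text())


def write_report(path, report, extra: dict | None = None) -> None:
    """Evaluation report as structured text (JSON)."""
    payload = {
        "schema": "fibroegm-report-1",
        "task": report.task,
        "n_realizations": report.n_realizations,
        "accuracy_mean": report.accuracy_mean,
        "accuracy_se": report.accuracy_se,
        "sensitivity_mean": report.sensitivity_mean,
        "sensitivity_se": report.sensitivity_se,
        "specificity_mean": report.specificity_mean,
        "specificity_se": report.specificity_se,
        "validation_accuracy_mean": report.validation_accuracy_mean,
        "classes": report.classes,
        "confusion": np.asarray(report.confusion).tolist(),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def plot_confusion(report, path) -> None:
    """Render the summed confusion matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = np.asarray(report.confusion, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(cm, cmap="Blues")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, f"{int(cm[i, j])}", ha="center", va="center")
    ax.set_xticks(range(len(report.classes)), report.classes, rotation=45)
    ax.set_yticks(range(len(report.classes)), report.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("truth")
    ax.set_title(f"{report.task}: {report.accuracy_mean:.1f} % accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_field(path, field, dt_ms: float | None = None) -> None:
    """Transmembrane field frames as a compressed array container with a
    metadata block (grid shape, spacing mm, sampling, units mV/ms)."""
    np.savez_compressed(
        path,
        vm_mv=field.data,
        fs_hz=np.array([field.fs]),
        spacing_mm=np.array([field.spacing]),
        dt_ms=np.array([dt_ms if dt_ms is not None else 1000.0 / field.fs]),
        units=np.array(["mV", "ms"]),
        schema=np.array(["fibroegm-field-1"]),
    )


def read_field(path):
    """Read a field container written by :func:`write_field`."""
    from .propagation import VmField

    with np.load(path, allow_pickle=False) as z:
        if str(z["schema"][0]) != "fibroegm-field-1":
            raise DataError(f"unrecognized field schema in {path}")
        return VmField(
            data=z["vm_mv"],
            fs=float(z["fs_hz"][0]),
            spacing=float(z["spacing_mm"][0]),
        )
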