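"""Substrate maps: voltage-cutoff labeling, classifier predictions, and
Sorensen-Dice comparison on planar synthetic maps with known ground truth.

Clinical electroanatomical geometries are not modeled; a synthetic map is a
planar grid of points, each carrying a bipolar trace drawn from a substrate
condition, the clinical-style low/high voltage label (0.5 mV cutoff on
peak-to-peak amplitude), the generating ground truth, and classifier
predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .classify import TrainedModel
from .errors import DataError, NoActivityError, ParameterError
from .features import extract_features
from .processing import detect_activity, peak_to_peak

VOLTAGE_CUTOFF_MV = 0.5


@dataclass
class MapPoint:
    point_id: int
    x: float
    y: float
    z: float = 0.0
    p2p: float | None = None
    voltage_label: str | None = None  # "low" | "high"
    true_binary: str = "non-fibrotic"
    true_density: str = "none"
    true_transmurality: str = "none"
    predictions: dict = field(default_factory=dict)
    usable: bool = True
    trace: np.ndarray | None = field(default=None, repr=False)


@dataclass
class SubstrateMap:
    points: list
    map_id: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.points:
            raise DataError("a substrate map needs at least one point")
        ids = [p.point_id for p in self.points]
        if len(set(ids)) != len(ids):
            raise DataError("map point ids must be unique")

    def point_set(self, predicate) -> set:
        return {p.point_id for p in self.points if predicate(p)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            d = asdict(p)
            d.pop("trace")
            preds = d.pop("predictions")
            for k, v in preds.items():
                d[f"pred_{k}"] = v
            rows.append(d)
        return pd.DataFrame(rows)


def voltage_labels(points: list, cutoff_mv: float = VOLTAGE_CUTOFF_MV) -> list:
    """Label each point low/high voltage by its p2p against the cutoff.

    A p2p exactly at the cutoff is labeled high (strict < rule).
    """
    for p in points:
        if p.p2p is None:
            raise DataError(f"point {p.point_id} has no p2p value")
        p.voltage_label = "low" if p.p2p < cutoff_mv else "high"
    return points


def dice(set_a: set, set_b: set) -> float:
    """Sorensen-Dice index 2|A&B| / (|A| + |B|); two empty sets give 1."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def predict_map(model: TrainedModel, substrate_map: SubstrateMap,
                fs: float = 2000.0) -> SubstrateMap:
    """Attach classifier predictions to every usable map point.

    Points whose trace yields no activity are flagged unusable and excluded
    from downstream Dice computations rather than aborting the map.
    """
    for p in substrate_map.points:
        if p.trace is None:
            raise DataError(f"point {p.point_id} has no trace")
        segs = detect_activity(p.trace, fs=fs)
        try:
            fv = extract_features(p.trace, segs, fs=fs)
        except NoActivityError:
            p.usable = False
            continue
        p.usable = True
        p.p2p = fv.p2p if p.p2p is None else p.p2p
        row = pd.DataFrame([fv.as_dict()])
        p.predictions[model.task] = str(model.tree.predict(
            row[model.features].to_numpy())[0])
    return substrate_map


@dataclass(frozen=True)
class FibroticPatch:
    """Circular fibrotic patch on the planar pseudo-atrium."""

    center: tuple  # (x, y) mm
    radius: float  # mm
    density: str  # "10" | "20" | "40" | "60"
    transmurality: str  # "0.5" | "1" | "2"


def generate_synthetic_map(
    patches: list,
    trace_factory,
    rng: np.random.Generator,
    extent_mm: tuple = (80.0, 80.0),
    grid_shape: tuple = (20, 20),
    map_id: str = "synthetic",
) -> SubstrateMap:
    """Planar pseudo-atrium sampled on a regular grid of points.

    ``trace_factory(condition, rng)`` returns a bipolar trace (mV, 2 kHz)
    for a substrate condition tuple (binary, density, transmurality); the
    map generator only decides geometry and ground truth.  Overlapping
    patches are rejected.
    """
    for i, a in enumerate(patches):
        for b in patches[i + 1 :]:
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < a.radius + b.radius:
                raise ParameterError("fibrotic patches overlap")
    xs = np.linspace(0, extent_mm[0], grid_shape[0])
    ys = np.linspace(0, extent_mm[1], grid_shape[1])
    points = []
    pid = 0
    for x in xs:
        for y in ys:
            truth = ("non-fibrotic", "none", "none")
            for patch in patches:
                if np.hypot(x - patch.center[0], y - patch.center[1]) <= patch.radius:
                    truth = ("fibrotic", patch.density, patch.transmurality)
                    break
            trace = trace_factory(truth, rng)
            segs = detect_activity(trace)
            p2p = max((peak_to_peak(trace, s) for s in segs), default=0.0)
            points.append(
                MapPoint(
                    point_id=pid,
                    x=float(x),
                    y=float(y),
                    p2p=float(p2p),
                    true_binary=truth[0],
                    true_density=truth[1],
                    true_transmurality=truth[2],
                    trace=np.asarray(trace, dtype=float),
                )
            )
            pid += 1
    m = SubstrateMap(points=points, map_id=map_id,
                     metadata={"extent_mm": extent_mm, "grid_shape": grid_shape})
    voltage_labels(m.points)
    return m


def map_dice_report(substrate_map: SubstrateMap, task: str = "binary") -> dict:
    """Truth-vs-voltage and truth-vs-prediction Dice over usable points."""
    usable = [p for p in substrate_map.points if p.usable]
    truth = {p.point_id for p in usable if p.true_binary == "fibrotic"}
    low = {p.point_id for p in usable if p.voltage_label == "low"}
    pred = {
        p.point_id
        for p in usable
        if p.predictions.get(task) not in (None, "non-fibrotic", "none")
    }
    return {
        "n_usable": len(usable),
        "dice_truth_voltage": dice(truth, low),
        "dice_truth_prediction": dice(truth, pred),
    }


def write_map(substrate_map: SubstrateMap, path) -> None:
    """Structured-text map serialization (point records, no traces)."""
    payload = {
        "schema": "fibroegm-map-1",
        "map_id": substrate_map.map_id,
        "metadata": substrate_map.metadata,
        "points": [
            {k: v for k, v in asdict(p).items() if k != "trace"}
            for p in substrate_map.points
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_map(path) -> SubstrateMap:
    with open(path) as fh:
        payload = json.load(fh)
    points = [MapPoint(**d) for d in payload["points"]]
    return SubstrateMap(points=points, map_id=payload["map_id"],
                        metadata=payload.get("metadata", {}))
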