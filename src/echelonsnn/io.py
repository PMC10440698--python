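"""Readers and writers for the model, spike and plan containers.

A layer model is stored as a JSON manifest (dimensions, density, delay
range, precision) next to a ``.npz`` payload holding the dense integer
weight/delay/mask arrays; small models can additionally be exported as CSV
(one file each for weights, delays and the connectivity mask).  Spike trains
travel either as a dense 0/1 CSV matrix (rows = timesteps) or as an event
CSV with header ``t,neuron``.  Merge records, circle sets and split plans —
exactly the objects preloaded to PEs before inference — serialize to JSON.
All indices are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .densify import CircleSet, MergeGroup, MergeRecord
from .splitting import Processor, Rectangle, SplitMode, SplitPlan
from .model import SNNLayerModel, SpikeTrain

__all__ = ["write_model", "read_model", "export_model_csv",
           "read_model_csv", "write_spikes", "read_spikes",
           "write_spike_events", "read_spike_events",
           "plan_to_json", "plan_from_json", "write_plan", "read_plan"]

_MANIFEST_VERSION = 1


class ContainerError(ValueError):
    """Malformed or inconsistent on-disk container."""


def write_model(path: str | Path, model: SNNLayerModel) -> Path:
    """Write a JSON manifest plus an ``.npz`` array payload; returns the
    manifest path."""
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    payload = path.with_suffix(".npz")
    manifest = {
        "container": "echelonsnn-model",
        "version": _MANIFEST_VERSION,
        "n_pre": model.n_pre,
        "n_post": model.n_post,
        "delay_range": model.delay_range,
        "density": model.density,
        "arrays": payload.name,
    }
    np.savez(payload, weights=model.weights, delays=model.delays,
             connected=model.connected)
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_model(path: str | Path) -> SNNLayerModel:
    path = Path(path)
    try:
        manifest = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ContainerError(f"{path}: unreadable manifest: {exc}") from exc
    if manifest.get("container") != "echelonsnn-model":
        raise ContainerError(f"{path}: not a model manifest")
    payload = path.parent / manifest["arrays"]
    try:
        with np.load(payload) as npz:
            arrays = {k: npz[k] for k in ("weights", "delays", "connected")}
    except (OSError, KeyError, ValueError) as exc:
        raise ContainerError(f"{payload}: unreadable array payload: {exc}") from exc
    try:
        return SNNLayerModel(
            n_pre=int(manifest["n_pre"]), n_post=int(manifest["n_post"]),
            delay_range=int(manifest["delay_range"]),
            weights=arrays["weights"], delays=arrays["delays"],
            connected=arrays["connected"],
            density=float(manifest["density"]))
    except (KeyError, ValueError) as exc:
        raise ContainerError(f"{path}: inconsistent model: {exc}") from exc


def export_model_csv(directory: str | Path, model: SNNLayerModel) -> Path:
    """CSV export for small models: weights.csv, delays.csv, connected.csv
    plus the JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in (("weights", model.weights), ("delays", model.delays),
                      ("connected", model.connected.astype(int))):
        np.savetxt(directory / f"{name}.csv", arr, fmt="%d", delimiter=",")
    manifest = {
        "container": "echelonsnn-model-csv", "version": _MANIFEST_VERSION,
        "n_pre": model.n_pre, "n_post": model.n_post,
        "delay_range": model.delay_range, "density": model.density,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_model_csv(directory: str | Path) -> SNNLayerModel:
    directory = Path(directory)
    try:
        manifest = json.loads((directory / "manifest.json").read_text())
        arrays = {name: np.loadtxt(directory / f"{name}.csv", delimiter=",",
                                   dtype=np.int64, ndmin=2)
                  for name in ("weights", "delays", "connected")}
    except (OSError, json.JSONDecodeError, ValueError) as exc:
        raise ContainerError(f"{directory}: unreadable CSV container: {exc}") from exc
    return SNNLayerModel(
        n_pre=int(manifest["n_pre"]), n_post=int(manifest["n_post"]),
        delay_range=int(manifest["delay_range"]),
        weights=arrays["weights"], delays=arrays["delays"],
        connected=arrays["connected"].astype(bool),
        density=float(manifest["density"]))


def write_spikes(path: str | Path, spikes: SpikeTrain) -> Path:
    """Dense 0/1 CSV matrix, one row per timestep."""
    path = Path(path)
    np.savetxt(path, spikes.values, fmt="%d", delimiter=",")
    return path


def read_spikes(path: str | Path) -> SpikeTrain:
    try:
        values = np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    except (OSError, ValueError) as exc:
        raise ContainerError(f"{path}: unreadable spike CSV: {exc}") from exc
    return SpikeTrain(values)


def write_spike_events(path: str | Path, spikes: SpikeTrain) -> Path:
    """Event CSV with header ``t,neuron`` (0-based)."""
    t, n = np.nonzero(spikes.values)
    lines = ["t,neuron"] + [f"{a},{b}" for a, b in zip(t, n)]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_spike_events(path: str | Path, T: int, n: int) -> SpikeTrain:
    text = Path(path).read_text().strip().splitlines()
    if not text or text[0].strip() != "t,neuron":
        raise ContainerError(f"{path}: missing 't,neuron' header")
    values = np.zeros((T, n), dtype=np.int64)
    for lineno, line in enumerate(text[1:], start=2):
        try:
            t, neuron = (int(x) for x in line.split(","))
            values[t, neuron] = 1
        except (ValueError, IndexError) as exc:
            raise ContainerError(f"{path}:{lineno}: bad event '{line}'") from exc
    return SpikeTrain(values)


# ---------------------------------------------------------------------------
# plan JSON
# ---------------------------------------------------------------------------

def _rect_to_json(r: Rectangle) -> dict:
    return {"row_start": r.row_start, "row_count": r.row_count,
            "col_start": r.col_start, "col_count": r.col_count,
            "processor": r.processor.value}


def _rect_from_json(d: dict) -> Rectangle:
    return Rectangle(d["row_start"], d["row_count"], d["col_start"],
                     d["col_count"], Processor(d["processor"]))


def plan_to_json(plan: SplitPlan, circles: CircleSet | None = None,
                 record: MergeRecord | None = None) -> dict:
    doc = {
        "container": "echelonsnn-plan",
        "version": _MANIFEST_VERSION,
        "mode": plan.mode.value,
        "m": plan.m,
        "rectangles": [_rect_to_json(r) for r in plan.rectangles],
        "arm_strip": _rect_to_json(plan.arm_strip) if plan.arm_strip else None,
        "pe_groups": [[_rect_to_json(r) for r in g] for g in plan.pe_groups],
        "per_pe_value_counts": plan.per_pe_value_counts,
    }
    if circles is not None:
        doc["circles"] = {"circles_list": circles.circles_list,
                          "reversed_circle_list": circles.reversed_circle_list}
    if record is not None:
        doc["merge_record"] = {
            "kept": record.kept,
            "groups": [{"base_row": g.base_row, "members": g.members}
                       for g in record.groups]}
    return doc


def plan_from_json(doc: dict) -> tuple[SplitPlan, CircleSet | None,
                                       MergeRecord | None]:
    if doc.get("container") != "echelonsnn-plan":
        raise ContainerError("not a plan document")
    plan = SplitPlan(
        rectangles=[_rect_from_json(r) for r in doc["rectangles"]],
        pe_groups=[[_rect_from_json(r) for r in g] for g in doc["pe_groups"]],
        per_pe_value_counts=list(doc["per_pe_value_counts"]),
        m=doc["m"], mode=SplitMode(doc["mode"]),
        arm_strip=_rect_from_json(doc["arm_strip"]) if doc.get("arm_strip")
        else None)
    circles = None
    if "circles" in doc:
        circles = CircleSet(
            circles_list=[list(c) for c in doc["circles"]["circles_list"]],
            reversed_circle_list=[list(c) for c in
                                  doc["circles"]["reversed_circle_list"]])
    record = None
    if "merge_record" in doc:
        record = MergeRecord(
            groups=[MergeGroup(g["base_row"],
                               [tuple(m) for m in g["members"]])
                    for g in doc["merge_record"]["groups"]],
            kept=list(doc["merge_record"]["kept"]))
    return plan, circles, record


def write_plan(path: str | Path, plan: SplitPlan,
               circles: CircleSet | None = None,
               record: MergeRecord | None = None) -> Path:
    Path(path).write_text(json.dumps(plan_to_json(plan, circles, record),
                                     indent=2))
    return Path(path)


def read_plan(path: str | Path):
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ContainerError(f"{path}: unreadable plan: {exc}") from exc
    return plan_from_json(doc)
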