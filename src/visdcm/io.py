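"""Readers and writers for the package's on-disk formats.

Time series and events are tab-separated UTF-8 text with '.' decimals and
Unix newlines; structured results (sidecars, posteriors, model spaces,
reports) are JSON.  Everything the package writes it can read back
losslessly (time series to 12 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import EventSchedule, build_input_regressors
from .dynamics import BoldTimeSeries
from .network import DCMParams
from .posterior import GaussianPosterior
from .synth import StudyDataset, SubjectData

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_events", "read_events",
    "write_posterior", "read_posterior",
    "write_study", "read_study",
    "write_json", "read_json",
]


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_timeseries(bold: BoldTimeSeries, path) -> None:
    """TSV with node-label header plus a JSON sidecar holding TR and units."""
    path = Path(path)
    labels = bold.node_labels or tuple(f"node{i}" for i in range(bold.y.shape[1]))
    df = pd.DataFrame(bold.y, columns=list(labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")
    write_json(
        {"TR": bold.tr, "slice_offset": bold.slice_offset,
         "units": "percent signal change", "nodes": list(labels)},
        path.with_suffix(".json"),
    )


def read_timeseries(path) -> BoldTimeSeries:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = read_json(sidecar_path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as err:
        raise FormatError(f"{path}: {err}") from err
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
            raise FormatError(f"{path}: non-numeric cell in column {col!r}, line {row}")
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1))[0]) + 2
        raise FormatError(f"{path}: ragged or missing values at line {row}")
    nodes = sidecar.get("nodes")
    if nodes is not None and list(df.columns) != list(nodes):
        raise FormatError(
            f"{path}: header {list(df.columns)} does not match sidecar nodes {nodes}")
    return BoldTimeSeries(
        y=df.to_numpy(float), tr=float(sidecar["TR"]),
        slice_offset=float(sidecar.get("slice_offset", 0.5)),
        node_labels=tuple(df.columns),
    )


def write_events(schedule: EventSchedule, path) -> None:
    schedule.to_frame().to_csv(Path(path), sep="\t", index=False,
                               float_format="%.17g", lineterminator="\n")


def read_events(path) -> EventSchedule:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return EventSchedule(events=[], trials=[])
    neg = df["duration"] < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0]) + 2
        raise FormatError(f"{path}: negative duration at line {row}")
    try:
        return EventSchedule.from_frame(df)
    except ValueError as err:
        raise FormatError(f"{path}: {err}") from err


def write_posterior(post: GaussianPosterior, path) -> None:
    write_json(post.to_dict(), path)


def read_posterior(path) -> GaussianPosterior:
    return GaussianPosterior.from_dict(read_json(path))


def write_study(study: StudyDataset, root) -> None:
    """Directory tree: one folder per subject plus a top-level manifest."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "visdcm-study",
        "version": 1,
        "provenance": dict(study.provenance),
        "subjects": [],
    }
    for sub in study.subjects:
        sdir = root / sub.subject_id
        sdir.mkdir(exist_ok=True)
        write_timeseries(sub.bold, sdir / "bold.tsv")
        write_events(sub.schedule, sdir / "events.tsv")
        pd.DataFrame({
            "trial_index": np.arange(len(sub.vividness)),
            "vividness": sub.vividness,
        }).to_csv(sdir / "vividness.tsv", sep="\t", index=False,
                  lineterminator="\n")
        if sub.true_params is not None:
            write_json(sub.true_params.to_dict(), sdir / "true_params.json")
        manifest["subjects"].append(sub.subject_id)
    write_json(manifest, root / "manifest.json")


def read_study(root) -> StudyDataset:
    root = Path(root)
    manifest = read_json(root / "manifest.json")
    if manifest.get("format") != "visdcm-study":
        raise FormatError(f"{root}: not a study directory")
    dt = float(manifest["provenance"].get("dt", 0.1))
    subjects = []
    for sid in manifest["subjects"]:
        sdir = root / sid
        bold = read_timeseries(sdir / "bold.tsv")
        schedule = read_events(sdir / "events.tsv")
        viv = pd.read_csv(sdir / "vividness.tsv", sep="\t")["vividness"].to_numpy(float)
        inputs = build_input_regressors(schedule, viv, dt=dt)
        true_path = sdir / "true_params.json"
        true_params = (DCMParams.from_dict(read_json(true_path))
                       if true_path.exists() else None)
        subjects.append(SubjectData(
            subject_id=sid, bold=bold, inputs=inputs, schedule=schedule,
            vividness=viv, true_params=true_params))
    ds = StudyDataset(subjects=subjects, provenance=manifest["provenance"])
    ds.validate()
    return ds
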