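"""Tab-delimited readers and writers for all pipeline artifacts.

Everything on disk is TSV (human-diffable, language-neutral) with fixed
6-decimal float formatting so repeated runs are byte-identical:

* time series — header row of ROI labels, one row per timepoint;
* connectivity / attribution matrices — ROI labels as header row and
  first column;
* subject manifest — columns subject_id, age, sex;
* atlas lookup — columns roi_label, network, hemisphere.

Model checkpoints are single-file ``.npz`` archives with the model spec
embedded as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ModelSpec, Network
from .types import ConnectivityMatrix, RoiTimeSeries, Subject

logger = logging.getLogger(__name__)

__all__ = [
    "read_timeseries", "write_timeseries",
    "read_matrix", "write_matrix",
    "read_manifest", "write_manifest",
    "read_atlas", "write_atlas",
    "save_checkpoint", "load_checkpoint",
    "write_provenance",
]

_FLOAT_FMT = "%.6f"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows carry a line number
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc


def read_timeseries(path: str | Path, subject_id: str | None = None) -> RoiTimeSeries:
    path = Path(path)
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate ROI label(s) in header: {dupes}")
    df = _read_tsv(path)
    labels = header
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        bad = df.apply(lambda col: pd.to_numeric(col, errors="coerce")).isna()
        row = int(bad.any(axis=1).idxmax())
        raise ValueError(f"{path}: non-numeric cell at data line {row + 2}") from exc
    sid = subject_id or path.stem
    return RoiTimeSeries(sid, values, labels)


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    header = "\t".join(ts.roi_labels)
    body = "\n".join("\t".join(_FLOAT_FMT % v for v in row) for row in ts.values)
    Path(path).write_text(header + "\n" + body + "\n")


def read_matrix(path: str | Path, validate: bool = True) -> ConnectivityMatrix:
    path = Path(path)
    df = _read_tsv(path)
    labels = [str(c) for c in df.columns[1:]]
    row_labels = df.iloc[:, 0].tolist()
    if row_labels != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    cm = ConnectivityMatrix(values=values, roi_labels=labels)
    if validate:
        asym = np.abs(values - values.T)
        if asym.size and asym.max() > 1e-6:
            i, j = np.unravel_index(asym.argmax(), asym.shape)
            raise ValueError(
                f"{path}: asymmetric at ({labels[i]}, {labels[j]}): "
                f"{values[i, j]:.6g} vs {values[j, i]:.6g}"
            )
        cm.values = (values + values.T) / 2.0
    return cm


def write_matrix(cm: ConnectivityMatrix, path: str | Path) -> None:
    lines = ["roi\t" + "\t".join(cm.roi_labels)]
    for lab, row in zip(cm.roi_labels, cm.values):
        lines.append(lab + "\t" + "\t".join(_FLOAT_FMT % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> list[Subject]:
    """Parse the subject manifest, excluding out-of-range ages (logged)."""
    df = _read_tsv(path)
    required = {"subject_id", "age"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    subjects = []
    for _, row in df.iterrows():
        age = float(row["age"])
        sex = str(row.get("sex", "NA"))
        try:
            subjects.append(Subject(str(row["subject_id"]), age, sex))
        except ValueError as exc:
            logger.warning("excluding subject %s: %s", row["subject_id"], exc)
    return subjects


def write_manifest(subjects: list[Subject], path: str | Path) -> None:
    lines = ["subject_id\tage\tsex\tgroup"]
    for s in subjects:
        lines.append(f"{s.subject_id}\t{s.age:g}\t{s.sex}\t{s.group}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_atlas(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"roi_label", "network", "hemisphere"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: atlas needs columns {sorted(required)}")
    if df["roi_label"].duplicated().any():
        dupes = df.loc[df["roi_label"].duplicated(), "roi_label"].tolist()
        raise ValueError(f"{path}: duplicate atlas label(s): {dupes[:5]}")
    return df


def write_atlas(rows: list[tuple[str, str, str]], path: str | Path) -> None:
    lines = ["roi_label\tnetwork\themisphere"]
    lines += [f"{lab}\t{net}\t{hemi}" for lab, net, hemi in rows]
    Path(path).write_text("\n".join(lines) + "\n")


def save_checkpoint(model: Network, path: str | Path) -> None:
    """Single-file weight archive with the ModelSpec manifest embedded."""
    state = model.state_dict()
    manifest = json.dumps({"format_version": 1, "spec": model.spec.to_dict()})
    np.savez(path, __manifest__=np.frombuffer(manifest.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> Network:
    with np.load(path) as archive:
        manifest = json.loads(bytes(archive["__manifest__"]).decode())
        spec = ModelSpec.from_dict(manifest["spec"])
        net = Network(spec)
        net.load_state_dict({k: archive[k] for k in archive.files if k != "__manifest__"})
    return net


def write_provenance(out_dir: str | Path, stage: str, seed: int, config: dict) -> None:
    """Record the stage, seed and configuration alongside every output."""
    import fcage

    record = {"stage": stage, "seed": seed, "config": config, "fcage_version": fcage.__version__}
    Path(out_dir, f"provenance_{stage}.json").write_text(json.dumps(record, indent=2, default=str))
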