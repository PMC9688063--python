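"""Reading and writing the package's on-disk formats.

Recordings travel as plain numeric CSV matrices (channels x samples, in
microvolts) with a JSON sidecar declaring the sampling rate and channel
names, or as EDF (read via :mod:`mne` when available). Templates, feature
tables, rankings and ground truth use CSV/JSON. Numeric CSVs keep full
double precision; leading ``#`` comment lines carry provenance and are
skipped on read.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .microstates import TemplateSet
from .montage import CHANNELS_1020, Montage, standard_1020
from .recording import Recording
from .simulate import GroundTruth

__all__ = [
    "write_recording_csv",
    "read_recording",
    "write_templates",
    "read_templates",
    "write_feature_table",
    "read_feature_table",
    "write_ground_truth",
    "read_ground_truth",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    """Write channels x samples CSV plus a JSON sidecar with metadata."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter=",")
    meta = {
        "fs": rec.fs,
        "channel_names": list(rec.montage.channel_names),
        "subject_id": rec.subject_id,
        "group": rec.group,
        "units": "uV",
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def _resolve_montage(channel_names: list[str]) -> Montage:
    std = standard_1020()
    known = [n for n in channel_names if n in CHANNELS_1020]
    if len(known) == len(channel_names):
        idx = [std.index(n) for n in channel_names]
        return Montage(tuple(channel_names), std.positions[idx])
    warnings.warn(
        "unknown channel names; falling back to positional layout",
        stacklevel=2,
    )
    n = len(channel_names)
    angles = 2 * np.pi * np.arange(n) / n
    pos = 0.8 * np.column_stack([np.cos(angles), np.sin(angles)])
    return Montage(tuple(channel_names), pos)


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    fs: float | None = None,
    channel_names: list[str] | None = None,
) -> Recording:
    """Read a recording from CSV (+ JSON sidecar) or EDF.

    CSV requires a sampling rate, either from the sidecar written by
    :func:`write_recording_csv` or via the ``fs`` argument. EDF reading
    uses :mod:`mne` and resolves the montage from the file's channel
    labels.
    """
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        meta: dict = {}
        if _sidecar(path).exists():
            meta = json.loads(_sidecar(path).read_text())
        fs = fs if fs is not None else meta.get("fs")
        if fs is None:
            raise ValueError(
                f"{path}: CSV recordings need a sampling rate (sidecar or fs=)"
            )
        data = np.loadtxt(path, delimiter=",", comments="#")
        names = channel_names or meta.get("channel_names")
        if names is None:
            names = [f"ch{i}" for i in range(data.shape[0])]
        return Recording(
            data=data, fs=float(fs), montage=_resolve_montage(list(names)),
            subject_id=meta.get("subject_id", path.stem),
            group=meta.get("group", ""),
        )
    if fmt == "edf":
        import mne  # lazy: only needed for EDF input

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        names = [n.strip().replace("EEG ", "") for n in raw.ch_names]
        return Recording(
            data=data, fs=float(raw.info["sfreq"]),
            montage=_resolve_montage(names), subject_id=path.stem,
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_templates(
    ts: TemplateSet, path: str | Path, montage: Montage | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Templates as a channels x K CSV plus JSON metadata."""
    path = Path(path)
    df = pd.DataFrame(
        ts.maps.T, columns=list(ts.labels),
        index=list(montage.channel_names) if montage else None,
    )
    df.to_csv(path, index=montage is not None)
    meta = {
        "labels": list(ts.labels), "gev": ts.gev,
        "n_restarts": ts.n_restarts, "seed": ts.seed,
    }
    meta.update(extra_meta or {})
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    df = pd.read_csv(path, index_col=0 if _has_index(path) else None)
    meta = json.loads(_sidecar(path).read_text())
    return TemplateSet(
        maps=df[meta["labels"]].to_numpy().T,
        labels=tuple(meta["labels"]),
        gev=meta.get("gev", float("nan")),
        n_restarts=meta.get("n_restarts", 0),
        seed=meta.get("seed"),
    )


def _has_index(path: Path) -> bool:
    with open(path) as f:
        first = f.readline()
    return first.startswith(",") or first.split(",")[0] not in ("A", "0")


def write_feature_table(
    table: pd.DataFrame, path: str | Path, header_comment: str = ""
) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        if header_comment:
            f.write(f"# {header_comment}\n")
        table.to_csv(f, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ground_truth(gt: GroundTruth, path_prefix: str | Path) -> tuple[Path, Path]:
    """Ground truth as JSON (parameters) + CSV label sequence."""
    prefix = Path(path_prefix)
    meta = {
        "group": gt.group,
        "seed": gt.seed,
        "params": {
            "occurrence_weight": list(gt.params.occurrence_weight),
            "mean_duration_ms": list(gt.params.mean_duration_ms),
            "gfp_scale": list(gt.params.gfp_scale),
            "duration_shape": gt.params.duration_shape,
            "noise_sd": gt.params.noise_sd,
        } if gt.params else None,
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=1))
    csv_path = prefix.with_suffix(".labels.csv")
    np.savetxt(csv_path, gt.state_sequence[None, :], fmt="%d", delimiter=",")
    return json_path, csv_path


def read_ground_truth(path_prefix: str | Path) -> tuple[dict, np.ndarray]:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    seq = np.loadtxt(
        prefix.with_suffix(".labels.csv"), delimiter=",", dtype=int
    ).ravel()
    return meta, seq
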