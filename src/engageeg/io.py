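"""Readers and writers binding the pipeline stages together.

CSV (RFC-4180, UTF-8, '.' decimal) is the canonical interchange format;
EEG recordings are stored as rows = samples, columns = channels, with a
single ``#``-prefixed provenance/header line carrying the sampling
rate, subject and session. EDF input is supported through mne when a
file ends in ``.edf``; all outputs are CSV. A JSON manifest maps
subject/session to files and labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .preprocess import Recording

__all__ = [
    "write_recording_csv",
    "read_recording",
    "read_metrics_csv",
    "write_metrics_csv",
    "read_flow_csv",
    "write_flow_csv",
    "write_table",
    "write_manifest",
    "read_manifest",
]


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    header = (
        f"# engageeg recording fs={rec.fs} "
        f"subject={rec.subject_id} session={rec.session}\n"
    )
    frame = pd.DataFrame(rec.data.T, columns=list(rec.channel_names))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)
    return path


def _parse_recording_header(line: str) -> dict:
    meta = {}
    for tok in line.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def read_recording(
    path: str | Path,
    fs: float | None = None,
    subject_id: str | None = None,
    session: str | None = None,
) -> Recording:
    """Read a recording from CSV (or EDF, via mne)."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            data=raw.get_data() * 1e6,  # volts -> µV
            fs=float(raw.info["sfreq"]),
            channel_names=tuple(raw.ch_names),
            subject_id=subject_id or "",
            session=session or "",
        )

    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    meta = _parse_recording_header(first) if first.startswith("#") else {}
    frame = pd.read_csv(path, comment="#")
    fs = fs if fs is not None else float(meta.get("fs", 0) or 0)
    if fs <= 0:
        raise ValidationError(f"{path}: sampling rate not in header and not given")
    return Recording(
        data=frame.to_numpy().T,
        fs=fs,
        channel_names=tuple(frame.columns),
        subject_id=subject_id if subject_id is not None else meta.get("subject", ""),
        session=session if session is not None else meta.get("session", ""),
    )


def write_metrics_csv(metrics, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [(m.level, m.tc, m.tm, m.oh) for m in metrics],
        columns=["level", "tc", "tm", "oh"],
    )
    frame.to_csv(path, index=False)
    return path


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"level", "tc", "tm", "oh"}
    if not required <= set(frame.columns):
        raise ValidationError(
            f"{path}: metrics CSV needs columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    return frame


def write_flow_csv(responses, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in responses:
        row = {"subject_id": r.subject_id, "session": r.session}
        row.update({f"item_{i + 1}": v for i, v in enumerate(r.items)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_flow_csv(path: str | Path):
    from .flow import N_ITEMS, FlowScaleResponse

    frame = pd.read_csv(path, comment="#")
    item_cols = [f"item_{i + 1}" for i in range(N_ITEMS)]
    missing = [c for c in item_cols if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: flow CSV missing columns {missing}")
    return [
        FlowScaleResponse(
            items=tuple(int(row[c]) for c in item_cols),
            subject_id=str(row.get("subject_id", "")),
            session=str(row.get("session", "")),
        )
        for _, row in frame.iterrows()
    ]


def write_table(frame: pd.DataFrame, path: str | Path, sidecar: dict | None = None, index: bool = False) -> Path:
    """Write a CSV table with an optional JSON metadata sidecar."""
    path = Path(path)
    frame.to_csv(path, index=index)
    if sidecar is not None:
        with open(path.with_suffix(path.suffix + ".meta.json"), "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True, default=str)
    return path


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def read_manifest(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
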