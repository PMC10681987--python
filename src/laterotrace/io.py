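"""Session containers on disk, behavior CSV, and WAV stimulus reading.

Two interchangeable session dialects are supported and round-trip losslessly:

* **HDF5** — a single file with a ``traces`` dataset (trials x channels x
  samples, float64), ``sample_rate`` and JSON ``metadata`` attributes, and
  the channel/event tables stored as column datasets under ``channels/``
  and ``events/``.
* **Flat binary** — a directory with ``traces.bin`` (little-endian float64,
  C order), ``meta.json`` (shape, sample rate, channel table, metadata) and
  ``events.csv`` (onset/duration/time in seconds, 0-based trial indices).

Both carry a schema version; mismatches raise instead of mis-parsing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .session import RecordingSession

SCHEMA_VERSION = "1"

BEHAVIOR_COLUMNS = ["subject", "day", "trial", "type", "responded", "correct"]


def _df_to_group(df: pd.DataFrame, grp: h5py.Group) -> None:
    grp.attrs["columns"] = json.dumps(list(df.columns))
    for col in df.columns:
        vals = df[col].to_numpy()
        if vals.dtype == object or vals.dtype.kind in "US":
            grp.create_dataset(col, data=np.array(vals, dtype=h5py.string_dtype()))
        else:
            grp.create_dataset(col, data=vals)


def _group_to_df(grp: h5py.Group) -> pd.DataFrame:
    columns = json.loads(grp.attrs["columns"])
    data = {}
    for col in columns:
        vals = grp[col][()]
        if vals.dtype.kind in "OS":
            vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
        data[col] = vals
    return pd.DataFrame(data)


def write_session(path: str | Path, session: RecordingSession) -> None:
    """Write a session as HDF5 (or flat-binary if ``path`` has no suffix)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["sample_rate"] = session.sample_rate
            f.attrs["metadata"] = json.dumps(session.metadata)
            f.create_dataset("traces", data=session.traces)
            _df_to_group(session.channels, f.create_group("channels"))
            _df_to_group(session.events, f.create_group("events"))
    else:
        write_session_flat(path, session)


def read_session(path: str | Path) -> RecordingSession:
    """Read a session written by :func:`write_session` (either dialect)."""
    path = Path(path)
    if path.is_dir():
        return read_session_flat(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"not a readable session container: {path} ({exc})") from exc
    with f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"schema version mismatch: file has {version!r}, expected {SCHEMA_VERSION!r}"
            )
        return RecordingSession(
            traces=f["traces"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            channels=_group_to_df(f["channels"]),
            events=_group_to_df(f["events"]),
            metadata=json.loads(f.attrs["metadata"]),
        )


def write_session_flat(directory: str | Path, session: RecordingSession) -> None:
    """Flat-binary dialect: traces.bin + meta.json + events.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    session.traces.astype("<f8").tofile(directory / "traces.bin")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "shape": list(session.traces.shape),
        "dtype": "<f8",
        "sample_rate": session.sample_rate,
        "channels": session.channels.to_dict(orient="list"),
        "metadata": session.metadata,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    session.events.to_csv(directory / "events.csv", index=False)


def read_session_flat(directory: str | Path) -> RecordingSession:
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise ValueError(f"not a session directory (no meta.json): {directory}")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"schema version mismatch: {meta.get('schema_version')!r} != {SCHEMA_VERSION!r}"
        )
    shape = tuple(meta["shape"])
    traces = np.fromfile(directory / "traces.bin", dtype=meta["dtype"])
    if traces.size != int(np.prod(shape)):
        raise ValueError(
            f"corrupted traces.bin: {traces.size} values, expected {int(np.prod(shape))}"
        )
    events = pd.read_csv(directory / "events.csv")
    return RecordingSession(
        traces=traces.reshape(shape),
        sample_rate=float(meta["sample_rate"]),
        channels=pd.DataFrame(meta["channels"]),
        events=events,
        metadata=meta["metadata"],
    )


def write_behavior_log(path: str | Path, log: pd.DataFrame) -> None:
    log[BEHAVIOR_COLUMNS].to_csv(path, index=False)


def read_behavior_log(path: str | Path) -> pd.DataFrame:
    log = pd.read_csv(path)
    missing = [c for c in BEHAVIOR_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"behavior log missing columns: {missing}")
    return log


def read_wav(path: str | Path) -> tuple[float, np.ndarray]:
    """Read a mono PCM WAV file, returning (sample_rate, float waveform).

    Integer PCM is scaled to [-1, 1]; multi-channel audio is rejected.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"expected mono audio, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return float(rate), data
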