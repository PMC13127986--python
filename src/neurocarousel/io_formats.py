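"""Interchange formats for LFP, tracking and tidy result tables.

LFP travels as CSV (one column per channel, header = channel ids) or flat
little-endian float32 binary, both accompanied by a JSON sidecar declaring
sampling rate, channel ids, dtype and units.  EDF/EDF+ is accepted read-only
when :mod:`mne` is importable.  Tracking is a plain ``t,x,y`` CSV or the
DeepLabCut multi-header export dialect.

Conventions: positions in cm, times in seconds, 0-based sample indexing,
half-open windows ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LfpRecording",
    "Trajectory",
    "read_lfp",
    "write_lfp",
    "read_tracking",
    "write_tracking",
    "read_table",
    "write_table",
]


@dataclass
class LfpRecording:
    """Multichannel uniformly sampled voltage series.

    Parameters
    ----------
    channel_ids : list of str
        Electrode labels, one per channel.
    samples : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    fs : float
        Sampling rate in Hz (the study hardware samples at 2000 Hz).
    t0 : float
        Recording start time in seconds.
    meta : dict
        Free-form provenance (hardware band, filter settings, seed, ...).
    """

    channel_ids: list[str]
    samples: np.ndarray
    fs: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"{len(self.channel_ids)} channel ids but samples has "
                f"{self.samples.shape[0]} rows"
            )
        if self.samples.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, key: int | str) -> np.ndarray:
        """1-D view of one channel, by index or id."""
        if isinstance(key, str):
            key = self.channel_ids.index(key)
        return self.samples[key]


@dataclass
class Trajectory:
    """Timestamped 2-D positions in a declared reference frame.

    ``frame`` is ``"room"`` (laboratory-fixed) or ``"arena"`` (disc-fixed);
    the distinction matters only for the rotating-arena task.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame: str = "room"
    likelihood: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.frame not in ("room", "arena"):
            raise ValueError(f"frame must be 'room' or 'arena', got {self.frame!r}")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0


# ---------------------------------------------------------------------------
# LFP

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_lfp(rec: LfpRecording, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write *rec* as CSV (``.csv``) or flat float32 binary (``.f32``) plus sidecar.

    Returns the sidecar path.  Binary layout is sample-major (interleaved
    channels), little-endian float32.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if path.suffix == ".csv":
        pd.DataFrame(rec.samples.T, columns=rec.channel_ids).to_csv(path, index=False)
        dtype = "float64"
    elif path.suffix == ".f32":
        rec.samples.T.astype("<f4").tofile(path)
        dtype = "float32"
    else:
        raise ValueError(f"unsupported LFP extension {path.suffix!r} (use .csv or .f32)")
    meta = dict(rec.meta)
    sidecar.write_text(json.dumps({
        "fs": rec.fs,
        "channels": rec.channel_ids,
        "dtype": dtype,
        "units": "uV",
        "t0": rec.t0,
        "meta": meta,
    }, indent=1))
    return sidecar


def read_lfp(path: str | Path, sidecar: str | Path | None = None) -> LfpRecording:
    """Read an LFP recording from CSV/.f32 + JSON sidecar, or from EDF.

    The sidecar must declare ``fs`` and ``channels``; a channel-count
    mismatch with the data file is a hard error.  EDF files carry their own
    header and need no sidecar (requires :mod:`mne`).
    """
    path = Path(path)
    if path.suffix.lower() in (".edf", ".bdf"):
        return _read_edf(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar {sidecar} not found")
    info = json.loads(sidecar.read_text())
    if "fs" not in info:
        raise ValueError(f"sidecar {sidecar} does not declare 'fs'")
    channels = info.get("channels")
    if channels is None:
        raise ValueError(f"sidecar {sidecar} does not declare 'channels'")
    if path.suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.shape[1] != len(channels):
            raise ValueError(
                f"sidecar declares {len(channels)} channels but {path} has "
                f"{df.shape[1]} columns"
            )
        samples = df.to_numpy(dtype=float).T
    elif path.suffix == ".f32":
        raw = np.fromfile(path, dtype="<f4")
        n_ch = len(channels)
        if raw.size % n_ch:
            raise ValueError(
                f"{path} holds {raw.size} float32 values, not divisible by "
                f"{n_ch} declared channels"
            )
        samples = raw.reshape(-1, n_ch).T.astype(float)
    else:
        raise ValueError(f"unsupported LFP extension {path.suffix!r}")
    meta = dict(info.get("meta", {}))
    meta.setdefault("units", info.get("units", "uV"))
    meta.setdefault("source", str(path))
    return LfpRecording(
        channel_ids=list(channels),
        samples=samples,
        fs=float(info["fs"]),
        t0=float(info.get("t0", 0.0)),
        meta=meta,
    )


def _read_edf(path: Path) -> LfpRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return LfpRecording(
        channel_ids=list(raw.ch_names),
        samples=data,
        fs=float(raw.info["sfreq"]),
        t0=0.0,
        meta={"units": "uV", "source": str(path), "format": "edf"},
    )


# ---------------------------------------------------------------------------
# Tracking

def write_tracking(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y})
    if traj.likelihood is not None:
        df["likelihood"] = traj.likelihood
    df.to_csv(path, index=False)
    return path


def read_tracking(
    path: str | Path,
    dialect: str = "plain",
    bodypart: str | None = None,
    likelihood_threshold: float = 0.9,
    fs: float = 30.0,
    frame: str = "room",
) -> Trajectory:
    """Read a trajectory CSV.

    ``plain`` expects columns ``t,x,y`` (cm, s).  ``dlc`` expects the
    DeepLabCut export dialect (scorer / bodyparts / coords header rows);
    *bodypart* selects which tracked point to use and rows whose likelihood
    falls below *likelihood_threshold* are linearly interpolated from their
    neighbours.  DLC files index by video frame; *fs* converts frames to
    seconds.
    """
    path = Path(path)
    if dialect == "plain":
        df = pd.read_csv(path)
        missing = {"t", "x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"plain tracking CSV missing columns {sorted(missing)}")
        for col in ("x", "y"):
            if df[col].isna().all():
                raise ValueError(f"column {col!r} is entirely NaN")
        lik = df["likelihood"].to_numpy() if "likelihood" in df.columns else None
        return Trajectory(df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(),
                          frame=frame, likelihood=lik)
    if dialect == "dlc":
        return _read_dlc(path, bodypart, likelihood_threshold, fs, frame)
    raise ValueError(f"unknown tracking dialect {dialect!r}")


def _read_dlc(path: Path, bodypart: str | None, threshold: float, fs: float,
              frame: str) -> Trajectory:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    if bodypart is None:
        bodypart = bodyparts[0]
    if bodypart not in bodyparts:
        raise ValueError(f"bodypart {bodypart!r} not in {bodyparts}")
    scorer = df.columns.get_level_values(0)[0]
    x = df[(scorer, bodypart, "x")].to_numpy(dtype=float)
    y = df[(scorer, bodypart, "y")].to_numpy(dtype=float)
    lik = df[(scorer, bodypart, "likelihood")].to_numpy(dtype=float)
    if np.all(np.isnan(x)) or np.all(np.isnan(y)):
        raise ValueError("coordinate column is entirely NaN")
    t = df.index.to_numpy(dtype=float) / fs
    bad = (lik < threshold) | np.isnan(x) | np.isnan(y)
    if bad.all():
        raise ValueError("every row falls below the likelihood threshold")
    if bad.any():
        good = ~bad
        x = x.copy(); y = y.copy()
        x[bad] = np.interp(t[bad], t[good], x[good])
        y[bad] = np.interp(t[bad], t[good], y[good])
    return Trajectory(t, x, y, frame=frame, likelihood=lik)


# ---------------------------------------------------------------------------
# Tidy tables

def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy result table (one row per animal/window/metric)."""
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
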