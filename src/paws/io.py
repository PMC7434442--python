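"""Reading and writing trajectories, feature tables, and fitted models.

Trajectory files are plain CSV/TSV exports from markerless trackers
(ProAnalyst-style ``.csv``/``.txt``, pose-estimation CSV): one row per video
frame with a frame index and the paw's x (anterior/posterior) and y
(vertical) coordinates in the camera reference frame.  Column names vary by
tracker, so mapping is config-driven (names or 0-based indices); the default
expects a ``frame,x,y`` header.

Feature tables carry one row per trial: strain, mouse id, the ordered
stimulus label (cs < db < lp < hp), an optional condition label, and the
named kinematic features.

Fitted pain-scale models are serialized as JSON with floats written via
``repr`` (17 significant digits), so a save/load round trip is bit-exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import Config
from .errors import FormatError, ModelError, ParseError, TooShortError

logger = logging.getLogger("paws")

#: Ordered stimulus levels: cotton swab, dynamic brush, light pinprick,
#: heavy pinprick.  cs/db are innocuous ("no-pain"), lp/hp noxious ("pain").
STIMULI: tuple[str, ...] = ("cs", "db", "lp", "hp")

#: Stimuli counted as painful in the binary classification.
PAIN_STIMULI: frozenset[str] = frozenset({"lp", "hp"})

_DEFAULT_TRAJ_COLUMNS = {"frame": "frame", "x": "x", "y": "y"}

_TIME_UNIFORMITY_TOL = 1e-9


@dataclass
class Trajectory:
    """A single trial's paw-position time series.

    ``x`` is anterior/posterior displacement, ``y`` vertical height (larger =
    higher paw), both in the tracker's spatial units.  ``times`` is derived
    from the frame index as ``frame / fps`` (frames are 0-based).
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float
    trial_id: str = ""
    strain: str = ""
    mouse_id: str = ""
    stimulus: str = ""
    spatial_unit: str = "a.u."

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.times)
        if len(self.x) != n or len(self.y) != n:
            raise FormatError("times, x and y must have equal length")
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise FormatError("times must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > _TIME_UNIFORMITY_TOL:
                raise FormatError(
                    "times must be uniformly spaced to within 1e-9 s"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Trial span in seconds (last minus first sample time)."""
        return float(self.times[-1] - self.times[0])


def _resolve_column(
    df: pd.DataFrame, key: str, spec: str | int, path: Path
) -> pd.Series:
    if isinstance(spec, int):
        if spec >= df.shape[1]:
            raise FormatError(
                f"{path}: column index {spec} for '{key}' out of range "
                f"(file has {df.shape[1]} columns)"
            )
        return df.iloc[:, spec]
    if spec not in df.columns:
        raise FormatError(f"{path}: missing required column '{spec}' (for '{key}')")
    return df[spec]


def _numeric(series: pd.Series, name: str, path: Path) -> np.ndarray:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric value {series.iloc[row]!r} in column "
            f"'{name}' at data row {row}"
        )
    if converted.isna().any():
        row = int(np.flatnonzero(converted.isna().to_numpy())[0])
        raise ParseError(f"{path}: empty cell in column '{name}' at data row {row}")
    return converted.to_numpy(dtype=float)


def read_trajectory(
    path: str | Path,
    column_map: Mapping[str, str | int] | None = None,
    fps: float = 2000.0,
    invert_y: bool = False,
    delimiter: str | None = None,
    config: Config | None = None,
    **metadata: str,
) -> Trajectory:
    """Read a tracker-exported trajectory CSV.

    Parameters
    ----------
    column_map
        Maps the canonical keys ``frame``, ``x``, ``y`` to column names or
        0-based column indices.  Defaults to the ``frame,x,y`` header.
    fps
        Frame rate used to convert frame indices to seconds.
    invert_y
        Reflect y about its maximum so that larger y = higher paw (for
        down-positive image coordinates).
    delimiter
        Field delimiter; ``None`` auto-detects comma vs tab from the suffix
        (``.txt`` and ``.tsv`` default to tab).
    config
        If given, enforces the minimum length (Savitzky-Golay window) and
        supplies ``fps``/``invert_y`` defaults.
    metadata
        Optional ``trial_id``, ``strain``, ``mouse_id``, ``stimulus``,
        ``spatial_unit`` passed through to the :class:`Trajectory`.
    """
    path = Path(path)
    if config is not None:
        fps = config.fps
        invert_y = config.invert_y
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".txt", ".tsv"} else ","
    cmap = dict(_DEFAULT_TRAJ_COLUMNS)
    if column_map:
        cmap.update(column_map)
    has_index_specs = any(isinstance(v, int) for v in cmap.values())
    df = pd.read_csv(path, sep=delimiter, header=None if has_index_specs else 0,
                     float_precision="round_trip")
    if df.empty:
        raise FormatError(f"{path}: empty trajectory file")

    frame = _numeric(_resolve_column(df, "frame", cmap["frame"], path), "frame", path)
    x = _numeric(_resolve_column(df, "x", cmap["x"], path), "x", path)
    y = _numeric(_resolve_column(df, "y", cmap["y"], path), "y", path)

    min_len = config.sg_window if config is not None else 4
    if len(frame) < min_len:
        raise TooShortError(
            f"{path}: trajectory has {len(frame)} frames; at least {min_len} required"
        )
    if invert_y:
        y = np.max(y) - y
    times = frame / fps
    return Trajectory(times=times, x=x, y=y, fps=fps, **metadata)


def write_trajectory(traj: Trajectory, path: str | Path, delimiter: str = ",") -> None:
    """Write a trajectory back to CSV (``frame,x,y`` header)."""
    frame = np.round(traj.times * traj.fps).astype(int)
    df = pd.DataFrame({"frame": frame, "x": traj.x, "y": traj.y})
    # default float formatting is shortest round-trip repr: values survive
    # a write/read cycle bit-exactly
    df.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

#: Metadata columns recognized in feature tables.
META_COLUMNS = ("strain", "mouse_id", "stimulus", "condition", "trial_id")


def read_feature_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a per-trial feature table CSV.

    The stimulus column is normalized (case-insensitively) onto the ordered
    levels ``cs < db < lp < hp``; unrecognized labels raise ``ValueError``.
    Rows with missing feature values are dropped with a logged count.  Every
    non-metadata column is treated as a feature.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        missing = [v for v in column_map.values() if v not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing mapped column(s) {missing}")
        df = df.rename(columns=rename)
    for required in ("strain", "mouse_id", "stimulus"):
        if required not in df.columns:
            raise FormatError(f"{path}: missing required column '{required}'")

    stim = df["stimulus"].astype(str).str.strip().str.lower()
    bad = sorted(set(stim) - set(STIMULI))
    if bad:
        raise ValueError(
            f"{path}: unrecognized stimulus label(s) {bad}; expected one of {list(STIMULI)}"
        )
    df = df.copy()
    df["stimulus"] = pd.Categorical(stim, categories=list(STIMULI), ordered=True)
    df["mouse_id"] = df["mouse_id"].astype(str)
    df["strain"] = df["strain"].astype(str)

    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    n_before = len(df)
    df = df.dropna(subset=feature_cols).reset_index(drop=True)
    dropped = n_before - len(df)
    if dropped:
        logger.warning("dropped %d row(s) with missing feature values", dropped)
    logger.info("read %d trial rows from %s", len(df), path)
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature (non-metadata) columns of a table."""
    return [c for c in table.columns if c not in META_COLUMNS]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table to CSV, preserving numeric values exactly."""
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model (de)serialization
# ---------------------------------------------------------------------------


def save_model(model: "PainScaleModel", path: str | Path) -> None:  # noqa: F821
    """Serialize a fitted pain-scale model to JSON (bit-exact floats)."""
    from .pain_scale import PainScaleModel  # local import: avoid cycle

    if not isinstance(model, PainScaleModel):
        raise ModelError(f"expected a PainScaleModel, got {type(model).__name__}")
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path: str | Path) -> "PainScaleModel":  # noqa: F821
    """Load a pain-scale model saved by :func:`save_model`."""
    from .pain_scale import PainScaleModel

    path = Path(path)
    try:
        data = json.loads(path.read_text())
        return PainScaleModel.from_dict(data)
    except (OSError, ValueError, KeyError, TypeError) as exc:
        raise ModelError(f"could not deserialize model from {path}: {exc}") from exc
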