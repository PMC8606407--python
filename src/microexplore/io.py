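"""Reading, writing and clipping markerless-pose trajectory files.

The on-disk layout is the de-facto standard emitted by markerless pose
estimation tools: a CSV with a three-row header (``scorer``, ``bodyparts``,
``coords``), an integer frame-index column, and for every tracked body part
three columns ``x`` / ``y`` / ``likelihood``.  Coordinates are image
coordinates in pixels with the origin at the top-left corner of the camera
view, sampled at a fixed frame rate (30 fps by default).

Missing frames (e.g. occluded handle) are represented as NaN coordinates and
are propagated as missing by all downstream metrics — the time base is never
compacted or interpolated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_FPS = 30.0
HEADER_ROWS = ("scorer", "bodyparts", "coords")
COORD_FIELDS = ("x", "y", "likelihood")


class PoseFormatError(ValueError):
    """Raised when a pose CSV does not have the expected three-row header."""


class PoseParseError(ValueError):
    """Raised when a cell of the pose-file body cannot be parsed as a number."""


class InsufficientDataError(ValueError):
    """Raised when a track is too short for the requested clip."""


@dataclasses.dataclass
class PoseTrack:
    """Per-frame 2D coordinates (+ tracking likelihood) for one trial clip.

    Parameters
    ----------
    data
        Frame-indexed DataFrame with a two-level column index
        ``(bodypart, field)`` where field is ``x``, ``y`` or ``likelihood``.
        The frame index is strictly increasing from 0.
    fps
        Sampling rate in frames per second.
    participant_id, trial_number
        Optional provenance identifiers.
    scorer
        Network/scorer label stored in the first header row.
    """

    data: pd.DataFrame
    fps: float = DEFAULT_FPS
    participant_id: str | None = None
    trial_number: int | None = None
    scorer: str = "microexplore"

    def __post_init__(self) -> None:
        idx = np.asarray(self.data.index)
        if len(idx) and (idx[0] != 0 or np.any(np.diff(idx) <= 0)):
            raise ValueError("frame_index must be strictly increasing from 0")
        lik = self.data.xs("likelihood", axis=1, level=1)
        with np.errstate(invalid="ignore"):
            bad = ((lik < 0) | (lik > 1)).to_numpy()
        if np.any(bad & np.isfinite(lik.to_numpy())):
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def bodyparts(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def time_s(self) -> np.ndarray:
        """Time of each frame in seconds: frame_index / fps."""
        return np.asarray(self.data.index, dtype=float) / self.fps

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def mask_low_likelihood(self, threshold: float) -> "PoseTrack":
        """Mark frames below a tracking-likelihood threshold as missing.

        Coordinates of sub-threshold frames become NaN; the frames themselves
        stay in place so that the time base is intact.  No filtering is
        applied by default anywhere in the package — this is an opt-in step.
        """
        data = self.data.copy()
        for part in self.bodyparts:
            low = data[(part, "likelihood")] < threshold
            data.loc[low, (part, "x")] = np.nan
            data.loc[low, (part, "y")] = np.nan
        return dataclasses.replace(self, data=data)


def _pose_columns(bodyparts: Iterable[str], scorer: str) -> pd.MultiIndex:
    tuples = [(scorer, bp, c) for bp in bodyparts for c in COORD_FIELDS]
    return pd.MultiIndex.from_tuples(tuples, names=HEADER_ROWS)


def make_track(
    frames: dict[str, np.ndarray],
    fps: float = DEFAULT_FPS,
    participant_id: str | None = None,
    trial_number: int | None = None,
    scorer: str = "microexplore",
) -> PoseTrack:
    """Build a PoseTrack from per-bodypart ``(n, 3)`` arrays of x, y, likelihood."""
    cols = {}
    n = None
    for part, arr in frames.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"bodypart {part!r}: expected an (n, 3) array")
        if n is None:
            n = arr.shape[0]
        elif arr.shape[0] != n:
            raise ValueError("all bodyparts must have the same frame count")
        for j, field in enumerate(COORD_FIELDS):
            cols[(part, field)] = arr[:, j]
    df = pd.DataFrame(cols, index=pd.RangeIndex(n, name="frame"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=("bodyparts", "coords"))
    return PoseTrack(df, fps=fps, participant_id=participant_id,
                     trial_number=trial_number, scorer=scorer)


def read_pose_csv(path: str | Path, fps: float = DEFAULT_FPS,
                  participant_id: str | None = None,
                  trial_number: int | None = None) -> PoseTrack:
    """Read a pose CSV with the standard three-row header.

    Raises
    ------
    PoseFormatError
        If the three header rows (scorer / bodyparts / coords) are absent,
        naming the missing row.
    PoseParseError
        If a body cell is non-numeric, with row and column location.
    """
    path = Path(path)
    with open(path) as fh:
        head = [fh.readline().rstrip("\n") for _ in range(3)]
    for expect, line in zip(HEADER_ROWS, head):
        first = line.split(",", 1)[0] if line else ""
        if first != expect:
            raise PoseFormatError(
                f"{path}: missing header row {expect!r} "
                f"(found {first!r}); expected rows {HEADER_ROWS}")
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                         float_precision="round_trip")
    except ValueError as exc:
        raise PoseParseError(f"{path}: {exc}") from exc
    scorer = df.columns.get_level_values(0)[0]
    # drop the scorer level; it is uniform by construction of the format
    df.columns = pd.MultiIndex.from_tuples(
        [(b, c) for _, b, c in df.columns], names=("bodyparts", "coords"))
    for j, col in enumerate(df.columns):
        if not np.issubdtype(df.dtypes.iloc[j], np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = int(np.argmax(bad.to_numpy())) if bad.any() else 0
            raise PoseParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at "
                f"frame {df.index[row]}, column {col}")
    df.index = df.index.astype(int)
    df.index.name = "frame"
    return PoseTrack(df.astype(float), fps=fps, participant_id=participant_id,
                     trial_number=trial_number, scorer=scorer)


def write_pose_csv(track: PoseTrack, path: str | Path) -> None:
    """Write a PoseTrack in the three-row-header CSV layout.

    Floats are written at full (shortest round-trip) precision so that
    ``read_pose_csv(write_pose_csv(t))`` reproduces every value bit-exactly.
    """
    out = track.data.copy()
    out.columns = _pose_columns(track.bodyparts, track.scorer)
    out.index.name = None  # header-row labels come from the column-level names
    out.to_csv(path)


def write_pose_hdf5(track: PoseTrack, path: str | Path) -> None:
    """HDF5 sibling of the CSV layout (same schema; CSV is canonical)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["fps"] = track.fps
        f.attrs["scorer"] = track.scorer
        if track.participant_id is not None:
            f.attrs["participant_id"] = track.participant_id
        if track.trial_number is not None:
            f.attrs["trial_number"] = track.trial_number
        f.create_dataset("frame", data=np.asarray(track.data.index, dtype=np.int64))
        for part in track.bodyparts:
            g = f.create_group(part)
            for field in COORD_FIELDS:
                g.create_dataset(field, data=track.data[(part, field)].to_numpy())


def read_pose_hdf5(path: str | Path) -> PoseTrack:
    import h5py

    with h5py.File(path, "r") as f:
        frames = {
            part: np.column_stack([f[part][field][()] for field in COORD_FIELDS])
            for part in f if isinstance(f[part], h5py.Group)
        }
        track = make_track(frames, fps=float(f.attrs["fps"]),
                           participant_id=f.attrs.get("participant_id"),
                           trial_number=int(f.attrs["trial_number"])
                           if "trial_number" in f.attrs else None,
                           scorer=str(f.attrs.get("scorer", "microexplore")))
    return track


def clip_trial(track: PoseTrack, duration: float = 20.0) -> PoseTrack:
    """Trim a track to its first ``duration`` seconds.

    Keeps exactly the frames with ``time_s < duration``.  Tracks shorter than
    the clip raise :class:`InsufficientDataError`: every analysed trial must
    reach the common clip length so that all trials contribute equal data.
    Idempotent — clipping a clipped track is the identity.
    """
    n_keep = int(np.ceil(duration * track.fps - 1e-9))
    if track.n_frames < n_keep:
        raise InsufficientDataError(
            f"track spans {track.duration_s:.2f} s < clip duration {duration} s")
    data = track.data.iloc[:n_keep].copy()
    data.index = pd.RangeIndex(n_keep, name="frame")
    return dataclasses.replace(track, data=data)


def select_point(track: PoseTrack, bodypart: str = "handle_base") -> pd.DataFrame:
    """Extract the analysis point as a ``(time_s, x, y)`` frame-ordered table.

    The conventional analysis point is the beginning (base) of the rope
    handle.  Order is preserved and no frame is dropped; missing frames stay
    as NaN rows.
    """
    if bodypart not in track.bodyparts:
        raise KeyError(
            f"unknown bodypart {bodypart!r}; available: {track.bodyparts}")
    return pd.DataFrame({
        "time_s": track.time_s,
        "x": track.data[(bodypart, "x")].to_numpy(),
        "y": track.data[(bodypart, "y")].to_numpy(),
    }, index=track.data.index)


# ---------------------------------------------------------------------------
# Trial metadata

TRIAL_META_COLUMNS = [
    "participant_id", "condition", "trial_number", "trial_length",
    "motor_score", "trying_time", "max_force", "negative_affect",
    "help_seeking", "hints_recovery", "unproductive_intervals",
]

CONDITIONS = ("Easy", "Hard", "Impossible")


def read_trial_meta(path: str | Path) -> pd.DataFrame:
    """Read the one-row-per-participant-x-trial metadata table and validate it."""
    meta = pd.read_csv(path)
    missing = [c for c in TRIAL_META_COLUMNS if c not in meta.columns]
    if missing:
        raise PoseFormatError(f"{path}: metadata columns missing: {missing}")
    validate_trial_meta(meta)
    return meta


def validate_trial_meta(meta: pd.DataFrame) -> None:
    bad_cond = set(meta["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}")
    if not meta["trial_number"].isin([1, 2, 3]).all():
        raise ValueError("trial_number must be 1-3")
    if (meta["trial_length"] < 20).any():
        raise ValueError("trial_length must be >= 20 s (all analysed trials "
                         "survive the 20 s clip)")
    if not meta["unproductive_intervals"].isin(range(5)).all():
        raise ValueError("unproductive_intervals must be 0-4 per trial")
    if ((meta["motor_score"] < 0) | (meta["motor_score"] > 24)).any():
        raise ValueError("motor_score must be 0-24")


def write_trial_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)
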