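"""Imitative-baseline ("straight back" pull) anchor estimation and unit scale.

Not every infant produces a pull judged imitative, so exploration cannot be
centred on each participant's own imitation.  Instead, hand-labelled
imitative pull segments from every contributing participant are pooled and
their frame-weighted mean coordinate becomes a single, global anchor: the
"zero" of all deviation measures.  A pull counts as imitative when the rope
handle stays within the shoulders in both axes while the infant is properly
seated.

The pixel-to-centimetre scale is fixed by the camera geometry.  The default
scale is the ratio of the anchor's pixel x-coordinate to its physical
distance from the left edge of the frame (458.29 px / 35.25 cm); the
vertical pair (347.79 px / 26.75 cm) yields the same scale to three
decimals, confirming isotropic pixels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Default pixels-per-centimetre scale implied by the camera geometry.
DEFAULT_PX_PER_CM = 458.29 / 35.25


class AnchorEstimationError(ValueError):
    """Raised when no imitative frames are available to pool."""


@dataclasses.dataclass(frozen=True)
class ImitativeSegment:
    """A labelled sub-sequence of frames judged to be imitative pulling."""

    participant_id: str
    xy: np.ndarray  # (n, 2) pixel coordinates

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] == 0:
            raise ValueError("segment must be a non-empty (n, 2) array")
        object.__setattr__(self, "xy", xy)


@dataclasses.dataclass(frozen=True)
class ImitativeAnchor:
    """Pooled mean imitative-pull coordinate plus the pixel-to-cm scale."""

    x_anchor: float
    y_anchor: float
    n_frames: int
    n_contributors: int
    px_per_cm: float = DEFAULT_PX_PER_CM

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("anchor needs at least one contributing frame")
        if not (self.px_per_cm > 0):
            raise ValueError("px_per_cm must be positive")
        if self.x_anchor < 0 or self.y_anchor < 0:
            raise ValueError("anchor coordinates are image coordinates >= 0")


def estimate_anchor(segments: Iterable[ImitativeSegment],
                    px_per_cm: float = DEFAULT_PX_PER_CM) -> ImitativeAnchor:
    """Pool all imitative frames from all segments into one mean anchor.

    Every frame contributes with equal weight (frame pooling, not
    per-participant averaging), so longer imitative episodes weigh more.
    NaN frames (occlusions inside a labelled segment) are ignored.
    """
    segments = list(segments)
    if not segments:
        raise AnchorEstimationError("no imitative segments provided")
    xy = np.concatenate([s.xy for s in segments], axis=0)
    ok = ~np.isnan(xy).any(axis=1)
    if not ok.any():
        raise AnchorEstimationError("all imitative frames are missing")
    contributors = {s.participant_id for s in segments}
    mean = xy[ok].mean(axis=0)
    return ImitativeAnchor(
        x_anchor=float(mean[0]), y_anchor=float(mean[1]),
        n_frames=int(ok.sum()), n_contributors=len(contributors),
        px_per_cm=px_per_cm)


def px_to_cm(value, anchor: ImitativeAnchor | None = None,
             px_per_cm: float | None = None):
    """Convert pixels to centimetres with the anchor's (or an explicit) scale.

    The conversion is exact; rounding to two decimals happens only at
    presentation.  Non-finite input raises rather than propagating silently.
    """
    if px_per_cm is None:
        px_per_cm = anchor.px_per_cm if anchor is not None else DEFAULT_PX_PER_CM
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite pixel value cannot be converted")
    out = arr / px_per_cm
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# Segment manifest I/O

MANIFEST_COLUMNS = ["participant_id", "trial_number", "start_frame", "end_frame"]


def read_segment_manifest(path: str | Path) -> pd.DataFrame:
    """Read the imitative-segment manifest: rows point into pose files.

    ``start_frame`` is inclusive, ``end_frame`` exclusive.
    """
    man = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in man.columns]
    if missing:
        raise ValueError(f"{path}: manifest columns missing: {missing}")
    return man


def write_segment_manifest(man: pd.DataFrame, path: str | Path) -> None:
    man.to_csv(path, index=False)


def segments_from_manifest(man: pd.DataFrame, coords_by_trial,
                           ) -> list[ImitativeSegment]:
    """Materialise segments by slicing selected-point coordinate tables.

    Parameters
    ----------
    man
        Manifest table (participant_id, trial_number, start_frame, end_frame).
    coords_by_trial
        Mapping ``(participant_id, trial_number) -> (time_s, x, y)`` table
        as returned by :func:`microexplore.io.select_point`.
    """
    segments = []
    for row in man.itertuples(index=False):
        coords = coords_by_trial[(row.participant_id, row.trial_number)]
        sl = coords.iloc[int(row.start_frame):int(row.end_frame)]
        segments.append(ImitativeSegment(
            participant_id=str(row.participant_id),
            xy=sl[["x", "y"]].to_numpy()))
    return segments
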