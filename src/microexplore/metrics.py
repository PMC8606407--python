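"""Deviation, similarity and spatial-variability measures for one trial.

All measures derive from the selected handle coordinate series and the
global imitative anchor:

* ``dev_x``, ``dev_y`` — absolute per-frame deviation from the anchor in
  each axis (pixels).  Deviation in either direction counts equally.
* difference score — ``dev_x - dev_y``; positive values mean exploration is
  concentrated in the horizontal axis.
* imitative similarity — ``-(dev_x + dev_y)``; 0 is perfect imitation and
  more negative values mean more exploration.
* per-second variability — mean of the within-1-s-window sample SDs of x
  and y, each about the window's own mean ("the previous second"): local,
  real-time exploration.
* overall variability — mean of the whole-trial sample SDs of x and y,
  each about the trial-global mean: the global breadth of locations tested.

The two variability timescales deliberately dissociate: an infant who dwells
on one location per second but hops between distant locations across the
trial scores low per-second but high overall variability.

Missing frames (NaN) propagate as missing and reduce window n; they are
never interpolated or treated as zeros, because SD-based measures are biased
by interpolation.
"""

from __future__ import annotations

import math
from typing import Literal

import numpy as np
import pandas as pd

from .baseline import ImitativeAnchor

DDOF = 1  # sample SD everywhere


def _sample_sd(vals: np.ndarray) -> float:
    """Sample SD that is exactly 0 for a constant series.

    ``np.std`` of n identical values can return ~1e-13 because the pairwise
    mean need not be bit-equal to the value; a constant series must score
    exactly zero variability.
    """
    if vals.max() == vals.min():
        return 0.0
    return float(np.std(vals, ddof=DDOF))


def deviation_series(coords: pd.DataFrame, anchor: ImitativeAnchor) -> pd.DataFrame:
    """Per-frame deviations from the imitative anchor.

    Parameters
    ----------
    coords
        ``(time_s, x, y)`` table from :func:`microexplore.io.select_point`.
    anchor
        Global imitative anchor.

    Returns
    -------
    DataFrame with columns ``time_s, dev_x, dev_y, diff_score, similarity``.
    Missing frames stay NaN in every derived column.
    """
    if len(coords) == 0:
        raise ValueError("empty coordinate series")
    dev_x = (coords["x"] - anchor.x_anchor).abs()
    dev_y = (coords["y"] - anchor.y_anchor).abs()
    return pd.DataFrame({
        "time_s": coords["time_s"],
        "dev_x": dev_x,
        "dev_y": dev_y,
        "diff_score": dev_x - dev_y,
        "similarity": -(dev_x + dev_y),
    }, index=coords.index)


def _window_slices(n_frames: int, fps: float):
    """Non-overlapping right-closed 1 s windows aligned to clip start.

    Window k covers frames with time in (k-1 s, k s]; with frame times
    i / fps this is the frame block [k*fps, (k+1)*fps).  A trailing
    incomplete window is dropped.
    """
    per = int(round(fps))
    n_windows = n_frames // per
    return [(k, slice(k * per, (k + 1) * per)) for k in range(n_windows)]


def per_second_variability(coords: pd.DataFrame, fps: float = 30.0) -> pd.Series:
    """Windowed local variability: mean(SD(x), SD(y)) per complete second.

    Each SD is the sample SD about the window's own mean.  Windows with
    fewer than two present frames yield NaN.  The result is indexed by
    ``second_index`` (1 = the first second of the clip).
    """
    slices = _window_slices(len(coords), fps)
    if not slices:
        raise ValueError("need at least one complete 1 s window")
    x = coords["x"].to_numpy(dtype=float)
    y = coords["y"].to_numpy(dtype=float)
    out = {}
    for k, sl in slices:
        wx, wy = x[sl], y[sl]
        ok = ~np.isnan(wx) & ~np.isnan(wy)
        if ok.sum() < 2:
            out[k + 1] = np.nan
        else:
            out[k + 1] = 0.5 * (_sample_sd(wx[ok]) + _sample_sd(wy[ok]))
    s = pd.Series(out, name="sd_local")
    s.index.name = "second_index"
    return s


def overall_variability(coords: pd.DataFrame) -> float:
    """Whole-trial variability: mean(SD(x), SD(y)) about the global means."""
    x = coords["x"].to_numpy(dtype=float)
    y = coords["y"].to_numpy(dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return float("nan")
    return float(0.5 * (_sample_sd(x[ok]) + _sample_sd(y[ok])))


def sqrt_transform(values):
    """Elementwise square root for right-skewed non-negative measures."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("square-root transform requires non-negative values")
    out = np.sqrt(arr)
    return float(out) if np.isscalar(values) or arr.ndim == 0 else out


def subsample_1hz(series: pd.DataFrame, fps: float = 30.0,
                  duration: float = 20.0,
                  rule: Literal["last", "mean"] = "last") -> pd.DataFrame:
    """Thin a per-frame series to one record per second of the standard clip.

    The default rule keeps the final present frame of each 1 s window
    (frames 29, 59, ... at 30 fps); ``rule="mean"`` takes the window mean of
    each value column instead.  A 20 s clip therefore yields 20 records.
    """
    n_needed = int(round(duration * fps))
    if len(series) < n_needed:
        raise ValueError(
            f"series has {len(series)} frames; the standard {duration} s clip "
            f"needs {n_needed}")
    slices = _window_slices(n_needed, fps)
    value_cols = [c for c in series.columns if c != "time_s"]
    rows = []
    for k, sl in slices:
        win = series.iloc[sl]
        if rule == "last":
            present = win.dropna(subset=value_cols)
            rec = (present.iloc[-1] if len(present) else win.iloc[-1]).copy()
        elif rule == "mean":
            rec = win[value_cols].mean()
            rec["time_s"] = win["time_s"].iloc[-1]
        else:
            raise ValueError(f"unknown subsample rule {rule!r}")
        rec["second_index"] = k + 1
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("second_index")
    return out[["time_s", *value_cols]]


def exclude_outliers(values, rule: str = "zscore", k: float = 3.0):
    """Filter extreme values deterministically and log every exclusion.

    ``rule="none"`` is the identity; ``rule="zscore"`` removes values more
    than ``k`` sample SDs from the mean of the supplied collection.  The
    exact rule applied to the original cohort is not recoverable, so this
    default is a declared stand-in, not a reproduction.

    Returns
    -------
    (retained, log)
        ``retained`` is a float array of surviving values; ``log`` a
        DataFrame of ``(index, value, reason)`` for each removal.
    """
    arr = np.asarray(values, dtype=float)
    idx = np.arange(arr.size)
    ok_finite = np.isfinite(arr)
    if rule == "none":
        keep = ok_finite
        reason = "non-finite"
    elif rule == "zscore":
        mu = arr[ok_finite].mean() if ok_finite.any() else np.nan
        sd = arr[ok_finite].std(ddof=DDOF) if ok_finite.sum() > 1 else 0.0
        if sd > 0:
            keep = ok_finite & (np.abs(arr - mu) <= k * sd)
        else:
            keep = ok_finite
        reason = f"|z| > {k}"
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    dropped = ~keep
    log = pd.DataFrame({
        "index": idx[dropped],
        "value": arr[dropped],
        "reason": np.where(np.isfinite(arr[dropped]), reason, "non-finite"),
    })
    return arr[keep], log


def trial_metrics(coords: pd.DataFrame, anchor: ImitativeAnchor,
                  fps: float = 30.0, duration: float = 20.0,
                  subsample_rule: Literal["last", "mean"] = "last"):
    """All per-trial derived measures in one call.

    Returns
    -------
    dict with keys:
      ``deviation`` — per-frame DataFrame from :func:`deviation_series`;
      ``subsampled`` — its 1 Hz thinning (one row per clip second);
      ``per_second`` — per-second variability Series (pixels);
      ``per_second_sqrt`` — its square-root transform;
      ``overall`` — overall variability scalar (pixels);
      ``overall_sqrt`` — its square root.
    """
    dev = deviation_series(coords, anchor)
    per_sec = per_second_variability(coords, fps=fps)
    overall = overall_variability(coords)
    return {
        "deviation": dev,
        "subsampled": subsample_1hz(dev, fps=fps, duration=duration,
                                    rule=subsample_rule),
        "per_second": per_sec,
        "per_second_sqrt": pd.Series(sqrt_transform(per_sec.to_numpy()),
                                     index=per_sec.index, name="sd_local_sqrt"),
        "overall": overall,
        "overall_sqrt": math.sqrt(overall) if not math.isnan(overall) else float("nan"),
    }
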