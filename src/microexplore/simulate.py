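"""Synthetic cohorts of bout-structured infant pulling trajectories.

Real 18-month-olds solving a rope-pulling task do not wander continuously:
they dwell on one candidate location or strategy for a stretch of time, then
hop to another.  The generator mimics that structure with a bout process:

* successive bout *targets* are drawn from a 2D normal centred on the
  imitative anchor, with a dispersion that grows across trials (firsthand
  failure pushes infants to test a wider variety of locations);
* the *dwell* in each bout is exponential, with a mean that grows within
  the trial (infants persist longer at each location as failure accrues);
* frames within a bout are the target plus small isotropic jitter;
* a small per-frame occlusion probability yields missing coordinates with
  low tracking likelihood, as when the infant's body hides the handle.

Participants who "engage in imitative pulling" (a configurable fraction of
the cohort) spend the first bout of their first trial exactly at the anchor;
those frames are what the cohort manifest flags as imitative segments.

Hand-coded performance measures (maximum pulling force, trying time,
negative-affect frames, help-seeking, recovery hints) are drawn through a
Gaussian copula tied to each participant's trial-averaged overall spatial
variability, so the pipeline's robust-correlation stage has known planted
targets to recover.  The default targets are the cohort-level estimates the
method was designed to detect.  Everything is reproducible bit-for-bit from
the seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as mio
from . import metrics as mmet
from .io import PoseTrack, make_track

#: Default planted correlation of each performance measure with
#: (trial-averaged) overall spatial variability.
DEFAULT_PERF_CORR = {
    "max_force": 0.22,
    "trying_time": -0.27,
    "negative_affect": 0.13,
    "help_seeking": 0.11,
    "hints_recovery": -0.37,
}

DEFAULT_ANCHOR = (458.29, 347.79)


@dataclasses.dataclass
class SimParams:
    """Study conditions for one synthetic cohort.

    Defaults are the conditions the analysis pipeline assumes: a 96-infant
    cohort split evenly over the three demonstration conditions, 30 fps
    video, trials of 20-120 s, bout dispersion growing by 20 px per trial
    and dwell starting at 2 s and lengthening as the trial progresses.
    """

    n_participants: int = 96
    conditions: tuple[str, ...] = mio.CONDITIONS
    fps: float = 30.0
    trial_length_scale: float = 18.0   # s; lengths are 20 + Exp(scale), <= 120
    anchor: tuple[float, float] = DEFAULT_ANCHOR
    sigma_explore_base: float = 150.0  # px, bout-target dispersion, trial 1
    sigma_explore_trial_slope: float = 20.0  # px per trial
    dwell_mean_base: float = 2.0       # s, mean bout dwell at trial start
    dwell_time_slope: float = 0.05     # s of extra mean dwell per elapsed s
    sigma_jitter: float = 10.0         # px, within-bout frame jitter
    occlusion_rate: float = 0.02       # probability per frame
    imitative_prob: float = 78.0 / 96.0
    perf_corr: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PERF_CORR))
    trial_share: float = 0.8           # participant-level copula variance share
    max_hints: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("sigma_explore_base", "sigma_explore_trial_slope",
                     "sigma_jitter", "occlusion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dwell_mean_base <= 0:
            raise ValueError("dwell_mean_base must be > 0")
        if not 0 <= self.imitative_prob <= 1:
            raise ValueError("imitative_prob must be in [0, 1]")
        if not 0 < self.trial_share <= 1:
            raise ValueError("trial_share must be in (0, 1]")
        for k, rho in self.perf_corr.items():
            if not abs(rho) < 1:
                raise ValueError(f"perf_corr[{k!r}] must satisfy |rho| < 1")
        # joint feasibility of the copula correlation matrix
        rhos = np.array(list(self.perf_corr.values()))
        k = rhos.size
        corr = np.eye(k + 1)
        corr[0, 1:] = corr[1:, 0] = rhos
        corr[1:, 1:] = np.outer(rhos, rhos) + np.diag(1 - rhos ** 2)
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError("perf_corr matrix is not positive definite") from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(d["conditions"])
        d["anchor"] = list(d["anchor"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        d["conditions"] = tuple(d.get("conditions", mio.CONDITIONS))
        d["anchor"] = tuple(d.get("anchor", DEFAULT_ANCHOR))
        return cls(**d)


def _trial_rng(params: SimParams, participant_index: int,
               trial_number: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([params.seed, participant_index, trial_number]))


def _cohort_rng(params: SimParams) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, 10 ** 6]))


def assign_conditions(params: SimParams) -> list[str]:
    """Round-robin assignment: equal cells over the condition set."""
    k = len(params.conditions)
    return [params.conditions[i % k] for i in range(params.n_participants)]


def draw_trial_length(params: SimParams,
                      rng: np.random.Generator) -> int:
    """Trial length in whole seconds: 20 + Exp(scale), capped at 120."""
    return int(round(min(20.0 + rng.exponential(params.trial_length_scale),
                         120.0)))


def generate_trial(params: SimParams, participant_index: int,
                   trial_number: int, imitative_first_bout: bool = False,
                   trial_length_s: float | None = None,
                   ) -> tuple[PoseTrack, int]:
    """Simulate one trial's handle track.

    Returns the track and the frame count of the first bout (the imitative
    segment length when ``imitative_first_bout`` is set, else 0).
    """
    params.validate()
    if trial_number not in (1, 2, 3):
        raise ValueError("trial_number must be 1-3")
    rng = _trial_rng(params, participant_index, trial_number)
    if trial_length_s is None:
        trial_length_s = draw_trial_length(params, rng)
    n_frames = int(round(trial_length_s * params.fps))
    sigma = (params.sigma_explore_base
             + params.sigma_explore_trial_slope * (trial_number - 1))
    anchor = np.asarray(params.anchor, dtype=float)

    xy = np.empty((n_frames, 2))
    t = 0
    first_bout_frames = 0
    bout = 0
    while t < n_frames:
        if bout == 0 and imitative_first_bout:
            target = anchor.copy()
        else:
            target = anchor + rng.normal(scale=sigma, size=2) if sigma > 0 \
                else anchor.copy()
        elapsed_s = t / params.fps
        dwell_mean = params.dwell_mean_base + params.dwell_time_slope * elapsed_s
        dwell_s = rng.exponential(dwell_mean)
        n_bout = max(1, int(round(dwell_s * params.fps)))
        n_bout = min(n_bout, n_frames - t)
        jitter = (rng.normal(scale=params.sigma_jitter, size=(n_bout, 2))
                  if params.sigma_jitter > 0 else 0.0)
        xy[t:t + n_bout] = target + jitter
        if bout == 0:
            first_bout_frames = n_bout
        t += n_bout
        bout += 1

    np.maximum(xy, 0.0, out=xy)  # image coordinates cannot go negative
    occluded = rng.random(n_frames) < params.occlusion_rate
    likelihood = np.where(occluded, rng.uniform(0.0, 0.5, n_frames),
                          rng.uniform(0.9, 1.0, n_frames))
    xy[occluded] = np.nan
    track = make_track(
        {"handle_base": np.column_stack([xy, likelihood])},
        fps=params.fps,
        participant_id=f"p{participant_index:03d}",
        trial_number=trial_number,
        scorer="synthetic")
    return track, (first_bout_frames if imitative_first_bout else 0)


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Empirical normal (van der Waerden) scores; rank-based, tie-averaged."""
    ranks = sps.rankdata(values)
    return sps.norm.ppf(ranks / (len(values) + 1.0))


def generate_performance(params: SimParams, avg_overall: pd.Series,
                         trial_lengths: pd.DataFrame) -> pd.DataFrame:
    """Draw performance measures tied to overall variability by a copula.

    Parameters
    ----------
    avg_overall
        Participant-indexed trial-averaged overall spatial variability
        (pixels), computed from the generated tracks.
    trial_lengths
        One row per participant x trial with columns ``participant_id``,
        ``trial_number``, ``trial_length``.

    Returns a per-trial table of the five measures.  Trial-level measures
    share ``trial_share`` of their copula variance at the participant level;
    recovery hints are a single participant-level count repeated across the
    participant's rows.
    """
    params.validate()
    rng = _cohort_rng(params)
    participants = list(avg_overall.index)
    n = len(participants)
    z_v = pd.Series(_normal_scores(avg_overall.to_numpy()), index=participants)

    rows = []
    z_meas = {}
    for name, rho in params.perf_corr.items():
        eps = rng.normal(size=n)
        z_meas[name] = rho * z_v.to_numpy() + np.sqrt(1 - rho ** 2) * eps
    hints_u = sps.norm.cdf(z_meas["hints_recovery"])
    hints = np.minimum(np.floor(sps.gamma.ppf(hints_u, a=2.0, scale=1.5)),
                       params.max_hints).astype(int)

    w = params.trial_share
    for i, pid in enumerate(participants):
        sub = trial_lengths[trial_lengths["participant_id"] == pid]
        for row in sub.itertuples(index=False):
            rec = {"participant_id": pid, "trial_number": row.trial_number}
            for name in ("max_force", "trying_time", "negative_affect",
                         "help_seeking"):
                z = (np.sqrt(w) * z_meas[name][i]
                     + np.sqrt(1 - w) * rng.normal())
                u = sps.norm.cdf(z)
                if name == "max_force":
                    rec[name] = float(sps.gamma.ppf(u, a=2.0, scale=1.2))
                elif name == "trying_time":
                    # bounded by the 20 s clip <= every trial length
                    rec[name] = float(20.0 * sps.beta.ppf(u, 2.0, 3.0))
                elif name == "negative_affect":
                    rec[name] = int(np.floor(sps.gamma.ppf(u, a=1.5, scale=20.0)))
                else:
                    rec[name] = int(np.floor(sps.gamma.ppf(u, a=1.2, scale=2.0)))
            rec["hints_recovery"] = int(hints[i])
            rows.append(rec)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class Cohort:
    """An in-memory synthetic cohort: tracks, metadata and manifest."""

    params: SimParams
    tracks: dict  # (participant_id, trial_number) -> PoseTrack
    meta: pd.DataFrame
    manifest: pd.DataFrame  # imitative segments


def generate_cohort(params: SimParams) -> Cohort:
    """Generate a full cohort: trajectories, metadata, imitative manifest."""
    params.validate()
    rng = _cohort_rng(params)
    conditions = assign_conditions(params)
    engages = rng.random(params.n_participants) < params.imitative_prob
    motor = rng.binomial(24, 0.75, size=params.n_participants)
    unproductive = rng.integers(0, 5, size=(params.n_participants, 3))

    tracks, man_rows, len_rows = {}, [], []
    for i in range(params.n_participants):
        pid = f"p{i:03d}"
        for trial in (1, 2, 3):
            imit = bool(engages[i]) and trial == 1
            track, seg_len = generate_trial(params, i, trial,
                                            imitative_first_bout=imit)
            tracks[(pid, trial)] = track
            len_rows.append({"participant_id": pid, "trial_number": trial,
                             "trial_length": int(round(track.duration_s))})
            if imit and seg_len > 0:
                man_rows.append({"participant_id": pid, "trial_number": trial,
                                 "start_frame": 0, "end_frame": seg_len})
    lengths = pd.DataFrame(len_rows)

    # trial-averaged overall variability of the standard 20 s clips drives
    # the performance-measure copula
    overall = {}
    for (pid, trial), track in tracks.items():
        coords = mio.select_point(mio.clip_trial(track, 20.0), "handle_base")
        overall.setdefault(pid, []).append(mmet.overall_variability(coords))
    avg_overall = pd.Series({pid: float(np.nanmean(v))
                             for pid, v in overall.items()}).sort_index()

    perf = generate_performance(params, avg_overall, lengths)
    meta = lengths.merge(perf, on=["participant_id", "trial_number"])
    meta["condition"] = [conditions[int(pid[1:])] for pid in meta["participant_id"]]
    meta["motor_score"] = [int(motor[int(pid[1:])]) for pid in meta["participant_id"]]
    meta["unproductive_intervals"] = [
        int(unproductive[int(pid[1:]), t - 1])
        for pid, t in zip(meta["participant_id"], meta["trial_number"])]
    meta = meta[mio.TRIAL_META_COLUMNS]
    from .baseline import MANIFEST_COLUMNS
    manifest = pd.DataFrame(man_rows, columns=MANIFEST_COLUMNS)
    return Cohort(params=params, tracks=tracks, meta=meta, manifest=manifest)


def write_cohort(params: SimParams, outdir: str | Path) -> Cohort:
    """Materialise a cohort on disk: pose CSVs, metadata, manifest, params.

    The parameter/seed record written alongside is sufficient to regenerate
    the file set bit-identically.
    """
    outdir = Path(outdir)
    (outdir / "poses").mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(params)
    for (pid, trial), track in cohort.tracks.items():
        mio.write_pose_csv(track, outdir / "poses" / f"{pid}_trial{trial}.csv")
    mio.write_trial_meta(cohort.meta, outdir / "trial_meta.csv")
    cohort.manifest.to_csv(outdir / "imitative_segments.csv", index=False)
    with open(outdir / "sim_params.json", "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
    return cohort


def read_cohort(indir: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    with open(indir / "sim_params.json") as fh:
        params = SimParams.from_dict(json.load(fh))
    meta = mio.read_trial_meta(indir / "trial_meta.csv")
    manifest = pd.read_csv(indir / "imitative_segments.csv")
    tracks = {}
    for row in meta.itertuples(index=False):
        path = indir / "poses" / f"{row.participant_id}_trial{row.trial_number}.csv"
        tracks[(row.participant_id, row.trial_number)] = mio.read_pose_csv(
            path, fps=params.fps, participant_id=row.participant_id,
            trial_number=row.trial_number)
    return Cohort(params=params, tracks=tracks, meta=meta, manifest=manifest)
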