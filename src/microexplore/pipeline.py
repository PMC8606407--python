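"""End-to-end orchestration: cohort -> metrics -> inference -> report bundle.

A run follows the analysis order of the underlying study design: imitative
similarity (location tests and mixed models), spatial variability at two
timescales (mixed models), individual-difference robust correlations, and
the recovery-expectation prediction, plus the construct-validity check
against human-coded unproductive movement.  Every effective setting is
echoed into a run manifest; re-running from the manifest alone reproduces
the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baseline as mb
from . import io as mio
from . import metrics as mmet
from . import simulate as msim
from . import stats as mst

log = logging.getLogger("microexplore")


@dataclasses.dataclass
class RunConfig:
    """Every knob of a pipeline run; defaults are the analysis conventions."""

    input_dir: str | None = None      # load a cohort; None -> simulate
    out_dir: str = "microexplore_run"
    seed: int = 0
    sim: dict = dataclasses.field(default_factory=dict)  # SimParams overrides
    clip_seconds: float = 20.0
    bodypart: str = "handle_base"
    likelihood_threshold: float | None = None  # None = no filtering
    subsample_rule: str = "last"
    outlier_rule: str = "zscore"
    outlier_k: float = 3.0
    beta: float = 0.2                 # percentage-bend fraction
    icc_model: str = "consistency"
    reference_condition: str = "Easy"
    make_plots: bool = True
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _load_or_simulate(config: RunConfig) -> msim.Cohort:
    if config.input_dir is not None:
        log.info("loading cohort from %s", config.input_dir)
        return msim.read_cohort(config.input_dir)
    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", config.seed)
    params = msim.SimParams.from_dict(sim_kwargs)
    log.info("simulating cohort: n=%d seed=%d", params.n_participants,
             params.seed)
    return msim.generate_cohort(params)


def compute_metric_tables(cohort: msim.Cohort, config: RunConfig,
                          anchor: mb.ImitativeAnchor):
    """Derive the three tidy metric tables for a cohort.

    Returns ``(subsampled, per_second, overall, attrition_log)``.  Trials
    shorter than the clip are excluded and logged rather than failing the
    run, mirroring the attrition a longer cut-off would cause.
    """
    sub_rows, sec_rows, ov_rows, attrition = [], [], [], []
    for (pid, trial), track in sorted(cohort.tracks.items()):
        if config.likelihood_threshold is not None:
            track = track.mask_low_likelihood(config.likelihood_threshold)
        try:
            clipped = mio.clip_trial(track, config.clip_seconds)
        except mio.InsufficientDataError as exc:
            attrition.append({"participant_id": pid, "trial_number": trial,
                              "reason": str(exc)})
            continue
        coords = mio.select_point(clipped, config.bodypart)
        tm = mmet.trial_metrics(coords, anchor, fps=track.fps,
                                duration=config.clip_seconds,
                                subsample_rule=config.subsample_rule)
        sub = tm["subsampled"].reset_index()
        sub.insert(0, "participant_id", pid)
        sub.insert(1, "trial_number", trial)
        sub_rows.append(sub)
        sec = pd.DataFrame({
            "sd_local": tm["per_second"],
            "sd_local_sqrt": tm["per_second_sqrt"],
        }).reset_index()
        sec.insert(0, "participant_id", pid)
        sec.insert(1, "trial_number", trial)
        sec["time_s"] = sec["second_index"].astype(float)
        sec_rows.append(sec)
        ov_rows.append({"participant_id": pid, "trial_number": trial,
                        "overall": tm["overall"],
                        "overall_sqrt": tm["overall_sqrt"]})
    meta = cohort.meta
    subsampled = pd.concat(sub_rows, ignore_index=True).merge(
        meta, on=["participant_id", "trial_number"])
    per_second = pd.concat(sec_rows, ignore_index=True).merge(
        meta, on=["participant_id", "trial_number"])
    overall = pd.DataFrame(ov_rows).merge(
        meta, on=["participant_id", "trial_number"])
    return subsampled, per_second, overall, pd.DataFrame(
        attrition, columns=["participant_id", "trial_number", "reason"])


def _excluded_devs(subsampled: pd.DataFrame, config: RunConfig):
    """Outlier-filter subsampled deviations within participant x axis."""
    kept = {"dev_x": [], "dev_y": []}
    logs = []
    for pid, grp in subsampled.groupby("participant_id"):
        for axis in ("dev_x", "dev_y"):
            vals, lg = mmet.exclude_outliers(grp[axis].to_numpy(),
                                             rule=config.outlier_rule,
                                             k=config.outlier_k)
            kept[axis].append(vals)
            lg.insert(0, "participant_id", pid)
            lg.insert(1, "axis", axis)
            logs.append(lg)
    return (np.concatenate(kept["dev_x"]), np.concatenate(kept["dev_y"]),
            pd.concat(logs, ignore_index=True) if logs else pd.DataFrame())


def participant_summary(overall: pd.DataFrame,
                        subsampled: pd.DataFrame) -> pd.DataFrame:
    """Trial-averaged, participant-level quantities for correlation analyses.

    Trying time and maximum force are square-root transformed before
    averaging (the convention for these right-skewed measures); overall
    variability is trial-averaged, then square-root transformed.
    """
    sim_avg = (subsampled.groupby("participant_id")["similarity"]
               .mean().rename("similarity_avg"))
    agg = overall.groupby("participant_id").agg(
        overall_avg=("overall", "mean"),
        trying_time=("trying_time", lambda v: np.sqrt(v).mean()),
        max_force=("max_force", lambda v: np.sqrt(v).mean()),
        negative_affect=("negative_affect", "mean"),
        help_seeking=("help_seeking", "mean"),
        hints_recovery=("hints_recovery", "first"),
    )
    agg["overall_sqrt_avg"] = np.sqrt(agg["overall_avg"])
    return agg.join(sim_avg)


def run_inference(subsampled: pd.DataFrame, per_second: pd.DataFrame,
                  overall: pd.DataFrame, config: RunConfig):
    """All inferential results of a run, as a list of StatResult."""
    results: list[mst.StatResult] = []

    # 1. imitative similarity: location tests against imitation (0)
    dev_x, dev_y, excl_log = _excluded_devs(subsampled, config)
    results.append(dataclasses.replace(
        mst.one_sample_t(dev_x), term="dev_x vs imitation"))
    results.append(dataclasses.replace(
        mst.one_sample_t(dev_y), term="dev_y vs imitation"))
    results.append(dataclasses.replace(
        mst.paired_t(subsampled["dev_x"], subsampled["dev_y"]),
        term="dev_x - dev_y"))

    # 2. mixed models over condition / trial / time
    full = ("condition", "trial_number", "time_s", "trial_number:time_s",
            "trial_length", "motor_score")
    for resp, table in (("similarity", subsampled),
                        ("diff_score", subsampled),
                        ("sd_local_sqrt", per_second)):
        spec = mst.LmmSpec(response=resp, fixed=full,
                           reference=config.reference_condition)
        results.extend(mst.fit_lmm(table, spec))
    spec = mst.LmmSpec(response="overall_sqrt",
                       fixed=("condition", "trial_number", "trial_length",
                              "motor_score"),
                       reference=config.reference_condition)
    results.extend(mst.fit_lmm(overall, spec))

    # 3. individual differences: robust correlations with both exploration
    #    metrics, then the recovery-expectation prediction
    summ = participant_summary(overall, subsampled)
    for measure in ("max_force", "trying_time", "negative_affect",
                    "help_seeking", "hints_recovery"):
        for metric in ("similarity_avg", "overall_sqrt_avg"):
            r = mst.percbend_corr(summ[measure], summ[metric],
                                  beta=config.beta)
            results.append(dataclasses.replace(
                r, term=f"{measure} vs {metric}"))
    return results, summ, excl_log


def validate_against_coding(overall: pd.DataFrame,
                            subsampled: pd.DataFrame) -> list[mst.StatResult]:
    """Construct validity: trial-level metrics vs unproductive-interval counts.

    If the trajectory metrics merely captured incidental movement or play,
    they would correlate with the human-coded count of 5 s intervals of
    unproductive movement (0-4 per trial); near-zero Pearson correlations
    support construct validity.
    """
    sim_trial = (subsampled.groupby(["participant_id", "trial_number"])
                 ["similarity"].mean().rename("similarity_trial"))
    tab = overall.set_index(["participant_id", "trial_number"]).join(sim_trial)
    out = []
    for col in ("similarity_trial", "overall"):
        r = mst.pearson_corr(tab[col], tab["unproductive_intervals"])
        out.append(dataclasses.replace(
            r, term=f"{col} vs unproductive_intervals"))
    return out


def _plots(subsampled, per_second, overall, summ, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(11, 8))
    for ax, (tab, col, title) in zip(axes.flat[:3], [
            (subsampled, "similarity", "Imitative similarity over time"),
            (subsampled, "diff_score", "Axis difference score over time"),
            (per_second, "sd_local_sqrt", "Per-second variability (sqrt)")]):
        for (cond, trial), grp in tab.groupby(["condition", "trial_number"]):
            curve = grp.groupby("second_index")[col].mean()
            ax.plot(curve.index, curve.values, alpha=0.7,
                    label=f"{cond} T{trial}")
        ax.set_xlabel("second of clip")
        ax.set_ylabel(col)
        ax.set_title(title)
    ax = axes.flat[3]
    for trial, grp in overall.groupby("trial_number"):
        ax.scatter([trial] * len(grp), grp["overall_sqrt"], s=6, alpha=0.4)
    ax.set_xlabel("trial")
    ax.set_ylabel("overall variability (sqrt)")
    ax.set_title("Overall variability by trial")
    axes.flat[0].legend(fontsize=6, ncol=3)
    fig.tight_layout()
    fig.savefig(outdir / "scores_over_time.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 5, figsize=(16, 3.2), sharey=True)
    for ax, measure in zip(axes, ("max_force", "trying_time",
                                  "negative_affect", "help_seeking",
                                  "hints_recovery")):
        ax.scatter(summ[measure], summ["overall_sqrt_avg"], s=10, alpha=0.6)
        ax.set_xlabel(measure)
    axes[0].set_ylabel("overall variability (sqrt, trial-avg)")
    fig.tight_layout()
    fig.savefig(outdir / "performance_scatter.png", dpi=120)
    plt.close(fig)


def run(config: RunConfig) -> dict:
    """Execute a full pipeline run and write the report bundle.

    Returns a dict with the anchor, metric tables, results table and paths.
    Identical config + seed produce identical numeric outputs.
    """
    logging.basicConfig(
        level=getattr(logging, config.verbosity.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "simulate/load"
    try:
        cohort = _load_or_simulate(config)
        stage = "anchor"
        coords_by = {key: mio.select_point(tr, config.bodypart)
                     for key, tr in cohort.tracks.items()}
        segments = mb.segments_from_manifest(cohort.manifest, coords_by)
        anchor = mb.estimate_anchor(segments)
        log.info("anchor (%.2f, %.2f) px from %d frames / %d participants",
                 anchor.x_anchor, anchor.y_anchor, anchor.n_frames,
                 anchor.n_contributors)
        stage = "metrics"
        subsampled, per_second, overall, attrition = compute_metric_tables(
            cohort, config, anchor)
        log.info("metrics: %d subsampled rows, %d per-second rows, "
                 "%d trials, %d trials excluded by the clip rule",
                 len(subsampled), len(per_second), len(overall),
                 len(attrition))
        stage = "stats"
        results, summ, excl_log = run_inference(subsampled, per_second,
                                                overall, config)
        results.extend(validate_against_coding(overall, subsampled))
        stage = "report"
        subsampled.to_csv(outdir / "metrics_subsampled.csv", index=False)
        per_second.to_csv(outdir / "metrics_per_second.csv", index=False)
        overall.to_csv(outdir / "metrics_overall.csv", index=False)
        summ.to_csv(outdir / "participant_summary.csv")
        attrition.to_csv(outdir / "attrition_log.csv", index=False)
        excl_log.to_csv(outdir / "exclusion_log.csv", index=False)
        stats_tab = mst.results_table(results)
        stats_tab.to_csv(outdir / "stats_results.csv", index=False)
        with open(outdir / "anchor.json", "w") as fh:
            json.dump(dataclasses.asdict(anchor), fh, indent=2)
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": _versions(),
        }
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        if config.make_plots:
            _plots(subsampled, per_second, overall, summ, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {"anchor": anchor, "subsampled": subsampled,
            "per_second": per_second, "overall": overall,
            "summary": summ, "results": stats_tab, "out_dir": str(outdir)}


def run_from_manifest(path: str | Path) -> dict:
    """Reproduce a run from its manifest alone."""
    with open(path) as fh:
        manifest = json.load(fh)
    return run(RunConfig.from_dict(manifest["config"]))


def planted_recovery_study(n_seeds: int = 20, base_seed: int = 1,
                           sim_overrides: dict | None = None) -> dict:
    """Simulation study: can the pipeline recover what the generator planted?

    For each seed, a default-conditioned cohort is generated and pushed
    through anchor estimation, the variability metrics, the trial-effect
    mixed model on square-root overall variability, and the robust
    correlations of each performance measure with trial-averaged overall
    variability.  Returns per-seed anchor errors, the fraction of seeds with
    a positive and significant trial coefficient, and the mean recovered
    correlation per planted target.
    """
    anchor_err, trial_pos_sig = [], []
    recovered: dict[str, list[float]] = {}
    targets = None
    for k in range(n_seeds):
        params = msim.SimParams.from_dict(
            {**(sim_overrides or {}), "seed": base_seed + k})
        targets = params.perf_corr
        cohort = msim.generate_cohort(params)
        coords_by = {key: mio.select_point(tr, "handle_base")
                     for key, tr in cohort.tracks.items()}
        segs = mb.segments_from_manifest(cohort.manifest, coords_by)
        est = mb.estimate_anchor(segs)
        anchor_err.append(max(abs(est.x_anchor - params.anchor[0]),
                              abs(est.y_anchor - params.anchor[1])))
        rows = []
        for (pid, trial), coords in coords_by.items():
            c20 = coords.iloc[:int(round(20 * params.fps))]
            ov = mmet.overall_variability(c20)
            rows.append({"participant_id": pid, "trial_number": trial,
                         "overall": ov, "overall_sqrt": np.sqrt(ov)})
        ovtab = pd.DataFrame(rows).merge(
            cohort.meta, on=["participant_id", "trial_number"])
        res = mst.fit_lmm(ovtab, mst.LmmSpec(
            response="overall_sqrt",
            fixed=("condition", "trial_number", "trial_length",
                   "motor_score")))
        coef = next(r for r in res if r.term == "trial_number")
        trial_pos_sig.append(coef.estimate > 0 and coef.p_value < 0.05)
        summ = ovtab.groupby("participant_id").agg(
            overall_avg=("overall", "mean"),
            max_force=("max_force", "mean"),
            trying_time=("trying_time", "mean"),
            negative_affect=("negative_affect", "mean"),
            help_seeking=("help_seeking", "mean"),
            hints_recovery=("hints_recovery", "first"))
        sqrt_ov = np.sqrt(summ["overall_avg"])
        for measure in targets:
            r = mst.percbend_corr(summ[measure], sqrt_ov)
            recovered.setdefault(measure, []).append(r.estimate)
    return {
        "n_seeds": n_seeds,
        "targets": dict(targets),
        "anchor_max_err_px": float(np.max(anchor_err)),
        "anchor_mean_err_px": float(np.mean(anchor_err)),
        "trial_effect_positive_significant_rate": float(np.mean(trial_pos_sig)),
        "mean_recovered_corr": {m: float(np.mean(v))
                                for m, v in recovered.items()},
    }


def _versions() -> dict:
    import matplotlib
    import scipy
    import statsmodels

    from . import __version__

    return {"microexplore": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "matplotlib": matplotlib.__version__}
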