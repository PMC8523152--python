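"""End-to-end workflow: simulate -> segment -> measure -> summarize -> infer.

Every stage is a pure function from tabular inputs to tabular outputs, so
the pipeline is re-entrant from any intermediate TSV, and a fixed config
plus seed reproduces byte-identical outputs.  All analysis constants
default to the published protocol values (8 Hz low-pass, 3.5 cm/s onset,
50% of peak for termination, 2 cm / 1 cm / 10 cm/s accidental-initiation
rules, 10 s / 20 cm no-vision validity rules, 1.5 x IQR outlier fences,
Cauchy prior width 1.39).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import cohort_usage, endpoint_metrics, kinematics, stats_inference
from . import synthetic_data, traj_io

__all__ = ["PipelineConfig", "run_pipeline", "run_cohort_analyses"]

log = logging.getLogger(__name__)




@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the published protocol constants."""

    out_dir: str = "reachkin_out"
    seed: int = 0
    # simulation (used when no input trajectory file is given)
    groups: tuple = ("control", "acquired", "congenital")
    n_per_group: int = 8
    trials_per_arm: int = 60
    task: str = "main"
    trajectories: str | None = None
    # kinematics
    filter_cutoff_hz: float = 8.0
    butter_order: int = 2
    filter_target: str = "speed"
    onset_threshold_cm_s: float = 3.5
    termination_fraction: float = 0.5
    unseen_hold_s: float = 1.0
    main_window_s: float = 1.0
    # exclusions
    near_home_cm: float = 2.0
    shallow_y_cm: float = 1.0
    end_speed_cm_s: float = 10.0
    loc2d_max_time_s: float = 10.0
    loc2d_max_error_cm: float = 20.0
    # summaries and inference
    transform: str = "log"
    corrective_anchor: str = "home"
    outlier_rule: bool = True
    iqr_multiplier: float = 1.5
    cauchy_scale: float = 1.39

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["groups"] = list(d["groups"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _seg_kwargs(cfg: PipelineConfig) -> dict:
    return dict(
        cutoff=cfg.filter_cutoff_hz, order=cfg.butter_order,
        filter_target=cfg.filter_target,
        onset_threshold=cfg.onset_threshold_cm_s,
        fraction=cfg.termination_fraction, hold=cfg.unseen_hold_s,
        main_window=cfg.main_window_s,
        near_home=cfg.near_home_cm, shallow_y=cfg.shallow_y_cm,
        end_speed=cfg.end_speed_cm_s, max_time=cfg.loc2d_max_time_s,
        max_error=cfg.loc2d_max_error_cm)


_KEYS = ["participant", "group", "arm", "task", "trial"]


def stage_simulate(cfg: PipelineConfig):
    """Generate the trial set for every configured group preset."""
    trials, truth = [], []
    for g_idx, g in enumerate(cfg.groups):
        tr, tru = synthetic_data.simulate_group(
            g, n_participants=cfg.n_per_group,
            trials_per_arm=cfg.trials_per_arm,
            seed=cfg.seed + 1000 * g_idx, task=cfg.task)
        trials.extend(tr)
        truth.append(tru)
    return trials, pd.concat(truth, ignore_index=True)


def stage_segment(trials, cfg: PipelineConfig) -> pd.DataFrame:
    """Segment every trial; one row per trial with landmarks and flags."""
    kw = _seg_kwargs(cfg)
    rows = []
    for tr in trials:
        seg = kinematics.segment_trial(tr, **kw)
        rows.append({
            "participant": tr.participant_id, "group": tr.group,
            "arm": tr.arm, "task": tr.task, "trial": tr.trial_index,
            "onset_i": seg.onset_index, "peak_i": seg.peak_index,
            "term_i": seg.termination_index,
            "trial_end_i": seg.trial_end_index,
            "endpoint_x": None if seg.endpoint is None else seg.endpoint[0],
            "endpoint_y": None if seg.endpoint is None else seg.endpoint[1],
            "peak_speed": seg.peak_speed,
            "movement_time": seg.movement_time,
            "excluded": seg.excluded, "reason": seg.exclusion_reason,
        })
    return pd.DataFrame(rows)


def stage_measure(trials, segments: pd.DataFrame,
                  cfg: PipelineConfig) -> pd.DataFrame:
    """Per-trial error measures for every non-excluded reach."""
    seg_ix = segments.set_index(_KEYS)
    rows = []
    for tr in trials:
        key = (tr.participant_id, tr.group, tr.arm, tr.task, tr.trial_index)
        s = seg_ix.loc[key]
        if bool(s["excluded"]):
            continue
        seg = kinematics.SegmentedReach(
            onset_index=int(s["onset_i"]), peak_index=int(s["peak_i"]),
            termination_index=int(s["term_i"]),
            endpoint=np.array([s["endpoint_x"], s["endpoint_y"]], float),
            peak_speed=float(s["peak_speed"]),
            movement_time=float(s["movement_time"]))
        m = endpoint_metrics.trial_measures(
            tr, seg, corrective_anchor=cfg.corrective_anchor)
        rows.append(dict(zip(_KEYS, key)) | {
            "abs_error": m.absolute_error,
            "err_x": m.error_vector[0], "err_y": m.error_vector[1],
            "init_dir_err": m.initial_directional_error,
            "corrective_angle": m.corrective_angle,
            "movement_time": m.movement_time,
        })
    return pd.DataFrame(rows)


def stage_summarize(measures: pd.DataFrame, segments: pd.DataFrame,
                    cfg: PipelineConfig) -> pd.DataFrame:
    """Per-participant x arm summaries with overlay decomposition.

    When the outlier rule is on, Tukey fences on the transformed error
    are applied per arm, pooled over groups, and flagged participants are
    marked (not dropped from the table).
    """
    rows = []
    n_excl = segments.groupby(["participant", "arm"])["excluded"].sum()
    for (pid, grp, arm), g in measures.groupby(
            ["participant", "group", "arm"], sort=False):
        trs = [endpoint_metrics.TrialMeasures(
            absolute_error=r.abs_error,
            error_vector=np.array([r.err_x, r.err_y]),
            initial_directional_error=r.init_dir_err,
            corrective_angle=r.corrective_angle,
            movement_time=r.movement_time) for r in g.itertuples()]
        summ = endpoint_metrics.participant_summary(trs, transform=cfg.transform)
        bn = summ.bias_noise
        rows.append({
            "participant": pid, "group": grp, "arm": arm,
            "n_trials": summ.n_trials,
            "n_excluded": int(n_excl.get((pid, arm), 0)),
            "abs_error_mean_log": summ.mean_abs_error,
            "bias_mag": bn.bias_magnitude, "bias_angle_deg": bn.bias_angle,
            "noise_sd": bn.noise_sd,
            "init_dir_err_mean": summ.mean_initial_directional_error,
            "corrective_angle_mean": summ.mean_corrective_angle,
        })
    out = pd.DataFrame(rows)
    out["outlier"] = False
    if cfg.outlier_rule and len(out):
        for arm, g in out.groupby("arm"):
            if len(g) < 4:
                continue
            flagged = endpoint_metrics.flag_outliers(
                dict(zip(g["participant"], g["abs_error_mean_log"])),
                k=cfg.iqr_multiplier)
            out.loc[out["arm"].eq(arm)
                    & out["participant"].isin(flagged), "outlier"] = True
    return out


_ANCOVA_MEASURES = ("abs_error_mean_log", "noise_sd", "bias_mag",
                    "init_dir_err_mean", "corrective_angle_mean")


def stage_stats(summary: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Group inference: ANCOVAs with the intact arm as covariate, plus a
    Watson-Williams test on artificial-arm bias angles."""
    art = summary[summary["arm"].eq("artificial_nondominant")
                  & ~summary["outlier"]]
    intact = summary[summary["arm"].eq("intact_dominant")]
    wide = art.merge(intact, on=["participant", "group"],
                     suffixes=("_art", "_int"))
    rows = []
    for meas in _ANCOVA_MEASURES:
        sub = wide.dropna(subset=[f"{meas}_art", f"{meas}_int"])
        if sub["group"].nunique() < 2 or sub.groupby("group").size().min() < 3:
            continue
        res = stats_inference.ancova(sub[f"{meas}_art"], sub[f"{meas}_int"],
                                     sub["group"])
        rows.append({"test": f"ancova_group:{meas}", "statistic": res.F,
                     "df": f"{res.df_effect},{res.df_error}", "p": res.p,
                     "effect_size": res.partial_eta_sq, "bf": None})
        for ph in res.posthoc:
            rows.append({"test": f"tukey:{meas}:{ph.pair[0]}-{ph.pair[1]}",
                         "statistic": ph.t, "df": res.df_error,
                         "p": ph.p_tukey, "effect_size": ph.cohens_d,
                         "bf": None})
    groups = [g["bias_angle_deg"].to_numpy()
              for _, g in art.groupby("group") if len(g) >= 2]
    if len(groups) >= 2:
        ww = stats_inference.watson_williams(groups)
        rows.append({"test": "watson_williams:bias_angle",
                     "statistic": ww.F, "df": f"{ww.df1},{ww.df2}",
                     "p": ww.p, "effect_size": None, "bf": None})
    return pd.DataFrame(rows, columns=["test", "statistic", "df", "p",
                                       "effect_size", "bf"])


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False,
                 float_format=traj_io._shortest)


def run_pipeline(cfg: PipelineConfig, stages=("simulate", "segment",
                                              "measure", "summarize",
                                              "stats")) -> dict:
    """Run the workflow and write one TSV per stage plus report.txt.

    Returns the stage outputs as a dict of DataFrames (plus the trial
    list under ``"trials"``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timings = []

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        try:
            value = fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        timings.append((name, dt))
        log.info("stage %s finished in %.2f s", name, dt)
        return value

    if "simulate" in stages and cfg.trajectories is None:
        trials, truth = timed("simulate", stage_simulate, cfg)
        traj_io.write_trajectories(trials, out / "trajectories.csv")
        _write(truth, out / "ground_truth.tsv")
        results["truth"] = truth
    else:
        src = cfg.trajectories or out / "trajectories.csv"
        trials = timed("load", traj_io.read_trajectories, src)
    results["trials"] = trials

    if "segment" in stages:
        segments = timed("segment", stage_segment, trials, cfg)
        _write(segments, out / "segments.tsv")
        results["segments"] = segments
    else:
        segments = pd.read_csv(out / "segments.tsv", sep="\t",
                               float_precision="round_trip")

    if "measure" in stages:
        measures = timed("measure", stage_measure, trials, segments, cfg)
        _write(measures, out / "trial_measures.tsv")
        results["measures"] = measures
    else:
        measures = pd.read_csv(out / "trial_measures.tsv", sep="\t",
                               float_precision="round_trip")

    if "summarize" in stages:
        summary = timed("summarize", stage_summarize, measures, segments, cfg)
        _write(summary, out / "participant_summary.tsv")
        results["summary"] = summary
    else:
        summary = pd.read_csv(out / "participant_summary.tsv", sep="\t",
                              float_precision="round_trip")

    if "stats" in stages:
        stats = timed("stats", stage_stats, summary, cfg)
        _write(stats, out / "stats.tsv")
        results["stats"] = stats

    lines = [
        f"reachkin {_version}",
        f"seed: {cfg.seed}",
        "config:",
    ]
    for f in dataclasses.fields(cfg):
        lines.append(f"  {f.name}: {getattr(cfg, f.name)}")
    if "segments" in results:
        tally = results["segments"].groupby("reason").size()
        lines.append("exclusion tally:")
        for reason, count in tally.items():
            lines.append(f"  {reason}: {count}")
    lines.append("stage timings (s):")
    for name, dt in timings:
        lines.append(f"  {name}: {dt:.2f}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    results["report"] = "\n".join(lines)
    return results


def run_cohort_analyses(records=None, cohort_path=None,
                        out_dir=None) -> dict:
    """Cohort-table analyses: inclusion counts, usage-score
    recomputation diagnostics, history derivations and the between-group
    tests on artificial-arm experience and usage.

    Returns a dict of derived quantities; writes ``cohort_history.tsv``
    and ``cohort_report.txt`` when ``out_dir`` is given.
    """
    if records is None:
        records = (traj_io.read_cohort(cohort_path) if cohort_path
                   else traj_io.load_packaged_cohort())
    included = cohort_usage.apply_inclusion(records)
    counts = {g: len(v) for g, v in included.items()}
    result: dict = {"included_counts": counts,
                    "total_counts": {}}
    for r in records:
        result["total_counts"][r.group] = \
            result["total_counts"].get(r.group, 0) + 1

    hist = cohort_usage.history_frame(records)
    result["history"] = hist

    users = hist[hist["included"]]
    if len(users):
        printed = {r.participant_id: r.usage_score for r in records
                   if r.usage_score is not None}
        both = [(row.usage_score_recomputed, printed[row.participant])
                for row in hist.itertuples()
                if row.participant in printed
                and row.usage_score_recomputed is not None]
        if len(both) >= 3:
            rec, pr = zip(*both)
            r, p = stats_inference.pearson(rec, pr)
            result["usage_recomputation_r"] = r
        exp_a = users.loc[users["group"].eq("acquired"), "experience_years"]
        exp_c = users.loc[users["group"].eq("congenital"), "experience_years"]
        if len(exp_a) >= 2 and len(exp_c) >= 2:
            t, df, p = stats_inference.pooled_t(exp_a, exp_c)
            result["experience_t"] = {"t": t, "df": df, "p": p,
                                      "mean_acquired": float(exp_a.mean()),
                                      "mean_congenital": float(exp_c.mean())}
            use_a = [r.usage_score for r in included.get("acquired", [])
                     if r.usage_score is not None]
            use_c = [r.usage_score for r in included.get("congenital", [])
                     if r.usage_score is not None]
            if len(use_a) >= 2 and len(use_c) >= 2:
                t, df, p = stats_inference.pooled_t(use_a, use_c)
                result["usage_t"] = {"t": t, "df": df, "p": p}

    lines = [f"reachkin {_version} cohort report",
             f"rows: {len(records)}",
             f"included counts: {counts}"]
    if "usage_recomputation_r" in result:
        lines.append("usage-score recomputation r = "
                     f"{result['usage_recomputation_r']:.4f}")
    if "experience_t" in result:
        e = result["experience_t"]
        lines.append(
            "experience years (acquired vs congenital): "
            f"t({e['df']}) = {e['t']:.3f}, p = {e['p']:.2e}; "
            f"means {e['mean_acquired']:.2f} vs {e['mean_congenital']:.2f}")
    if "usage_t" in result:
        u = result["usage_t"]
        lines.append(f"usage score: t({u['df']}) = {u['t']:.3f}, "
                     f"p = {u['p']:.3f}")
    report = "\n".join(lines)
    result["report"] = report
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write(hist, out / "cohort_history.tsv")
        (out / "cohort_report.txt").write_text(report + "\n")
    return result
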