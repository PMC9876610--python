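"""Stage orchestration: simulate -> preprocess -> metrics -> analyze.

Each stage reads and writes plain-text artifacts in the run directory so any
stage can be re-run or swapped for real exported tracker data with the same
column layout. ``analyze_all`` bundles the five study analyses:

1. LMM on overall proportional eye-looking time (trial level);
2. LMM on the proportion of first fixations on the eyes
   (participant x emotion level);
3. LMM on log first-fixation duration, eyes-first trials only;
4. LMM on log latency to the eyes, eyes-first trials only;
5. cluster-based permutation tests of the eye-looking time course between
   high/low AQ groups and high/low SPIN groups.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as mt
from .config import PipelineConfig
from .inference import ClusterPermutationTest, EyeLMM, EyeLMMResults, LMMSpec
from .preprocess import preprocess_dataset
from .simulate import (EMOTIONS, SimulationParams, TrialSpec, gen_cohort,
                       gen_dataset, load_dataset, simulate_aoi_sequence,
                       truth_to_fixations)


def simulate_design_level(params: SimulationParams,
                          n_trials: int = 80,
                          epoch_step_ms: float = 50.0,
                          epoch_window_ms: float = 250.0,
                          seed: int | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and compute metrics from the true fixation sequences.

    Skips 300 Hz sample rendering and fixation detection: the generator's
    ground-truth AOI intervals feed the metric layer directly. This isolates
    the metric and inference stages from detection noise and makes large
    simulation studies (calibration, power, parameter recovery) cheap.

    Returns ``(traits, trials, curves)``: standardized participant traits,
    a per-trial metrics table with design labels, and participant-mean
    epoch curves (participants x epochs).
    """
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    cohort = gen_cohort(params.n_participants, params,
                        rng=np.random.default_rng(root.spawn(1)[0]))
    part = pd.DataFrame([dataclasses.asdict(p) for p in cohort]).rename(
        columns={"id": "participant_id"})
    traits = mt.standardize_and_group(part)

    rows = []
    curve_acc: dict[str, list[pd.DataFrame]] = {}
    for p, pseq in zip(cohort, root.spawn(len(cohort) + 1)[1:]):
        prng = np.random.default_rng(pseq)
        u_dwell = params.participant_sd_log_dwell * prng.standard_normal()
        u_lat = params.participant_sd_log_latency * prng.standard_normal()
        for k in range(n_trials):
            spec = TrialSpec(
                participant_id=p.id, block=(k // 20) % 4 + 1,
                trial_index=k % 20 + 1, emotion=EMOTIONS[k % 5],
                fixation_side="left" if prng.random() < 0.5 else "right",
                duration_ms=params.duration_ms,
                sample_rate=params.sample_rate)
            intervals = simulate_aoi_sequence(spec, p, params, prng,
                                              u_dwell=u_dwell,
                                              u_latency=u_lat)
            fixes = truth_to_fixations(intervals)
            m = mt.trial_gaze_metrics(fixes)
            rows.append({
                "participant_id": p.id, "block": spec.block,
                "trial": spec.trial_index, "emotion": spec.emotion,
                "prop_eyes_overall": m.prop_eyes_overall,
                "first_face_fix_on_eyes": m.first_face_fix_on_eyes,
                "first_fix_duration": m.first_fix_duration,
                "latency_to_eyes": m.latency_to_eyes,
                "log_duration": m.log_duration,
                "log_latency": m.log_latency,
            })
            curve = mt.epoch_timecourse(fixes, params.duration_ms,
                                        epoch_window_ms, epoch_step_ms)
            curve_acc.setdefault(p.id, []).append(curve)
    trials = pd.DataFrame(rows).merge(
        traits[["participant_id", "sex", "z_aq4", "z_spin", "aq_group",
                "spin_group"]], on="participant_id")
    curves = pd.DataFrame({
        pid: pd.concat(frames).groupby("t_ms")["prop_eyes"].mean()
        for pid, frames in curve_acc.items()
    }).T.sort_index()
    curves.index.name = "participant_id"
    return traits, trials, curves


def stage_simulate(cfg: PipelineConfig, out_dir: str | Path,
                   render_gaze: bool = True) -> None:
    gen_dataset(cfg.simulation, out_dir=out_dir, render_gaze=render_gaze)


def stage_preprocess(cfg: PipelineConfig, run_dir: str | Path) -> None:
    run = Path(run_dir)
    ds = load_dataset(run)
    if ds.gaze is None:
        raise FileNotFoundError(f"no gaze.tsv in {run}; run the simulate "
                                "stage first or point at exported data")
    fixation_table, validity_table = preprocess_dataset(
        ds.gaze, ds.manifest, params=cfg.preprocess,
        duration_ms=cfg.simulation.duration_ms)
    fixation_table.to_csv(run / "fixations.csv", index=False)
    validity_table.to_csv(run / "validity.csv", index=False)


def stage_metrics(cfg: PipelineConfig, run_dir: str | Path) -> None:
    run = Path(run_dir)
    for name in ("fixations.csv", "validity.csv"):
        if not (run / name).exists():
            raise FileNotFoundError(f"missing {name} in {run}; run the "
                                    "preprocess stage first")
    fixation_table = pd.read_csv(run / "fixations.csv")
    validity_table = pd.read_csv(run / "validity.csv")
    trial_metrics, epoch_long = mt.compute_trial_metrics_table(
        fixation_table, validity_table,
        duration_ms=cfg.simulation.duration_ms,
        window_ms=cfg.metrics.window_ms, step_ms=cfg.metrics.step_ms)
    trial_metrics.to_csv(run / "trial_metrics.csv", index=False)
    epoch_long.to_csv(run / "epoch_curves.csv", index=False)

    participants = pd.read_csv(run / "participants.csv")
    analysed = participants[participants["participant_id"].isin(
        trial_metrics["participant_id"].unique())]
    traits = mt.standardize_and_group(analysed, cfg.metrics.aq_cutoff,
                                      cfg.metrics.spin_cutoff)
    traits.to_csv(run / "trait_scores.csv", index=False)


def _lmm_to_dict(res: EyeLMMResults, levels) -> dict:
    slopes = res.simple_slopes(levels)
    return {
        "formula": res.model.spec.formula,
        "tau2": res.tau2,
        "sigma2": res.sigma2,
        "converged": res.converged,
        "n_obs": int(res._reml.n),
        "anova": res.anova().reset_index().to_dict(orient="records"),
        "simple_slopes": [dataclasses.asdict(s) for s in slopes],
        "slope_differences": res.slope_difference_tests(levels)
        .to_dict(orient="records"),
    }


def _cluster_to_dict(result) -> dict:
    return {
        "n_perm": result.n_perm,
        "exact": result.exact,
        "cluster_alpha": result.cluster_alpha,
        "epoch_times": (None if result.epoch_times is None
                        else [float(v) for v in result.epoch_times]),
        "t_trace": [None if not np.isfinite(v) else float(v)
                    for v in result.t_obs],
        "clusters": [{"start": c.start, "end": c.end, "mass": c.mass,
                      "p": c.p,
                      "start_ms": (None if result.epoch_times is None
                                   else float(result.epoch_times[c.start])),
                      "end_ms": (None if result.epoch_times is None
                                 else float(result.epoch_times[c.end]))}
                     for c in result.clusters],
    }


def analyze_all(participants: pd.DataFrame, manifest: pd.DataFrame,
                trial_metrics: pd.DataFrame, epoch_long: pd.DataFrame,
                validity: pd.DataFrame, cfg: PipelineConfig | None = None,
                ) -> dict:
    """Run the five study analyses and return a JSON-ready results bundle."""
    if cfg is None:
        cfg = PipelineConfig()
    inf = cfg.inference
    levels = tuple(inf.aq_levels)

    analysed_ids = trial_metrics["participant_id"].unique()
    traits = mt.standardize_and_group(
        participants[participants["participant_id"].isin(analysed_ids)],
        cfg.metrics.aq_cutoff, cfg.metrics.spin_cutoff)
    tcols = ["participant_id", "sex", "z_aq4", "z_spin", "aq_group",
             "spin_group"]
    trials = trial_metrics.merge(
        manifest[["participant_id", "block", "trial", "emotion"]],
        on=["participant_id", "block", "trial"], how="left").merge(
        traits[tcols], on="participant_id", how="left")

    bundle: dict = {"config_digest": cfg.digest(), "seed": cfg.seed}
    bundle["exclusions"] = mt.exclusion_summary(validity)

    def fit(data: pd.DataFrame, response: str) -> dict:
        spec = LMMSpec(response=response, df_method=inf.df_method)
        return _lmm_to_dict(EyeLMM(data, spec).fit(), levels)

    bundle["overall_prop_eyes"] = fit(trials, "prop_eyes_overall")

    # participant x emotion proportion of eyes-first trials among valid
    # correct trials (the trial flag may be None/NaN when a valid trial had
    # no on-face fixation; those count in the denominator)
    cell = (trials.assign(
        eyes_first=lambda d: d["first_face_fix_on_eyes"].fillna(False)
        .astype(bool).astype(float))
        .groupby(["participant_id", "emotion"], as_index=False)
        .agg(first_fix_prop=("eyes_first", "mean")))
    cell = cell.merge(traits[tcols], on="participant_id", how="left")
    bundle["first_fix_proportion"] = fit(cell, "first_fix_prop")

    eyes_first = trials[trials["first_face_fix_on_eyes"] == True]  # noqa: E712
    bundle["log_first_fix_duration"] = fit(eyes_first, "log_duration")
    bundle["log_latency_to_eyes"] = fit(eyes_first, "log_latency")

    curves = mt.participant_epoch_curves(epoch_long)
    traits_ix = traits.set_index("participant_id").loc[curves.index]
    rng = np.random.default_rng(cfg.seed)
    bundle["cluster_tests"] = {}
    for col, key in (("aq_group", "aq_groups"), ("spin_group", "spin_groups")):
        labels = traits_ix[col].to_numpy()
        test = ClusterPermutationTest(curves, labels)
        res = test.fit(n_perm=inf.n_perm, cluster_alpha=inf.cluster_alpha,
                       seed=int(rng.integers(2 ** 31)))
        bundle["cluster_tests"][key] = _cluster_to_dict(res)
        bundle["cluster_tests"][key]["groups"] = [str(g) for g
                                                  in test.group_labels]
    return bundle


def stage_analyze(cfg: PipelineConfig, run_dir: str | Path) -> dict:
    run = Path(run_dir)
    needed = ["participants.csv", "manifest.csv", "trial_metrics.csv",
              "epoch_curves.csv", "validity.csv"]
    for name in needed:
        if not (run / name).exists():
            raise FileNotFoundError(f"missing {name} in {run}; run earlier "
                                    "stages first")
    bundle = analyze_all(
        participants=pd.read_csv(run / "participants.csv"),
        manifest=pd.read_csv(run / "manifest.csv"),
        trial_metrics=pd.read_csv(run / "trial_metrics.csv"),
        epoch_long=pd.read_csv(run / "epoch_curves.csv"),
        validity=pd.read_csv(run / "validity.csv"),
        cfg=cfg)
    with open(run / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=1)
    return bundle


def write_manifest(cfg: PipelineConfig, run_dir: str | Path,
                   stages: list[str]) -> None:
    import platform

    from . import __version__

    run = Path(run_dir)
    run.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "stages": stages,
        "traitgaze_version": __version__,
        "python": platform.python_version(),
    }
    with open(run / "run_manifest.json", "w") as fh:
        json.dump(meta, fh, indent=1)
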