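"""Simulation studies validating the pipeline against known ground truth.

These functions implement the package's standing validation protocol:

* null calibration — with every trait effect switched off, the trait
  interaction's Type III test and the cluster permutation test must reject
  at their nominal 5% level;
* direction recovery — generators with a known effect (a SPIN slope on log
  first-fixation duration present only at high autistic traits; a late-stage
  eye-looking decrement in the high-AQ group) must reproduce the qualitative
  result pattern in most replicates;
* round-trip fidelity — preprocessing noise-free rendered gaze must recover
  the generator's true fixation sequence.

Replicate counts and cohort sizes default to reduced scales chosen so the
full protocol runs in minutes on one core; all are parameters.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .inference import ClusterPermutationTest, EyeLMM, LMMSpec
from .pipeline import simulate_design_level
from .preprocess import PreprocessParams, preprocess_dataset
from .simulate import SimulationParams, gen_dataset


def null_params(n_participants: int, seed: int = 0) -> SimulationParams:
    """Generator settings with every trait effect switched off."""
    return SimulationParams(
        n_participants=n_participants, seed=seed,
        latency_slope_aq=0.0, latency_slope_spin=0.0,
        latency_slope_spin_by_aq=0.0,
        first_eye_slope_aq=0.0, first_eye_slope_spin=0.0,
        first_eye_slope_spin_by_aq=0.0,
        eye_dwell_slope_spin=0.0, eye_dwell_slope_spin_by_aq=0.0,
        avoidance_effect=0.0)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def null_calibration(n_reps: int = 500, n_participants: int = 20,
                     n_trials: int = 20, alpha: float = 0.05,
                     n_perm: int = 199, seed: int = 0) -> dict:
    """Type I error of the interaction F test and the cluster test.

    Each replicate simulates a fresh cohort with zero trait effects, fits
    the overall eye-looking LMM and tests the z-AQ x z-SPIN term, and runs
    the AQ-group cluster permutation test on 250 ms epochs. Replicates whose
    cohort leaves a trait group with fewer than two members are redrawn
    (group membership is independent of gaze under the null). Returns the
    two empirical rejection rates.
    """
    lmm_reject = 0
    cluster_reject = 0
    seeds = iter(_child_seeds(seed, 4 * n_reps))
    done = 0
    while done < n_reps:
        s = next(seeds)
        params = null_params(n_participants, seed=s)
        traits, trials, curves = simulate_design_level(
            params, n_trials=n_trials, epoch_step_ms=250.0)
        labels = traits.set_index("participant_id").loc[
            curves.index, "aq_group"].to_numpy()
        if min((labels == "high").sum(), (labels == "low").sum()) < 2:
            continue
        res = EyeLMM(trials, LMMSpec("prop_eyes_overall")).fit()
        p_int = res.anova(terms=["z_aq4:z_spin"])["p"].iloc[0]
        lmm_reject += p_int < alpha
        cres = ClusterPermutationTest(curves, labels).fit(
            n_perm=n_perm, seed=s, exact_limit=0)
        cluster_reject += any(c.p < alpha for c in cres.clusters)
        done += 1
    return {"n_reps": n_reps,
            "lmm_rejection_rate": lmm_reject / n_reps,
            "cluster_rejection_rate": cluster_reject / n_reps}


def duration_slope_recovery(n_reps: int = 100, n_participants: int = 30,
                            n_trials: int = 40, slope_spin: float = 0.15,
                            slope_spin_by_aq: float = 0.15,
                            seed: int = 0) -> dict:
    """Recovery of a SPIN effect on log first-fixation duration confined to
    high autistic traits.

    The generator injects log-dwell slopes giving a conditional SPIN slope
    of ``slope_spin + slope_spin_by_aq`` at z-AQ = +1 and
    ``slope_spin - slope_spin_by_aq`` (zero at the defaults) at z-AQ = -1.
    A replicate succeeds when the fitted simple slope is significantly
    positive at +1 SD and null at -1 SD.
    """
    successes = 0
    for s in _child_seeds(seed, n_reps):
        params = replace(null_params(n_participants, seed=s),
                         eye_dwell_slope_spin=slope_spin,
                         eye_dwell_slope_spin_by_aq=slope_spin_by_aq)
        _, trials, _ = simulate_design_level(params, n_trials=n_trials,
                                             epoch_step_ms=5000.0)
        eyes_first = trials[trials["first_face_fix_on_eyes"] == True]  # noqa: E712
        res = EyeLMM(eyes_first, LMMSpec("log_duration")).fit()
        slopes = {sl.level: sl for sl in res.simple_slopes((-1.0, 1.0))}
        ok = (slopes[1.0].p < 0.05 and slopes[1.0].B > 0
              and slopes[-1.0].p >= 0.05)
        successes += ok
    return {"n_reps": n_reps, "success_rate": successes / n_reps}


def late_cluster_recovery(n_reps: int = 100, n_participants: int = 30,
                          n_trials: int = 20, avoidance_effect: float = 0.5,
                          onset_ms: float = 5000.0, n_perm: int = 500,
                          seed: int = 0) -> dict:
    """Recovery of the late eye-looking decrement in the high-AQ group.

    A replicate succeeds when the AQ-group cluster test finds at least one
    significant cluster of reduced eye-looking (negative high-minus-low
    mass) ending after the avoidance onset.
    """
    successes = 0
    seeds = iter(_child_seeds(seed, 4 * n_reps))
    done = 0
    while done < n_reps:
        s = next(seeds)
        params = replace(null_params(n_participants, seed=s),
                         avoidance_effect=avoidance_effect,
                         avoidance_onset_ms=onset_ms)
        traits, _, curves = simulate_design_level(params, n_trials=n_trials,
                                                  epoch_step_ms=250.0)
        labels = traits.set_index("participant_id").loc[
            curves.index, "aq_group"].to_numpy()
        if min((labels == "high").sum(), (labels == "low").sum()) < 2:
            continue
        res = ClusterPermutationTest(curves, labels).fit(
            n_perm=n_perm, seed=s, exact_limit=0)
        epoch_times = res.epoch_times
        hit = False
        for c in res.clusters:
            late = epoch_times[c.end] >= onset_ms
            # group order is alphabetical: 'high' minus 'low'
            if c.p < 0.05 and late and c.mass < 0:
                hit = True
        successes += hit
        done += 1
    return {"n_reps": n_reps, "success_rate": successes / n_reps}


def roundtrip_fidelity(n_participants: int = 3, seed: int = 7,
                       min_detectable_ms: float | None = None) -> dict:
    """Noise-free render -> preprocess round trip against ground truth.

    Renders the generator's true fixation sequences to 300 Hz samples with
    zero noise and no missingness, runs the full preprocessing pipeline, and
    compares: the AOI of the first on-face fixation per trial, and the
    onset/offset of every detected fixation against its matched truth
    interval (truth intervals shorter than the detection minimum are not
    physically detectable and are skipped).
    """
    pp = PreprocessParams()
    if min_detectable_ms is None:
        min_detectable_ms = pp.min_fix_ms
    params = SimulationParams(n_participants=n_participants, seed=seed,
                              fixation_noise_px=0.0,
                              interocular_noise_px=0.0,
                              missing_burst_rate=0.0)
    ds = gen_dataset(params, render_gaze=True)
    fixation_table, validity = preprocess_dataset(ds.gaze, ds.manifest,
                                                  params=pp)
    dt = 1000.0 / params.sample_rate

    n_trials = 0
    first_fix_ok = 0
    edge_errors: list[float] = []
    seq_ok = 0
    for (pid, b, t), chunk in fixation_table.groupby(
            ["participant_id", "block", "trial"]):
        truth = ds.truth["trials"][f"{pid}/b{b}/t{t}"]["intervals"]
        truth_first = next((a for a, s, e in truth if a in ("eyes", "face")),
                           None)
        det = chunk.sort_values("onset_ms")
        det_first = det[det["aoi"].isin(["eyes", "face"])]
        n_trials += 1
        if truth_first is not None and len(det_first):
            first_fix_ok += det_first.iloc[0]["aoi"] == truth_first
        truth_d = [(a, s, e) for a, s, e in truth
                   if e - s >= min_detectable_ms]
        if len(det) == len(truth_d) and all(
                a == r.aoi for (a, s, e), r in zip(truth_d, det.itertuples())):
            seq_ok += 1
            for (a, s, e), r in zip(truth_d, det.itertuples()):
                edge_errors.append(max(abs(r.onset_ms - s),
                                       abs(r.offset_ms - e)))
    return {
        "n_trials": n_trials,
        "first_fix_recovery_rate": first_fix_ok / n_trials,
        "sequence_recovery_rate": seq_ok / n_trials,
        "max_edge_error_ms": max(edge_errors),
        "sample_period_ms": dt,
    }
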