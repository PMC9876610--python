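"""Forward simulation of a face-viewing eye-tracking experiment.

The generator emulates a cohort of college students with correlated autistic
traits (AQ) and social anxiety (SPIN) who each view emotional faces for 10 s
at a 300 Hz sampling rate, 4 blocks x 20 trials. Gaze on each trial follows a
semi-Markov sequence of fixations over three regions — the eyes band, the
rest of the face, and off-face — with trait-dependent structure:

* the latency of the first on-face fixation is log-normal, with linear trait
  effects on the log scale;
* whether that first fixation lands on the eyes is Bernoulli with linear
  trait effects on the logit scale (including an AQ x SPIN product term);
* eye-fixation dwell times are gamma distributed with linear trait effects on
  the log-mean (again with an AQ x SPIN product), so that social anxiety can
  lengthen first-fixation durations specifically at high autistic traits;
* after an avoidance onset time, simulants in the high-AQ group (dichotomous
  AQ >= 26) transition to the eyes less often, producing a late-stage
  decrement in proportional eye-looking.

Tracker drop-out is simulated as Poisson bursts of invalid samples. Every
random draw descends from one integer seed through per-participant /
per-trial child streams, so datasets are bit-reproducible and independent of
generation order.

Ground truth (the exact AOI interval sequence of every trial plus all
generative parameters) is recorded so that downstream preprocessing and
inference can be validated against known answers.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import AOISet, Rect

EMOTIONS = ("angry", "fearful", "happy", "sad", "neutral")

# Measured cohort moments used as simulation defaults: 4-point AQ 120.35
# (14.28), SPIN 24.37 (12.47), AQ-SPIN correlation 0.44, 21/60 male,
# age 22.02 (2.45).
AQ4_MEAN, AQ4_SD = 120.35, 14.28
SPIN_MEAN, SPIN_SD = 24.37, 12.47
TRAIT_CORR = 0.44


@dataclass(frozen=True)
class Participant:
    """One simulated (or observed) participant with questionnaire totals."""

    id: str
    age: float
    sex: str  # 'female' | 'male'
    aq4: int  # 4-point AQ total, 50..200
    aq_binary: int  # dichotomous AQ total, 0..50
    spin: int  # SPIN total, 0..68

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not 50 <= self.aq4 <= 200:
            raise ValueError(f"aq4 out of range [50, 200]: {self.aq4}")
        if not 0 <= self.aq_binary <= 50:
            raise ValueError(f"aq_binary out of range [0, 50]: {self.aq_binary}")
        if not 0 <= self.spin <= 68:
            raise ValueError(f"spin out of range [0, 68]: {self.spin}")


@dataclass(frozen=True)
class TrialSpec:
    """Design labels of a single trial."""

    participant_id: str
    block: int  # 1..4
    trial_index: int  # 1..20
    emotion: str
    fixation_side: str  # 'left' | 'right'
    duration_ms: float = 10_000.0
    sample_rate: float = 300.0

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}")
        if not 1 <= self.block <= 4:
            raise ValueError("block must be 1..4")
        if not 1 <= self.trial_index <= 20:
            raise ValueError("trial_index must be 1..20")
        if self.fixation_side not in ("left", "right"):
            raise ValueError("fixation_side must be 'left' or 'right'")
        n = self.duration_ms * self.sample_rate / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x sample_rate must give an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sample_rate / 1000.0))


@dataclass
class SimulationParams:
    """All knobs of the forward model. ``seed`` fully determines the output.

    Trait-effect defaults encode the qualitative result pattern the analysis
    is meant to detect: social anxiety lengthens first fixations on the eyes
    and delays them mainly at high autistic traits (positive SPIN and
    AQ x SPIN terms on log dwell / log latency, negative on the eyes-first
    logit), and high-AQ simulants show a late-stage eye-looking decrement.
    """

    n_participants: int = 60
    trait_corr: float = TRAIT_CORR
    aq4_mean: float = AQ4_MEAN
    aq4_sd: float = AQ4_SD
    spin_mean: float = SPIN_MEAN
    spin_sd: float = SPIN_SD
    male_prob: float = 21 / 60
    age_mean: float = 22.02
    age_sd: float = 2.45

    # first on-face fixation latency, log-normal on milliseconds
    latency_base: float = 5.7  # log ms; exp(5.7) ~ 299 ms
    latency_sd: float = 0.35
    latency_slope_aq: float = 0.0
    latency_slope_spin: float = 0.05
    latency_slope_spin_by_aq: float = 0.06

    # probability that the first on-face fixation lands on the eyes
    first_eye_prob_base: float = 0.29
    first_eye_slope_aq: float = 0.0
    first_eye_slope_spin: float = -0.07
    first_eye_slope_spin_by_aq: float = -0.21

    # dwell-time model (gamma; trait effects on the log-mean of eye dwells)
    eye_dwell_mean: float = 400.0  # ms
    face_dwell_mean: float = 450.0
    off_dwell_mean: float = 350.0
    dwell_shape: float = 4.0
    min_dwell: float = 100.0  # ms; floor keeps dwells detectable as fixations
    eye_dwell_slope_spin: float = 0.095
    eye_dwell_slope_spin_by_aq: float = 0.124
    participant_sd_log_dwell: float = 0.15  # random intercept on log eye dwell
    participant_sd_log_latency: float = 0.15

    # scanning chain
    p_off: float = 0.06  # chance of an off-face excursion after a fixation
    p_eyes_transition: float = 0.45  # chance an on-face fixation targets the eyes
    avoidance_effect: float = 0.30  # late reduction of eye transitions, high-AQ group
    avoidance_onset_ms: float = 5000.0
    aq_group_cutoff: int = 26  # dichotomous-AQ group split used by avoidance

    # response and missingness processes
    accuracy: float = 0.885
    missing_burst_rate: float = 0.12  # bursts per second
    missing_burst_dur: float = 180.0  # ms per burst

    # rendering noise (pixels)
    fixation_noise_px: float = 5.0
    interocular_noise_px: float = 2.5

    duration_ms: float = 10_000.0
    sample_rate: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.trait_corr < 1.0:
            raise ValueError("trait_corr must be strictly inside (-1, 1)")
        for name in ("first_eye_prob_base", "p_off", "p_eyes_transition",
                     "accuracy", "male_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.avoidance_effect <= 1.0:
            raise ValueError("avoidance_effect must be in [0, 1]")
        for name in ("missing_burst_rate", "missing_burst_dur", "eye_dwell_mean",
                     "face_dwell_mean", "off_dwell_mean", "min_dwell",
                     "fixation_noise_px", "interocular_noise_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrialRecord:
    """One trial's rendered gaze stream plus its ground truth."""

    spec: TrialSpec
    samples: pd.DataFrame  # t_ms, lx_px, ly_px, l_valid, rx_px, ry_px, r_valid
    truth_intervals: list[tuple[str, float, float]]  # (aoi, start_ms, end_ms)
    missing_bursts: list[tuple[float, float]]
    correct: bool
    response: str


def _z(value: float, mean: float, sd: float) -> float:
    return (value - mean) / sd


def trait_z(participant: Participant, params: SimulationParams) -> tuple[float, float]:
    """Participant traits on the generator's z scale (population moments)."""
    return (_z(participant.aq4, params.aq4_mean, params.aq4_sd),
            _z(participant.spin, params.spin_mean, params.spin_sd))


def aq4_to_binary(aq4: np.ndarray | int) -> np.ndarray | int:
    """Calibrated monotone map from the 4-point total to the dichotomous total.

    Both scales order respondents identically item-wise; lacking item-level
    data the dichotomous total is approximated by linearly rescaling the
    4-point range [50, 200] onto [0, 50].
    """
    out = np.clip(np.round((np.asarray(aq4) - 50) / 3.0), 0, 50).astype(int)
    return out if np.ndim(aq4) else int(out)


def gen_cohort(n: int, params: SimulationParams,
               rng: np.random.Generator | None = None,
               return_latent: bool = False):
    """Draw ``n`` participants with bivariate-normal latent AQ/SPIN traits.

    Latent traits hit the target Pearson correlation exactly in expectation;
    observed totals are rounded and clipped to the questionnaire ranges.
    """
    if n < 2:
        raise ValueError("need at least 2 participants")
    if not -1.0 < params.trait_corr < 1.0:
        raise ValueError("|trait_corr| must be < 1")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xC07]))
    cov = np.array([[1.0, params.trait_corr], [params.trait_corr, 1.0]])
    lat = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    aq4 = np.clip(np.round(params.aq4_mean + params.aq4_sd * lat[:, 0]), 50, 200).astype(int)
    spin = np.clip(np.round(params.spin_mean + params.spin_sd * lat[:, 1]), 0, 68).astype(int)
    aqb = aq4_to_binary(aq4)
    age = np.clip(np.round(rng.normal(params.age_mean, params.age_sd, size=n), 1), 18, 35)
    sex = np.where(rng.random(n) < params.male_prob, "male", "female")
    width = max(3, len(str(n)))
    cohort = [
        Participant(id=f"p{i + 1:0{width}d}", age=float(age[i]), sex=str(sex[i]),
                    aq4=int(aq4[i]), aq_binary=int(aqb[i]), spin=int(spin[i]))
        for i in range(n)
    ]
    if return_latent:
        # continuous pre-rounding/pre-clipping traits, for correlation checks
        latent = pd.DataFrame({
            "aq4": params.aq4_mean + params.aq4_sd * lat[:, 0],
            "spin": params.spin_mean + params.spin_sd * lat[:, 1],
        })
        return cohort, latent
    return cohort


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _gamma_dwell(rng: np.random.Generator, mean: float, shape: float,
                 floor: float) -> float:
    d = rng.gamma(shape, mean / shape)
    return max(d, floor)


def _draw_point(rng: np.random.Generator, rect: Rect, margin: float = 15.0,
                exclude: Rect | None = None,
                away_from: tuple[float, float] | None = None,
                min_sep: float = 60.0) -> tuple[float, float]:
    """Uniform point inside ``rect`` (shrunk by margin), optionally outside
    ``exclude`` and at least ``min_sep`` px from a previous fixation point."""
    for _ in range(200):
        x = rng.uniform(rect.x0 + margin, rect.x1 - margin)
        y = rng.uniform(rect.y0 + margin, rect.y1 - margin)
        if exclude is not None and exclude.contains(x, y):
            continue
        if away_from is not None and np.hypot(x - away_from[0], y - away_from[1]) < min_sep:
            continue
        return x, y
    return x, y  # pragma: no cover - astronomically unlikely


def _peripheral_point(side: str) -> tuple[float, float]:
    return (240.0, 540.0) if side == "left" else (1680.0, 540.0)


def simulate_aoi_sequence(spec: TrialSpec, participant: Participant,
                          params: SimulationParams, rng: np.random.Generator,
                          u_dwell: float = 0.0, u_latency: float = 0.0,
                          ) -> list[tuple[str, float, float]]:
    """Ground-truth fixation sequence: list of (aoi, start_ms, end_ms).

    The trial opens with an off-face interval (gaze still at the peripheral
    attention-getter and in transit), then alternates fixations whose targets
    and dwells follow the trait-modulated semi-Markov chain.
    """
    z_aq, z_spin = trait_z(participant, params)
    high_aq = participant.aq_binary >= params.aq_group_cutoff
    T = spec.duration_ms

    log_lat = (params.latency_base
               + params.latency_slope_aq * z_aq
               + params.latency_slope_spin * z_spin
               + params.latency_slope_spin_by_aq * z_aq * z_spin
               + u_latency
               + params.latency_sd * rng.standard_normal())
    latency = min(float(np.exp(log_lat)), T - params.min_dwell)
    latency = max(latency, 50.0)

    log_eye_mean = (np.log(params.eye_dwell_mean)
                    + params.eye_dwell_slope_spin * z_spin
                    + params.eye_dwell_slope_spin_by_aq * z_aq * z_spin
                    + u_dwell)
    eye_mean = float(np.exp(log_eye_mean))

    p_first = _sigmoid(_logit(params.first_eye_prob_base)
                       + params.first_eye_slope_aq * z_aq
                       + params.first_eye_slope_spin * z_spin
                       + params.first_eye_slope_spin_by_aq * z_aq * z_spin)

    intervals: list[tuple[str, float, float]] = [("off", 0.0, latency)]
    t = latency
    first = True
    while t < T:
        if first:
            aoi = "eyes" if rng.random() < p_first else "face"
            first = False
        elif rng.random() < params.p_off:
            aoi = "off"
        else:
            p_eyes = params.p_eyes_transition
            if high_aq and t >= params.avoidance_onset_ms:
                p_eyes *= 1.0 - params.avoidance_effect
            aoi = "eyes" if rng.random() < p_eyes else "face"
        mean = {"eyes": eye_mean, "face": params.face_dwell_mean,
                "off": params.off_dwell_mean}[aoi]
        dwell = _gamma_dwell(rng, mean, params.dwell_shape, params.min_dwell)
        end = min(t + dwell, T)
        intervals.append((aoi, t, end))
        t = end
    return intervals


def truth_to_fixations(intervals: Sequence[Sequence]) -> list:
    """Convert a ground-truth AOI interval list to labelled Fixation objects.

    Lets the metric layer run directly on the generator's true fixation
    sequence — useful for separating metric/inference behaviour from
    detection noise, and for validating detection against the truth.
    """
    from .preprocess import Fixation

    nan = float("nan")
    return [Fixation(onset=float(s), offset=float(e), cx=nan, cy=nan,
                     aoi=str(a))
            for a, s, e in intervals if e > s]


def render_samples(spec: TrialSpec, intervals: Sequence[tuple[str, float, float]],
                   params: SimulationParams, rng: np.random.Generator,
                   aois: AOISet | None = None,
                   ) -> tuple[pd.DataFrame, list[tuple[float, float]]]:
    """Render an AOI interval sequence to 300 Hz binocular samples.

    Each fixation gets one target point inside its AOI; the cyclopean gaze is
    that point plus isotropic jitter, and each eye adds small independent
    noise. Missingness bursts (Poisson starts, fixed duration) invalidate
    both eyes and blank the coordinates.
    """
    if aois is None:
        aois = AOISet.default()
    n = spec.n_samples
    dt = 1000.0 / spec.sample_rate
    t = np.arange(n) * dt
    cx = np.empty(n)
    cy = np.empty(n)
    covered = np.zeros(n, dtype=bool)

    face_margin_w = Rect(0, 0, aois.face_rect.x0, aois.screen_h)  # left strip
    prev_pt: tuple[float, float] | None = None
    for k, (aoi, start, end) in enumerate(intervals):
        if aoi == "eyes":
            pt = _draw_point(rng, aois.eyes_rect, margin=12.0,
                             away_from=prev_pt, min_sep=60.0)
        elif aoi == "face":
            pt = _draw_point(rng, aois.face_rect, margin=20.0,
                             exclude=aois.eyes_rect, away_from=prev_pt,
                             min_sep=60.0)
        elif k == 0:
            pt = _peripheral_point(spec.fixation_side)
        else:
            strip = face_margin_w if rng.random() < 0.5 else Rect(
                aois.face_rect.x1, 0, aois.screen_w, aois.screen_h)
            pt = _draw_point(rng, strip, margin=30.0)
        sel = (t >= start) & (t < end)
        cx[sel] = pt[0]
        cy[sel] = pt[1]
        covered |= sel
        prev_pt = pt
    if not covered.all():  # float-edge stragglers inherit the last fixation
        cx[~covered] = pt[0]
        cy[~covered] = pt[1]

    if params.fixation_noise_px > 0:
        cx = cx + rng.normal(0.0, params.fixation_noise_px, n)
        cy = cy + rng.normal(0.0, params.fixation_noise_px, n)

    def eye(coord: np.ndarray) -> np.ndarray:
        if params.interocular_noise_px > 0:
            return coord + rng.normal(0.0, params.interocular_noise_px, n)
        return coord.copy()

    lx, ly, rx, ry = eye(cx), eye(cy), eye(cx), eye(cy)
    valid = np.ones(n, dtype=bool)

    bursts: list[tuple[float, float]] = []
    if params.missing_burst_rate > 0 and params.missing_burst_dur > 0:
        n_bursts = rng.poisson(params.missing_burst_rate * spec.duration_ms / 1000.0)
        starts = np.sort(rng.uniform(0.0, spec.duration_ms, size=n_bursts))
        for s in starts:
            e = min(s + params.missing_burst_dur, spec.duration_ms)
            valid[(t >= s) & (t < e)] = False
            bursts.append((float(s), float(e)))
    for arr in (lx, ly, rx, ry):
        arr[~valid] = np.nan

    df = pd.DataFrame({
        "t_ms": t,
        "lx_px": lx, "ly_px": ly, "l_valid": valid,
        "rx_px": rx, "ry_px": ry, "r_valid": valid.copy(),
    })
    return df, bursts


def gen_trial_gaze(spec: TrialSpec, participant: Participant,
                   params: SimulationParams,
                   rng: np.random.Generator | None = None,
                   aois: AOISet | None = None,
                   u_dwell: float = 0.0, u_latency: float = 0.0) -> TrialRecord:
    """Simulate one complete trial (ground truth + rendered samples)."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, spec.block, spec.trial_index]))
    intervals = simulate_aoi_sequence(spec, participant, params, rng,
                                      u_dwell=u_dwell, u_latency=u_latency)
    samples, bursts = render_samples(spec, intervals, params, rng, aois=aois)
    correct = bool(rng.random() < params.accuracy)
    return TrialRecord(spec=spec, samples=samples, truth_intervals=intervals,
                       missing_bursts=bursts, correct=correct,
                       response="correct" if correct else "incorrect")


def build_design(participant_id: str, rng: np.random.Generator,
                 params: SimulationParams) -> list[TrialSpec]:
    """4 blocks x 20 trials; each block shows every emotion four times in a
    shuffled order; the peripheral attention-getter side is random."""
    specs = []
    for block in range(1, 5):
        emotions = np.array(sorted(EMOTIONS * 4))
        rng.shuffle(emotions)
        for idx in range(1, 21):
            specs.append(TrialSpec(
                participant_id=participant_id, block=block, trial_index=idx,
                emotion=str(emotions[idx - 1]),
                fixation_side="left" if rng.random() < 0.5 else "right",
                duration_ms=params.duration_ms, sample_rate=params.sample_rate))
    return specs


@dataclass
class Dataset:
    """In-memory simulated dataset plus its ground truth."""

    participants: pd.DataFrame
    manifest: pd.DataFrame
    gaze: pd.DataFrame | None
    truth: dict


def gen_dataset(params: SimulationParams, out_dir: str | Path | None = None,
                render_gaze: bool = True, aois: AOISet | None = None) -> Dataset:
    """Simulate the full experiment for ``params.n_participants`` people.

    With ``render_gaze=False`` only the design, responses and ground-truth
    AOI sequences are produced (the 300 Hz sample stream for the default
    4800-trial design is ~14M rows, which callers rarely need in memory).

    When ``out_dir`` is given, writes ``participants.csv``, ``manifest.csv``,
    ``gaze.tsv`` (if rendered) and ``ground_truth.json``.
    """
    root = np.random.SeedSequence(params.seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    cohort = gen_cohort(params.n_participants, params, rng=cohort_rng)

    part_rows = [dataclasses.asdict(p) for p in cohort]
    participants = pd.DataFrame(part_rows).rename(columns={"id": "participant_id"})

    manifest_rows = []
    gaze_frames: list[pd.DataFrame] = []
    truth_trials: dict[str, dict] = {}

    # one child stream per participant, split again per trial, so generation
    # is reproducible regardless of iteration order
    for p, pseq in zip(cohort, root.spawn(len(cohort) + 1)[1:]):
        prng = np.random.default_rng(pseq)
        u_dwell = params.participant_sd_log_dwell * prng.standard_normal()
        u_lat = params.participant_sd_log_latency * prng.standard_normal()
        specs = build_design(p.id, prng, params)
        trial_seqs = pseq.spawn(len(specs))
        for spec, tseq in zip(specs, trial_seqs):
            trng = np.random.default_rng(tseq)
            intervals = simulate_aoi_sequence(spec, p, params, trng,
                                              u_dwell=u_dwell, u_latency=u_lat)
            if render_gaze:
                samples, bursts = render_samples(spec, intervals, params, trng,
                                                 aois=aois)
                samples = samples.copy()
                samples.insert(0, "participant_id", p.id)
                samples.insert(1, "block", spec.block)
                samples.insert(2, "trial", spec.trial_index)
                gaze_frames.append(samples)
            else:
                bursts = []
            correct = bool(trng.random() < params.accuracy)
            manifest_rows.append({
                "participant_id": p.id, "block": spec.block,
                "trial": spec.trial_index, "emotion": spec.emotion,
                "fixation_side": spec.fixation_side,
                "response": "correct" if correct else "incorrect",
                "correct": int(correct),
            })
            truth_trials[f"{p.id}/b{spec.block}/t{spec.trial_index}"] = {
                "intervals": [[a, float(s), float(e)] for a, s, e in intervals],
                "missing_bursts": [[float(s), float(e)] for s, e in bursts],
                "correct": correct,
            }

    manifest = pd.DataFrame(manifest_rows)
    gaze = pd.concat(gaze_frames, ignore_index=True) if gaze_frames else None
    truth = {
        "params": dataclasses.asdict(params),
        "trials": truth_trials,
    }
    ds = Dataset(participants=participants, manifest=manifest, gaze=gaze, truth=truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        participants.to_csv(out / "participants.csv", index=False)
        manifest.to_csv(out / "manifest.csv", index=False)
        if gaze is not None:
            gaze.to_csv(out / "gaze.tsv", sep="\t", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh)
    return ds


def load_dataset(in_dir: str | Path) -> Dataset:
    """Read a dataset previously written by :func:`gen_dataset`."""
    root = Path(in_dir)
    participants = pd.read_csv(root / "participants.csv")
    manifest = pd.read_csv(root / "manifest.csv")
    gaze_path = root / "gaze.tsv"
    gaze = pd.read_csv(gaze_path, sep="\t") if gaze_path.exists() else None
    truth_path = root / "ground_truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return Dataset(participants=participants, manifest=manifest, gaze=gaze,
                   truth=truth)
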