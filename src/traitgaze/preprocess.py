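"""Gaze preprocessing: gap interpolation, binocular merging, fixation
detection, AOI labelling and trial validity classification.

The processing order mirrors standard practice for remote-tracker data:

1. short tracking drop-outs (<= 75 ms) are filled by linear interpolation,
   per eye and per coordinate;
2. the two eyes are merged into a cyclopean stream (mean when both valid,
   the valid eye when only one is);
3. fixations are detected with a dispersion-threshold algorithm (I-DT;
   a velocity-threshold I-VT mode is available);
4. fixation centroids are classified against the eyes/face AOIs;
5. trials are excluded when more than 30% of samples remain missing, when
   less than 50% of the trial is spent on the face, or when the emotion
   judgment was incorrect.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import AOISet, px_per_degree


@dataclass(frozen=True)
class Fixation:
    onset: float  # ms
    offset: float  # ms (exclusive; includes the final sample's period)
    cx: float
    cy: float
    aoi: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("fixation offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PreprocessParams:
    """Tunable preprocessing constants (defaults follow the study protocol)."""

    max_gap_ms: float = 75.0
    algorithm: str = "idt"  # 'idt' | 'ivt'
    dispersion_deg: float = 1.0
    min_fix_ms: float = 60.0
    velocity_deg_s: float = 30.0  # I-VT only
    missing_threshold: float = 0.30  # strict: > excludes
    face_threshold: float = 0.50  # strict: < excludes
    face_time_basis: str = "fixations"  # or 'samples'

    @property
    def dispersion_px(self) -> float:
        return self.dispersion_deg * px_per_degree()


@dataclass
class TrialValidity:
    valid: bool
    reasons: tuple[str, ...]
    missing_fraction: float
    face_fraction: float

    def __post_init__(self) -> None:
        if self.valid != (len(self.reasons) == 0):
            raise ValueError("valid flag inconsistent with reasons")


def _check_time_ordered(t: np.ndarray) -> None:
    if np.any(np.diff(t) <= 0):
        raise ValueError("gaze timestamps must be strictly increasing")


def _interpolate_channel(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                         valid: np.ndarray, max_gap: float,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill invalid runs bounded by valid samples when the bridged time gap
    (between the bounding valid samples) is at most ``max_gap``."""
    x, y, valid = x.copy(), y.copy(), valid.copy()
    n = len(t)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        # invalid run i..j-1; bounded iff i > 0 and j < n
        if i > 0 and j < n and (t[j] - t[i - 1]) <= max_gap:
            seg = slice(i, j)
            x[seg] = np.interp(t[seg], [t[i - 1], t[j]], [x[i - 1], x[j]])
            y[seg] = np.interp(t[seg], [t[i - 1], t[j]], [y[i - 1], y[j]])
            valid[seg] = True
        i = j
    return x, y, valid


def interpolate_gaps(samples: pd.DataFrame, max_gap: float = 75.0) -> pd.DataFrame:
    """Linear interpolation of short tracking losses, per eye.

    A maximal run of invalid samples is filled only when valid samples bound
    it on both sides and the time gap they bridge is at most ``max_gap`` ms;
    longer runs and runs touching the trial edges are left untouched. Valid
    samples are never altered.
    """
    t = samples["t_ms"].to_numpy(dtype=float)
    _check_time_ordered(t)
    out = samples.copy()
    for pre in ("l", "r"):
        x, y, v = _interpolate_channel(
            t,
            samples[f"{pre}x_px"].to_numpy(dtype=float),
            samples[f"{pre}y_px"].to_numpy(dtype=float),
            samples[f"{pre}_valid"].to_numpy(dtype=bool),
            max_gap,
        )
        out[f"{pre}x_px"], out[f"{pre}y_px"], out[f"{pre}_valid"] = x, y, v
    return out


def merge_binocular(samples: pd.DataFrame) -> pd.DataFrame:
    """Cyclopean gaze: mean of both eyes, single-eye fallback, else invalid."""
    lv = samples["l_valid"].to_numpy(dtype=bool)
    rv = samples["r_valid"].to_numpy(dtype=bool)
    lx = samples["lx_px"].to_numpy(dtype=float)
    ly = samples["ly_px"].to_numpy(dtype=float)
    rx = samples["rx_px"].to_numpy(dtype=float)
    ry = samples["ry_px"].to_numpy(dtype=float)

    x = np.full(len(samples), np.nan)
    y = np.full(len(samples), np.nan)
    both = lv & rv
    x[both] = (lx[both] + rx[both]) / 2.0
    y[both] = (ly[both] + ry[both]) / 2.0
    only_l = lv & ~rv
    x[only_l], y[only_l] = lx[only_l], ly[only_l]
    only_r = rv & ~lv
    x[only_r], y[only_r] = rx[only_r], ry[only_r]
    return pd.DataFrame({
        "t_ms": samples["t_ms"].to_numpy(dtype=float),
        "x_px": x, "y_px": y, "valid": lv | rv,
    })


def _sample_period(t: np.ndarray) -> float:
    if len(t) < 2:
        return 0.0
    return float(np.median(np.diff(t)))


def detect_fixations_idt(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                         valid: np.ndarray, dispersion_px: float,
                         min_fix_ms: float) -> list[Fixation]:
    """Dispersion-threshold (I-DT) fixation detection.

    A fixation is a maximal run of consecutive valid samples whose dispersion
    (x range + y range) stays within ``dispersion_px`` and whose duration —
    counted inclusively, one sample period per member sample — reaches
    ``min_fix_ms``. Scanning is greedy from left to right: from each start
    the window grows as far as dispersion allows; sub-threshold-duration
    windows shift the start forward by one sample. Invalid samples break
    windows.
    """
    _check_time_ordered(t)
    n = len(t)
    period = _sample_period(t)
    fixations: list[Fixation] = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        xmin = xmax = x[i]
        ymin = ymax = y[i]
        j = i
        while j + 1 < n and valid[j + 1]:
            nxmin, nxmax = min(xmin, x[j + 1]), max(xmax, x[j + 1])
            nymin, nymax = min(ymin, y[j + 1]), max(ymax, y[j + 1])
            if (nxmax - nxmin) + (nymax - nymin) > dispersion_px:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        duration = t[j] - t[i] + period
        if duration >= min_fix_ms:
            seg = slice(i, j + 1)
            fixations.append(Fixation(
                onset=float(t[i]), offset=float(t[j] + period),
                cx=float(np.mean(x[seg])), cy=float(np.mean(y[seg]))))
            i = j + 1
        else:
            i += 1
    return fixations


def detect_fixations_ivt(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                         valid: np.ndarray, velocity_deg_s: float,
                         min_fix_ms: float) -> list[Fixation]:
    """Velocity-threshold (I-VT) detection: samples whose point-to-point
    velocity is below threshold are fixation samples; runs shorter than
    ``min_fix_ms`` are discarded."""
    _check_time_ordered(t)
    n = len(t)
    if n == 0:
        return []
    period = _sample_period(t)
    thr_px_ms = velocity_deg_s * px_per_degree() / 1000.0
    slow = np.zeros(n, dtype=bool)
    slow[0] = valid[0]
    for k in range(1, n):
        if not (valid[k] and valid[k - 1]):
            slow[k] = False
            continue
        v = np.hypot(x[k] - x[k - 1], y[k] - y[k - 1]) / (t[k] - t[k - 1])
        slow[k] = v <= thr_px_ms
    fixations: list[Fixation] = []
    i = 0
    while i < n:
        if not slow[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and slow[j + 1]:
            j += 1
        if t[j] - t[i] + period >= min_fix_ms:
            seg = slice(i, j + 1)
            fixations.append(Fixation(
                onset=float(t[i]), offset=float(t[j] + period),
                cx=float(np.mean(x[seg])), cy=float(np.mean(y[seg]))))
        i = j + 1
    return fixations


def detect_fixations(samples: pd.DataFrame,
                     params: PreprocessParams | None = None) -> list[Fixation]:
    """Detect fixations on a cyclopean, gap-filled sample stream."""
    if params is None:
        params = PreprocessParams()
    if len(samples) == 0:
        return []
    t = samples["t_ms"].to_numpy(dtype=float)
    x = samples["x_px"].to_numpy(dtype=float)
    y = samples["y_px"].to_numpy(dtype=float)
    v = samples["valid"].to_numpy(dtype=bool)
    if params.algorithm == "idt":
        return detect_fixations_idt(t, x, y, v, params.dispersion_px,
                                    params.min_fix_ms)
    if params.algorithm == "ivt":
        return detect_fixations_ivt(t, x, y, v, params.velocity_deg_s,
                                    params.min_fix_ms)
    raise ValueError(f"unknown fixation algorithm {params.algorithm!r}")


def assign_aoi(fix: Fixation, aois: AOISet) -> str:
    """AOI label of a fixation's centroid (half-open rectangle membership)."""
    return aois.label(fix.cx, fix.cy)


def label_fixations(fixations: Sequence[Fixation], aois: AOISet) -> list[Fixation]:
    return [Fixation(f.onset, f.offset, f.cx, f.cy, assign_aoi(f, aois))
            for f in fixations]


def validate_trial(samples: pd.DataFrame, fixations: Sequence[Fixation],
                   correct: bool, params: PreprocessParams | None = None,
                   duration_ms: float | None = None) -> TrialValidity:
    """Apply the three exclusion rules to one trial.

    ``samples`` must be the merged, gap-filled stream: the missing fraction
    counts samples still invalid after interpolation, over the full trial
    window. Face time is the summed duration of fixations labelled eyes or
    face (or the corresponding sample count when ``face_time_basis`` is
    'samples' — requires AOI-labelled samples, not implemented here for
    fixation-free streams). Thresholds are strict: exactly 30% missing or
    exactly 50% face time keeps the trial.
    """
    if params is None:
        params = PreprocessParams()
    t = samples["t_ms"].to_numpy(dtype=float)
    if duration_ms is None:
        duration_ms = float(len(t) * _sample_period(t)) if len(t) else 0.0
    valid = samples["valid"].to_numpy(dtype=bool)
    missing_fraction = float(1.0 - valid.mean()) if len(valid) else 1.0

    if params.face_time_basis == "samples":
        aois = AOISet.default()
        x = samples["x_px"].to_numpy(dtype=float)
        y = samples["y_px"].to_numpy(dtype=float)
        on_face = np.zeros(len(samples), dtype=bool)
        for k in range(len(samples)):
            if valid[k]:
                on_face[k] = aois.label(x[k], y[k]) != "off"
        face_time = float(on_face.sum() * _sample_period(t))
    else:
        face_time = float(sum(f.duration for f in fixations
                              if f.aoi in ("eyes", "face")))
    face_fraction = face_time / duration_ms if duration_ms > 0 else 0.0

    reasons: list[str] = []
    # strict inequalities with a float guard: a trial at exactly the
    # threshold is kept
    eps = 1e-9
    if missing_fraction > params.missing_threshold + eps:
        reasons.append("missing_gt_30pct")
    if face_fraction < params.face_threshold - eps:
        reasons.append("face_lt_50pct")
    if not correct:
        reasons.append("incorrect_response")
    return TrialValidity(valid=not reasons, reasons=tuple(reasons),
                         missing_fraction=missing_fraction,
                         face_fraction=face_fraction)


def preprocess_trial(samples: pd.DataFrame, correct: bool,
                     aois: AOISet | None = None,
                     params: PreprocessParams | None = None,
                     duration_ms: float | None = None,
                     ) -> tuple[list[Fixation], TrialValidity]:
    """Full per-trial pipeline: interpolate -> merge -> detect -> label -> validate."""
    if params is None:
        params = PreprocessParams()
    if aois is None:
        aois = AOISet.default()
    filled = interpolate_gaps(samples, params.max_gap_ms)
    merged = merge_binocular(filled)
    fixations = label_fixations(detect_fixations(merged, params), aois)
    validity = validate_trial(merged, fixations, correct, params,
                              duration_ms=duration_ms)
    return fixations, validity


def preprocess_dataset(gaze: pd.DataFrame, manifest: pd.DataFrame,
                       aois: AOISet | None = None,
                       params: PreprocessParams | None = None,
                       duration_ms: float = 10_000.0,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the trial pipeline over a long-format gaze table.

    Returns a fixation table (one row per fixation) and a validity table
    (one row per trial with exclusion reasons). Trials present in the gaze
    table but absent from the manifest raise a data error.
    """
    if params is None:
        params = PreprocessParams()
    if aois is None:
        aois = AOISet.default()
    man = manifest.set_index(["participant_id", "block", "trial"])
    fix_rows: list[dict] = []
    val_rows: list[dict] = []
    for (pid, block, trial), chunk in gaze.groupby(
            ["participant_id", "block", "trial"], sort=True):
        try:
            correct = bool(man.loc[(pid, block, trial), "correct"])
        except KeyError as exc:
            raise KeyError(
                f"trial {pid}/b{block}/t{trial} missing from manifest") from exc
        fixations, validity = preprocess_trial(
            chunk.reset_index(drop=True), correct, aois=aois, params=params,
            duration_ms=duration_ms)
        for f in fixations:
            fix_rows.append({
                "participant_id": pid, "block": block, "trial": trial,
                "onset_ms": f.onset, "offset_ms": f.offset,
                "duration_ms": f.duration, "cx": f.cx, "cy": f.cy,
                "aoi": f.aoi,
            })
        val_rows.append({
            "participant_id": pid, "block": block, "trial": trial,
            "valid": validity.valid,
            "reasons": ";".join(validity.reasons),
            "missing_fraction": validity.missing_fraction,
            "face_fraction": validity.face_fraction,
        })
    fix_cols = ["participant_id", "block", "trial", "onset_ms", "offset_ms",
                "duration_ms", "cx", "cy", "aoi"]
    val_cols = ["participant_id", "block", "trial", "valid", "reasons",
                "missing_fraction", "face_fraction"]
    return (pd.DataFrame(fix_rows, columns=fix_cols),
            pd.DataFrame(val_rows, columns=val_cols))
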