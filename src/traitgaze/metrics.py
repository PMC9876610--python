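"""Questionnaire scoring, trait standardization and gaze dependent variables.

Covers the AQ (Autism-spectrum Quotient, 50 items) under both its 4-point
(range 50-200) and dichotomous (0-50) scoring systems, the SPIN (Social
Phobia Inventory, 17 items, 0-68), trait grouping at the published screening
cutoffs (dichotomous AQ >= 26, SPIN >= 19), and the per-trial eye-looking
measures: overall proportional eye-looking time, the first on-face fixation
(whether it lands on the eyes, its duration, and its latency from face
onset), and the 250 ms moving-average eye-looking time course.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import Fixation

AQ_CUTOFF = 26  # dichotomous scale
SPIN_CUTOFF = 19

# Standard AQ key: items where agreement indicates autistic traits; the
# remaining 26 items are reverse-keyed (disagreement is trait-consistent).
AQ_AGREE_ITEMS = (2, 4, 5, 6, 7, 9, 12, 13, 16, 18, 19, 20, 21, 22, 23, 26,
                  33, 35, 39, 41, 42, 43, 45, 46)

N_AQ_ITEMS = 50
N_SPIN_ITEMS = 17


def score_aq_items(responses: pd.DataFrame,
                   agree_items: Sequence[int] = AQ_AGREE_ITEMS,
                   ) -> pd.DataFrame:
    """Score 50 AQ items (columns aq_1..aq_50, responses 1-4).

    4-point total: each item scored 1-4 in the trait direction (reverse-keyed
    items flipped as 5 - response), summed over items (range 50-200).
    Dichotomous total: one point per item endorsed in the trait direction
    (oriented response of 3 or 4), range 0-50.
    """
    cols = [f"aq_{i}" for i in range(1, N_AQ_ITEMS + 1)]
    missing = [c for c in cols if c not in responses.columns]
    if missing:
        raise ValueError(f"missing AQ item columns: {missing[:5]}...")
    vals = responses[cols].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing AQ item responses; no imputation is applied")
    if not ((vals >= 1) & (vals <= 4)).all():
        raise ValueError("AQ items must be 1..4")
    agree = np.zeros(N_AQ_ITEMS, dtype=bool)
    agree[[i - 1 for i in agree_items]] = True
    oriented = np.where(agree, vals, 5 - vals)
    return pd.DataFrame({
        "aq4": oriented.sum(axis=1).astype(int),
        "aq_binary": (oriented >= 3).sum(axis=1).astype(int),
    }, index=responses.index)


def score_spin_items(responses: pd.DataFrame) -> pd.Series:
    """SPIN total: plain sum of 17 items rated 0-4."""
    cols = [f"spin_{i}" for i in range(1, N_SPIN_ITEMS + 1)]
    missing = [c for c in cols if c not in responses.columns]
    if missing:
        raise ValueError(f"missing SPIN item columns: {missing[:5]}...")
    vals = responses[cols].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing SPIN item responses; no imputation is applied")
    if not ((vals >= 0) & (vals <= 4)).all():
        raise ValueError("SPIN items must be 0..4")
    return pd.Series(vals.sum(axis=1).astype(int), index=responses.index,
                     name="spin")


def score_scales(data: pd.DataFrame) -> pd.DataFrame:
    """Questionnaire totals from item responses or pass-through totals.

    Accepts item columns (aq_1..aq_50 and/or spin_1..spin_17) and/or
    precomputed totals (aq4, aq_binary, spin); item columns take precedence.
    """
    out = pd.DataFrame(index=data.index)
    if "aq_1" in data.columns:
        out[["aq4", "aq_binary"]] = score_aq_items(data)
    elif {"aq4", "aq_binary"}.issubset(data.columns):
        out["aq4"] = data["aq4"].astype(int)
        out["aq_binary"] = data["aq_binary"].astype(int)
    if "spin_1" in data.columns:
        out["spin"] = score_spin_items(data)
    elif "spin" in data.columns:
        out["spin"] = data["spin"].astype(int)
    if out.empty or out.isna().any().any():
        raise ValueError("could not score scales: need items or totals")
    return out


def standardize_and_group(participants: pd.DataFrame,
                          aq_cutoff: int = AQ_CUTOFF,
                          spin_cutoff: int = SPIN_CUTOFF) -> pd.DataFrame:
    """Add z-scored traits (sample mean/SD) and high/low group labels.

    Standardization uses the analysis sample handed in (post-exclusion),
    with the unbiased (ddof=1) SD. Groups use the screening cutoffs on the
    dichotomous AQ and the SPIN total, both inclusive (>=).
    """
    if len(participants) < 2:
        raise ValueError("need at least 2 participants to standardize")
    out = participants.copy()
    for src, dst in (("aq4", "z_aq4"), ("spin", "z_spin")):
        x = out[src].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in {src}; cannot standardize")
        out[dst] = (x - x.mean()) / sd
    out["aq_group"] = np.where(out["aq_binary"] >= aq_cutoff, "high", "low")
    out["spin_group"] = np.where(out["spin"] >= spin_cutoff, "high", "low")
    return out


def aq_levels_from_moments(mean: float, sd: float,
                           levels: Sequence[float] = (-1.0, 0.0, 1.0)) -> dict[str, int]:
    """Map z-scale moderator levels back to original-scale scores (rounded).

    With the full-sample 4-point AQ moments 120.35 (SD 14.28) the -1/0/+1
    levels land on 106, 120 and 135.
    """
    names = {-1.0: "low", 0.0: "medium", 1.0: "high"}
    return {names.get(lv, str(lv)): int(round(mean + lv * sd)) for lv in levels}


@dataclass
class TrialMetrics:
    """Per-trial dependent variables (NaN where undefined)."""

    prop_eyes_overall: float
    first_face_fix_on_eyes: bool | None
    first_fix_duration: float
    latency_to_eyes: float

    @property
    def log_duration(self) -> float:
        return math.log(self.first_fix_duration) if self.first_fix_duration > 0 else math.nan

    @property
    def log_latency(self) -> float:
        return math.log(self.latency_to_eyes) if self.latency_to_eyes > 0 else math.nan


def trial_gaze_metrics(fixations: Sequence[Fixation]) -> TrialMetrics:
    """Eye-looking measures of one valid trial.

    ``prop_eyes_overall`` is eyes fixation time over eyes+face fixation time
    across the whole trial. The first on-face fixation is the earliest one
    labelled eyes or face; only when it lands on the eyes are the
    first-fixation duration and the latency to the eyes defined.
    """
    eyes_time = sum(f.duration for f in fixations if f.aoi == "eyes")
    face_time = sum(f.duration for f in fixations if f.aoi == "face")
    denom = eyes_time + face_time
    prop = eyes_time / denom if denom > 0 else math.nan

    on_face = [f for f in fixations if f.aoi in ("eyes", "face")]
    if not on_face:
        return TrialMetrics(prop, None, math.nan, math.nan)
    first = min(on_face, key=lambda f: f.onset)
    if first.aoi == "eyes":
        return TrialMetrics(prop, True, first.duration, first.onset)
    return TrialMetrics(prop, False, math.nan, math.nan)


def participant_first_fix_proportion(trial_flags: Iterable[bool | None]) -> float:
    """Share of valid correct trials whose first on-face fixation hit the eyes.

    ``trial_flags`` holds one entry per valid correct trial (None when the
    trial had no on-face fixation; such trials still count in the
    denominator, matching division by the number of valid correct trials).
    """
    flags = list(trial_flags)
    if not flags:
        raise ValueError("no valid correct trials for this participant")
    return sum(1 for f in flags if f is True) / len(flags)


def epoch_timecourse(fixations: Sequence[Fixation], duration_ms: float = 10_000.0,
                     window_ms: float = 250.0, step_ms: float = 50.0,
                     ) -> pd.DataFrame:
    """Moving-average proportional eye-looking time course.

    For each window position the value is eyes fixation time over eyes+face
    fixation time within the window, computed from exact fixation-interval
    overlap; windows with no face-looking at all are NaN. Returns columns
    ``t_ms`` (window centre) and ``prop_eyes``.
    """
    starts = np.arange(0.0, duration_ms - window_ms + 1e-9, step_ms)
    ends = starts + window_ms
    eyes = np.zeros(len(starts))
    face = np.zeros(len(starts))
    for f in fixations:
        if f.aoi not in ("eyes", "face"):
            continue
        overlap = np.clip(np.minimum(ends, f.offset) - np.maximum(starts, f.onset),
                          0.0, None)
        if f.aoi == "eyes":
            eyes += overlap
        else:
            face += overlap
    denom = eyes + face
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(denom > 0, eyes / denom, np.nan)
    return pd.DataFrame({"t_ms": starts + window_ms / 2.0, "prop_eyes": prop})


def exclusion_summary(validity: pd.DataFrame) -> dict:
    """Counts and percentages of excluded trials, overall and per reason.

    Reasons are non-exclusive (a trial can fail several rules); the overall
    invalid percentage is invalid/total x 100, rounded to one decimal.
    """
    total = len(validity)
    invalid = int((~validity["valid"].astype(bool)).sum())
    reason_counts: dict[str, int] = {}
    for reasons in validity["reasons"].fillna(""):
        for r in str(reasons).split(";"):
            if r:
                reason_counts[r] = reason_counts.get(r, 0) + 1
    pct = round(100.0 * invalid / total, 1) if total else 0.0
    return {
        "n_trials": total,
        "n_invalid": invalid,
        "invalid_pct": pct,
        "reason_counts": reason_counts,
    }


def compute_trial_metrics_table(fixation_table: pd.DataFrame,
                                validity_table: pd.DataFrame,
                                duration_ms: float = 10_000.0,
                                window_ms: float = 250.0,
                                step_ms: float = 50.0,
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy per-trial metrics and per-trial epoch curves over valid trials.

    Returns ``(trial_metrics, epoch_long)``: one row per valid trial, and one
    row per valid trial x epoch.
    """
    keys = ["participant_id", "block", "trial"]
    valid_ix = validity_table.loc[validity_table["valid"].astype(bool), keys]
    valid_set = set(map(tuple, valid_ix.to_numpy()))
    met_rows = []
    epoch_rows = []
    grouped = dict(tuple(fixation_table.groupby(keys, sort=True)))
    for key in sorted(valid_set):
        chunk = grouped.get(key)
        fixations = [] if chunk is None else [
            Fixation(r.onset_ms, r.offset_ms, r.cx, r.cy, r.aoi)
            for r in chunk.itertuples()
        ]
        m = trial_gaze_metrics(fixations)
        met_rows.append({
            "participant_id": key[0], "block": key[1], "trial": key[2],
            "prop_eyes_overall": m.prop_eyes_overall,
            "first_face_fix_on_eyes": m.first_face_fix_on_eyes,
            "first_fix_duration": m.first_fix_duration,
            "latency_to_eyes": m.latency_to_eyes,
            "log_duration": m.log_duration,
            "log_latency": m.log_latency,
        })
        curve = epoch_timecourse(fixations, duration_ms, window_ms, step_ms)
        curve.insert(0, "participant_id", key[0])
        curve.insert(1, "block", key[1])
        curve.insert(2, "trial", key[2])
        epoch_rows.append(curve)
    met_cols = ["participant_id", "block", "trial", "prop_eyes_overall",
                "first_face_fix_on_eyes", "first_fix_duration",
                "latency_to_eyes", "log_duration", "log_latency"]
    trial_metrics = pd.DataFrame(met_rows, columns=met_cols)
    epoch_long = (pd.concat(epoch_rows, ignore_index=True) if epoch_rows
                  else pd.DataFrame(columns=["participant_id", "block", "trial",
                                             "t_ms", "prop_eyes"]))
    return trial_metrics, epoch_long


def participant_epoch_curves(epoch_long: pd.DataFrame) -> pd.DataFrame:
    """Average each participant's valid-trial curves: participants x epochs."""
    return (epoch_long.pivot_table(index="participant_id", columns="t_ms",
                                   values="prop_eyes", aggfunc="mean")
            .sort_index(axis=1))
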