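"""Independent brute-force oracles used to validate the fast implementations.

Each oracle recomputes its quantity from first principles (full rescans,
exhaustive enumeration, per-sample counting) and shares no code with the
implementation path it checks.
"""
from __future__ import annotations

import itertools

import numpy as np
import scipy.stats as st


def idt_oracle(t, x, y, valid, dispersion_px, min_fix_ms):
    """Exhaustive window-growing fixation detection.

    From each candidate start, every window end is tested by recomputing the
    dispersion of the whole window from scratch; the maximal admissible
    window is kept if its inclusive duration reaches the minimum.
    Returns (onset, offset, cx, cy) tuples.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n = len(t)
    period = float(np.median(np.diff(t))) if n > 1 else 0.0
    out = []
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        best = None
        for j in range(i, n):
            if not valid[j]:
                break
            xs, ys = x[i:j + 1], y[i:j + 1]
            if (xs.max() - xs.min()) + (ys.max() - ys.min()) > dispersion_px:
                break
            best = j
        if best is not None and t[best] - t[i] + period >= min_fix_ms:
            seg = slice(i, best + 1)
            out.append((float(t[i]), float(t[best] + period),
                        float(np.mean(x[seg])), float(np.mean(y[seg]))))
            i = best + 1
        else:
            i += 1
    return out


def epoch_recount_oracle(fixations, duration_ms, window_ms, step_ms,
                         sample_rate=300.0):
    """Per-sample recount of the proportional eye-looking curve.

    Classifies every 300 Hz sample tick against the fixation intervals and
    counts ticks per window; equals interval-overlap arithmetic exactly when
    all interval and window edges sit on the sample grid.
    """
    dt = 1000.0 / sample_rate
    ticks = np.arange(int(round(duration_ms / dt))) * dt
    labels = np.full(len(ticks), "none", dtype=object)
    for f in fixations:
        sel = (ticks >= f.onset) & (ticks < f.offset)
        labels[sel] = f.aoi
    starts = np.arange(0.0, duration_ms - window_ms + 1e-9, step_ms)
    vals = []
    for s in starts:
        w = (ticks >= s) & (ticks < s + window_ms)
        eyes = np.sum((labels == "eyes") & w)
        face = np.sum((labels == "face") & w)
        vals.append(np.nan if eyes + face == 0 else eyes / (eyes + face))
    return np.array(starts + window_ms / 2.0), np.array(vals)


def _welch_t_scalar(a, b):
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    res = st.ttest_ind(a, b, equal_var=False)
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return res.statistic, df


def cluster_enumeration_oracle(curves, in_g1, alpha=0.05):
    """Exact cluster permutation p-values by full enumeration.

    Recomputes the epoch-wise Welch t through scipy, finds same-sign
    supra-threshold runs with a plain loop, and enumerates every relabelling
    of the participants (identity included).
    """
    curves = np.asarray(curves, dtype=float)
    n = curves.shape[0]
    n1 = int(np.sum(in_g1))

    def clusters_of(mask):
        g1 = curves[mask]
        g2 = curves[~mask]
        found = []
        run = []
        run_sign = 0
        for e in range(curves.shape[1]):
            tval, df = _welch_t_scalar(g1[:, e], g2[:, e])
            crit = st.t.ppf(1 - alpha / 2, df)
            sig = np.isfinite(tval) and abs(tval) > crit
            sign = int(np.sign(tval)) if sig else 0
            if sig and (not run or sign == run_sign):
                run.append((e, tval))
                run_sign = sign
            else:
                if run:
                    found.append((run[0][0], run[-1][0],
                                  sum(v for _, v in run)))
                run = [(e, tval)] if sig else []
                run_sign = sign
        if run:
            found.append((run[0][0], run[-1][0], sum(v for _, v in run)))
        return found

    obs = clusters_of(np.asarray(in_g1, dtype=bool))
    null_max = []
    for combo in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        cl = clusters_of(mask)
        null_max.append(max((abs(m) for _, _, m in cl), default=0.0))
    null_max = np.array(null_max)
    return [(i, j, m, float(np.mean(null_max >= abs(m) - 1e-12)))
            for i, j, m in obs]
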