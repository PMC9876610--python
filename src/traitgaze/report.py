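"""Human-readable reporting from a results bundle.

Everything rendered here is read verbatim from the bundle produced by
``analyze_all``; no statistics are computed in this layer.
"""
from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def _require(bundle: dict, key: str) -> dict:
    if key not in bundle:
        raise KeyError(f"results bundle is missing section {key!r}")
    return bundle[key]


def render_text(bundle: dict) -> str:
    lines = ["traitgaze analysis report",
             "=" * 30,
             f"config digest: {bundle.get('config_digest', '?')}, "
             f"seed: {bundle.get('seed', '?')}", ""]
    exc = _require(bundle, "exclusions")
    lines.append(f"Trials: {exc['n_trials']} total, {exc['n_invalid']} "
                 f"invalid ({exc['invalid_pct']}%)")
    for reason, count in sorted(exc.get("reason_counts", {}).items()):
        lines.append(f"  {reason}: {count}")
    lines.append("")

    analyses = [("overall_prop_eyes", "Overall proportional eye-looking time"),
                ("first_fix_proportion", "Proportion of first fixations on the eyes"),
                ("log_first_fix_duration", "Log first-fixation duration (eyes-first trials)"),
                ("log_latency_to_eyes", "Log latency to the eyes (eyes-first trials)")]
    for key, title in analyses:
        a = _require(bundle, key)
        lines.append(f"[{title}]  (n={a['n_obs']}, converged={a['converged']})")
        for row in a["anova"]:
            star = " *" if row["p"] < 0.05 else ""
            lines.append(f"  {row['term']:<40} F({row['num_df']}, "
                         f"{row['den_df']:.2f}) = {row['F']:.3f}, "
                         f"p = {row['p']:.4f}{star}")
        lines.append("  simple slopes of z_spin:")
        for s in a["simple_slopes"]:
            star = " *" if s["p"] < 0.05 else ""
            lines.append(f"    {s['label']:>6}: B={s['B']:+.4f}, "
                         f"t({s['df']:.1f})={s['t']:+.3f}, "
                         f"beta={s['beta']:+.3f}, p={s['p']:.4f}{star}")
        lines.append("")

    ct = _require(bundle, "cluster_tests")
    for key, title in (("aq_groups", "High vs low autistic traits"),
                       ("spin_groups", "High vs low social anxiety")):
        c = ct[key]
        mode = "exact" if c["exact"] else f"{c['n_perm']} permutations"
        lines.append(f"[Time course: {title}]  ({mode})")
        sig = [cl for cl in c["clusters"] if cl["p"] < 0.05]
        if not c["clusters"]:
            lines.append("  no significant clusters")
        for cl in c["clusters"]:
            star = " *" if cl["p"] < 0.05 else ""
            span = (f"{cl['start_ms']:.0f}-{cl['end_ms']:.0f} ms"
                    if cl.get("start_ms") is not None
                    else f"epochs {cl['start']}-{cl['end']}")
            lines.append(f"  cluster {span}: mass={cl['mass']:+.2f}, "
                         f"p={cl['p']:.4f}{star}")
        if c["clusters"] and not sig:
            lines.append("  no significant clusters")
        lines.append("")
    # the two group comparisons form the single temporal analysis
    lines.append(f"analyses reported: {len(analyses) + (1 if ct else 0)}")
    return "\n".join(lines)


def plot_simple_slopes(bundle: dict, key: str, path: str | Path) -> None:
    """Slope-of-SPIN plot at the three autistic-trait levels."""
    a = _require(bundle, key)
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = np.linspace(-2, 2, 50)
    for s in a["simple_slopes"]:
        ax.plot(xs, s["B"] * xs, label=f"{s['label']} AQ "
                f"(B={s['B']:+.3f}, p={s['p']:.3f})")
    ax.set_xlabel("z-SPIN")
    ax.set_ylabel(f"predicted change in {key}")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cluster_test(bundle: dict, key: str, path: str | Path) -> None:
    """Per-epoch t trace with significant clusters shaded."""
    c = _require(bundle, "cluster_tests")[key]
    t = np.array([np.nan if v is None else v for v in c["t_trace"]])
    x = (np.array(c["epoch_times"], dtype=float) / 1000.0
         if c.get("epoch_times") else np.arange(len(t)))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(x, t, lw=1.2, label="Welch t per epoch")
    for cl in c["clusters"]:
        if cl["p"] < 0.05:
            ax.axvspan(x[cl["start"]], x[cl["end"]], color="grey", alpha=0.4)
    ax.axhline(0.0, color="black", lw=0.5)
    ax.set_xlabel("time (s)" if c.get("epoch_times") else "epoch")
    ax.set_ylabel("t (group difference)")
    ax.set_title(f"{'/'.join(c.get('groups', []))} time-course comparison")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(bundle: dict, out_dir: str | Path) -> Path:
    """Write report.txt plus the slope and time-course figures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    text = render_text(bundle)
    (out / "report.txt").write_text(text)
    for key in ("overall_prop_eyes", "first_fix_proportion",
                "log_first_fix_duration", "log_latency_to_eyes"):
        plot_simple_slopes(bundle, key, out / f"slopes_{key}.png")
    for key in ("aq_groups", "spin_groups"):
        plot_cluster_test(bundle, key, out / f"timecourse_{key}.png")
    return out / "report.txt"


def load_bundle(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
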