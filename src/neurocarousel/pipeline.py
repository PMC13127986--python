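"""End-to-end orchestration: session-level ephys analysis, cohort
aggregation and the synthetic-replica experiment.

``run_session`` turns one animal's recording plus a session timeline into a
tidy metric table (band powers, baseline percent changes, PLV per band
pair); ``run_cohort`` simulates or consumes a cohort, assembles the group
table and applies the normality-gated statistics per metric.  Every output
row carries the seed and a config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import LfpRecording, read_lfp
from .preprocess import (Band, HIGH_GAMMA, LOW_GAMMA, THETA, SessionTimeline,
                         extract_window, remove_line_noise)
from .spectral import band_power, percent_change, welch_psd
from .pac import plv_pac
from .stats import StatReport, analyze_metric, groups_from_table, mean_sem
from .synthetic import CohortSpec, generate_cohort, spec_to_json

__all__ = ["SessionConfig", "run_session", "run_cohort", "CohortResult"]

DEFAULT_POWER_BANDS = (LOW_GAMMA, HIGH_GAMMA)
DEFAULT_PAC_PAIRS = ((THETA, LOW_GAMMA), (THETA, HIGH_GAMMA))


@dataclass
class SessionConfig:
    """Everything needed to analyse one animal's session."""

    animal: str
    recording: LfpRecording | str        # in-memory or a path readable by read_lfp
    timeline: SessionTimeline = field(default_factory=SessionTimeline)
    power_bands: tuple[Band, ...] = DEFAULT_POWER_BANDS
    pac_pairs: tuple[tuple[Band, Band], ...] = DEFAULT_PAC_PAIRS
    notch: dict = field(default_factory=lambda: {"base_freq": 50.0,
                                                 "n_harmonics": 5, "q": 30.0})
    seg_len: float = 2.0
    seed: int = 0

    def hash(self) -> str:
        payload = {
            "animal": self.animal,
            "windows": self.timeline.windows,
            "baseline": self.timeline.baseline_label,
            "bands": [(b.name, b.f_lo, b.f_hi) for b in self.power_bands],
            "pac": [(p.name, a.name) for p, a in self.pac_pairs],
            "notch": self.notch,
            "seg_len": self.seg_len,
            "seed": self.seed,
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True,
                                       default=str).encode()).hexdigest()[:12]


def _analyse_epoch(rec: LfpRecording, cfg: SessionConfig) -> dict[str, object]:
    """Band powers (per channel) and PAC results for one cleaned epoch."""
    clean = remove_line_noise(rec, **cfg.notch)
    psd = welch_psd(clean, seg_len=cfg.seg_len)
    powers = {b.name: band_power(psd, b) for b in cfg.power_bands}
    pac = {}
    for phase_b, amp_b in cfg.pac_pairs:
        pac[f"{phase_b.name}_{amp_b.name}"] = plv_pac(clean, amp_b, phase_b)
    return {"powers": powers, "pac": pac}


def run_session(cfg: SessionConfig) -> tuple[pd.DataFrame, list[str]]:
    """Analyse every window of one animal's session.

    Returns a tidy table with columns (animal, window, metric, value,
    config_hash, seed) — metrics are per-channel band powers averaged over
    valid electrodes, baseline percent changes for every non-baseline
    window, and PLV per band pair — plus a list of per-item error messages
    (a missing window or corrupt channel skips that item and the run
    continues).
    """
    rec = cfg.recording if isinstance(cfg.recording, LfpRecording) else read_lfp(cfg.recording)
    chash = cfg.hash()
    rows: list[dict] = []
    errors: list[str] = []
    epochs: dict[str, dict] = {}
    labels = list(cfg.timeline.windows) or ["__whole__"]
    for label in labels:
        try:
            win = rec if label == "__whole__" else extract_window(rec, cfg.timeline, label)
            epochs[label] = _analyse_epoch(win, cfg)
        except Exception as exc:  # keep going per spec: per-item error
            errors.append(f"{cfg.animal}/{label}: {exc}")
            continue
        res = epochs[label]
        for bname, bp in res["powers"].items():
            rows.append({"metric": f"{bname}_power", "window": label,
                         "value": bp.mean})
        for pname, pr in res["pac"].items():
            rows.append({"metric": f"plv_{pname}", "window": label,
                         "value": pr.plv})
            rows.append({"metric": f"plv_{pname}_phase", "window": label,
                         "value": pr.mean_phase})
    base = cfg.timeline.baseline_label
    if base in epochs:
        for label, res in epochs.items():
            if label == base:
                continue
            for bname, bp in res["powers"].items():
                try:
                    change = percent_change(bp, epochs[base]["powers"][bname])
                except Exception as exc:
                    errors.append(f"{cfg.animal}/{label}/{bname}: {exc}")
                    continue
                rows.append({"metric": f"{bname}_power_pct", "window": label,
                             "value": change.mean})
    df = pd.DataFrame(rows)
    if len(df):
        df.insert(0, "animal", cfg.animal)
        df["config_hash"] = chash
        df["seed"] = cfg.seed
    return df, errors


@dataclass
class CohortResult:
    """Group table, per-metric statistics and a readable report."""

    table: pd.DataFrame
    stats: dict[str, StatReport]
    report: str
    truth: pd.DataFrame
    errors: list[str] = field(default_factory=list)


# metrics the group comparison runs on, matching the study's comparisons:
# percent-of-baseline band power and post-epoch PLV per band pair
COHORT_METRICS = (
    "low_gamma_power_pct",
    "high_gamma_power_pct",
    "plv_theta_low_gamma",
    "plv_theta_high_gamma",
)


def run_cohort(spec: CohortSpec, alpha: float = 0.05,
               dunn_adjust: str = "bonferroni") -> CohortResult:
    """Simulate a cohort and push every animal through the full pipeline.

    Per animal: notch-clean both epochs, estimate band powers and PLV,
    express post-epoch power as percent of the animal's own baseline, and
    average electrodes.  Group statistics (normality gate, then ANOVA+Tukey
    or KW+Dunn) run per metric over the post-epoch values; groups with
    fewer than 3 animals skip statistics with a warning.
    """
    if len(spec.groups) < 2:
        raise ValueError("cohort statistics need at least 2 groups")
    animals, truth = generate_cohort(spec)
    chash = hashlib.sha1(spec_to_json(spec).encode()).hexdigest()[:12]
    frames = []
    errors: list[str] = []
    timeline = SessionTimeline(
        windows={"baseline": (0.0, spec.window_duration),
                 "post": (0.0, spec.window_duration)},
        baseline_label="baseline",
    )
    for a in animals:
        per_window = {}
        for label, rec in (("baseline", a.baseline), ("post", a.post)):
            cfg = SessionConfig(animal=a.animal, recording=rec,
                                timeline=SessionTimeline(
                                    windows={label: (0.0, spec.window_duration)},
                                    baseline_label="baseline"),
                                seed=spec.seed)
            try:
                per_window[label] = _analyse_epoch(rec, cfg)
            except Exception as exc:
                errors.append(f"{a.animal}/{label}: {exc}")
        if set(per_window) != {"baseline", "post"}:
            continue
        rows = []
        for bname in ("low_gamma", "high_gamma"):
            post_bp = per_window["post"]["powers"][bname]
            base_bp = per_window["baseline"]["powers"][bname]
            rows.append((f"{bname}_power_pct",
                         percent_change(post_bp, base_bp).mean))
        for pair in ("theta_low_gamma", "theta_high_gamma"):
            rows.append((f"plv_{pair}", per_window["post"]["pac"][pair].plv))
            rows.append((f"plv_{pair}_baseline",
                         per_window["baseline"]["pac"][pair].plv))
        frames.append(pd.DataFrame({
            "animal": a.animal, "group": a.group,
            "metric": [m for m, _ in rows], "value": [v for _, v in rows],
            "config_hash": chash, "seed": spec.seed,
        }))
    table = pd.concat(frames, ignore_index=True)
    counts = table.drop_duplicates("animal").groupby("group").size()
    small = counts[counts < 3]
    reports: dict[str, StatReport] = {}
    lines = [f"cohort {chash} seed={spec.seed} "
             f"groups={{{', '.join(f'{g}: {int(n)}' for g, n in counts.items())}}} "
             f"epoch={spec.window_duration:.0f}s"]
    if len(small):
        warnings.warn(f"groups with n < 3 excluded from statistics: "
                      f"{list(small.index)}", stacklevel=2)
        lines.append(f"  statistics skipped for small groups: {list(small.index)}")
    usable = [g for g in counts.index if counts[g] >= 3]
    for metric in COHORT_METRICS:
        groups = {g: v for g, v in groups_from_table(table, metric).items()
                  if g in usable}
        if len(groups) < 2:
            lines.append(f"  {metric}: fewer than 2 usable groups, skipped")
            continue
        rep = analyze_metric(groups, alpha, dunn_adjust)
        reports[metric] = rep
        summ = ", ".join(f"{g}: {mean_sem(v)[0]:.3g}+/-{mean_sem(v)[1]:.3g}"
                         for g, v in groups.items())
        stat_name = "F" if rep.test.startswith("one-way") else "H"
        sig = "*" if rep.significant(alpha) else "ns"
        lines.append(f"  {metric} [{rep.gate['route']}]: {stat_name}="
                     f"{rep.statistic:.3f} p={rep.p:.4f} {sig} | {summ}")
        for ph in rep.posthoc:
            lines.append(f"    {ph['pair'][0]} vs {ph['pair'][1]}: "
                         f"p_adj={ph['p_adj']:.4f}")
    return CohortResult(table, reports, "\n".join(lines), truth, errors)
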