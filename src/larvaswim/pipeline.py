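"""End-to-end experiment orchestration.

Chains the pipeline stages — simulate -> [render -> track] -> bout
kinematics -> classification/aggregation -> genotype statistics — for a
whole cohort, and records a run manifest (config snapshot, seed, stage
list, output digests, package version) so every number in the final
report is traceable to a seed and a config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (ClassifyParams, classify_bouts, select_escape,
                       summarize_fish, summarize_cohort, category_ratio)
from .errors import ConfigError
from .io import write_table
from .kinematics import DetectionParams, analyze_trace
from .simulate import (CohortConfig, SLOW_DEFAULTS, ESCAPE_DEFAULTS,
                       generate_cohort, iter_escape_trials, iter_slow_sessions)
from .stats import ANALYSES, compare_groups, results_table

__all__ = ["run_slow_experiment", "run_escape_experiment", "merge_summaries",
           "run_pipeline", "load_config", "default_config"]


def run_slow_experiment(
    cohort: pd.DataFrame,
    duration_s: float = 300.0,
    rate: float = 100.0,
    seed: int = 0,
    detection: DetectionParams = DetectionParams(),
    classify_params: ClassifyParams = ClassifyParams(),
    use_tracker: bool = False,
    px_per_mm: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and analyse one slow-swim session per fish.

    Returns ``(bout_table, fish_summaries)``.  With ``use_tracker`` the
    traces are rendered to silhouette stacks and re-tracked before bout
    detection (slow; meant for desk-scale validation runs).
    """
    bout_tables, rows = [], []
    for fish, trace, _gt in iter_slow_sessions(cohort, duration_s, rate, seed):
        if use_tracker:
            from .render import WellGeometry, render_frames
            from .tracking import track_stack
            well = WellGeometry(px_per_mm=px_per_mm)
            frames = render_frames(trace, well, rng=0)
            trace = track_stack(frames, well=well, rate=rate)
        bouts = analyze_trace(trace, detection, rate, fish_id=fish["fish_id"])
        bouts = classify_bouts(bouts, classify_params)
        bouts.insert(1, "genotype", fish["genotype"])
        bouts.insert(1, "clutch", fish["clutch"])
        bout_tables.append(bouts)
        rows.append(summarize_fish(
            bouts, fish_id=fish["fish_id"], clutch=fish["clutch"],
            genotype=fish["genotype"], recording_duration_s=duration_s,
            params=classify_params))
    bout_table = (pd.concat(bout_tables, ignore_index=True) if bout_tables
                  else pd.DataFrame())
    return bout_table, summarize_cohort(rows)


def run_escape_experiment(
    cohort: pd.DataFrame,
    n_trials: int = 10,
    trial_len: float = 1.0,
    stim_time: float = 0.2,
    rate: float = 650.0,
    seed: int = 0,
    detection: DetectionParams = DetectionParams(),
    classify_params: ClassifyParams = ClassifyParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and analyse escape trials for a cohort.

    Returns ``(escape_table, fish_summaries)``: one row per trial with
    the selection outcome, and one row per fish with the per-fish means
    of the eight escape parameters over selected trials.
    """
    per_fish: dict[str, list] = {}
    meta: dict[str, dict] = {}
    trial_rows = []
    for fish, t, trace, _gt in iter_escape_trials(cohort, n_trials, trial_len,
                                                  stim_time, rate, seed):
        bouts = analyze_trace(trace, detection, rate,
                              fish_id=fish["fish_id"], session_id=f"trial{t}")
        bouts = bouts.assign(offset_s=bouts["offset_frame"] / rate)
        res = select_escape(bouts, stim_time, classify_params, f"trial{t}")
        fid = fish["fish_id"]
        per_fish.setdefault(fid, []).append(res)
        meta[fid] = {"clutch": fish["clutch"], "genotype": fish["genotype"]}
        row = {"fish_id": fid, "trial_id": res.trial_id,
               "selected": res.selected, "contaminated": res.contaminated,
               "latency_ms": res.latency_ms, "cbend_deg": res.cbend_deg,
               "counterbend_deg": res.counterbend_deg}
        trial_rows.append(row)
    rows = [summarize_fish(None, escapes, fish_id=fid, **meta[fid],
                           params=classify_params)
            for fid, escapes in per_fish.items()]
    return pd.DataFrame(trial_rows), summarize_cohort(rows)


def merge_summaries(slow: pd.DataFrame | None,
                    escape: pd.DataFrame | None) -> pd.DataFrame:
    """Join slow-swim and escape per-fish summaries on fish identity."""
    if slow is None:
        return escape
    if escape is None:
        return slow
    keys = ["fish_id", "clutch", "genotype"]
    return slow.merge(escape, on=keys, how="outer")


# ---------------------------------------------------------------------------
# config-driven runs


def default_config() -> dict:
    """Demo configuration: 4 clutches x 15 fish per genotype, 5-min
    slow-swim sessions at 100 Hz and 10 escape trials at 650 Hz."""
    return {
        "seed": 1,
        "cohort": {"n_clutches": 4, "fish_per_clutch_per_genotype": 15,
                   "centering": "clutch"},
        "slow": {"enabled": True, "duration_s": 300.0, "rate_hz": 100.0},
        "escape": {"enabled": True, "n_trials": 10, "trial_len_s": 1.0,
                   "stim_time_s": 0.2, "rate_hz": 650.0},
        "analyses": ["boutrate", "forward", "turn", "escape"],
        "alpha": 0.05,
    }


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config, filling unspecified sections from the demo
    defaults."""
    cfg = default_config()
    if path is not None:
        import yaml
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cohort_config(cfg: dict, seed: int) -> CohortConfig:
    cc = dict(cfg.get("cohort", {}))
    slow_over = cc.pop("slow_params", {})
    esc_over = cc.pop("escape_params", {})
    slow = {g: dataclasses.replace(p, **slow_over.get(g, {}))
            for g, p in SLOW_DEFAULTS.items()}
    escape = {g: dataclasses.replace(p, **esc_over.get(g, {}))
              for g, p in ESCAPE_DEFAULTS.items()}
    return CohortConfig(seed=seed, slow=slow, escape=escape, **cc)


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path,
                 seed: int | None = None, log=print) -> dict:
    """Run the full pipeline from a config; returns the manifest.

    Writes the cohort table, bout table, escape table, fish summaries,
    per-analysis results tables, a JSON report and ``manifest.json`` into
    ``out_dir``.
    """
    t_start = time.time()
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stages = []

    def record(stage: str, **outputs: Path):
        stages.append({"stage": stage,
                       "outputs": {str(p): _digest(p) for p in outputs.values()}})

    cohort = generate_cohort(_cohort_config(cfg, seed))
    cohort_path = out / "cohort.tsv"
    write_table(cohort, cohort_path)
    record("simulate-cohort", cohort=cohort_path)
    log(f"[cohort] {len(cohort)} fish, "
        f"{cohort['clutch'].nunique()} clutches")

    classify_params = ClassifyParams(**cfg.get("classify", {}))
    slow_summ = esc_summ = None
    counts = {"fish": int(len(cohort))}

    if cfg["slow"].get("enabled", True):
        s = cfg["slow"]
        bouts, slow_summ = run_slow_experiment(
            cohort, s.get("duration_s", 300.0), s.get("rate_hz", 100.0),
            seed=seed + 1, classify_params=classify_params,
            use_tracker=s.get("use_tracker", False))
        bouts_path = out / "bouts.tsv"
        write_table(bouts, bouts_path)
        record("slow-swim", bouts=bouts_path)
        counts["bouts"] = int(len(bouts))
        counts["qc_failed_fish"] = int((~slow_summ["qc_pass"]).sum())
        ratio = category_ratio(bouts, by="genotype")
        ratio_path = out / "category_ratio.tsv"
        write_table(ratio.reset_index(), ratio_path)
        record("category-ratio", ratio=ratio_path)
        log(f"[slow] {counts['bouts']} bouts; "
            f"{counts['qc_failed_fish']} fish failed QC")

    if cfg["escape"].get("enabled", True):
        e = cfg["escape"]
        trials, esc_summ = run_escape_experiment(
            cohort, e.get("n_trials", 10), e.get("trial_len_s", 1.0),
            e.get("stim_time_s", 0.2), e.get("rate_hz", 650.0),
            seed=seed + 2, classify_params=classify_params)
        trials_path = out / "escapes.tsv"
        write_table(trials, trials_path)
        record("escape", trials=trials_path)
        counts["escape_trials"] = int(len(trials))
        counts["escapes_selected"] = int(trials["selected"].sum())
        log(f"[escape] {counts['escapes_selected']}/{counts['escape_trials']}"
            " trials selected")

    summaries = merge_summaries(slow_summ, esc_summ)
    summ_path = out / "fish_summaries.tsv"
    write_table(summaries, summ_path)
    record("summaries", summaries=summ_path)

    report = {"seed": seed, "version": __version__, "analyses": {}}
    for analysis in cfg.get("analyses", list(ANALYSES)):
        needed = ANALYSES[analysis]
        if not set(needed) <= set(summaries.columns):
            log(f"[stats] skipping {analysis}: inputs not produced")
            continue
        results = compare_groups(summaries, analysis)
        table = results_table(results)
        path = out / f"stats_{analysis}.tsv"
        write_table(table, path)
        record(f"stats-{analysis}", results=path)
        report["analyses"][analysis] = {
            "meff": results[0].meff if results else None,
            "significant": [r.parameter for r in results
                            if r.p_adj < cfg.get("alpha", 0.05)],
        }
        log(f"[stats] {analysis}: Meff={results[0].meff:.3f}, "
            f"significant at alpha={cfg.get('alpha', 0.05)}: "
            f"{report['analyses'][analysis]['significant'] or 'none'}")

    report["counts"] = counts
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    manifest = {
        "version": __version__, "seed": seed, "config": cfg,
        "stages": stages, "counts": counts,
        "runtime_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
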