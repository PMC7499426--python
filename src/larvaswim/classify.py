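"""Bout categorisation, escape selection, QC and per-fish aggregation.

Slow-swim bouts are split into *forward swims* and *routine turns* by a
25-degree cutoff on the maximal absolute bend amplitude.  Escape trials
keep the first post-stimulus bout with latency < 30 ms and a first tail
bend above 60 degrees.  Fish are summarised by the median of each
kinematic parameter over their bouts (per category) and by the mean of
the escape parameters over their selected trials; fish with fewer than
30 bouts in the 5-min recording fail QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClassifyParams", "EscapeResult", "classify_bout", "classify_bouts",
           "select_escape", "summarize_fish", "summarize_cohort",
           "category_ratio", "SLOW_PARAMS", "ESCAPE_PARAMS"]

#: six slow-swim parameters summarised per fish and category
SLOW_PARAMS = ["distance_mm", "duration_s", "speed_mm_s", "median_bend_deg",
               "n_osc", "tbf_hz"]
#: eight escape parameters averaged per fish over selected trials
ESCAPE_PARAMS = ["distance_mm", "duration_s", "speed_mm_s", "n_osc", "tbf_hz",
                 "latency_ms", "cbend_deg", "counterbend_deg"]


@dataclass(frozen=True)
class ClassifyParams:
    """Cutoffs of the classification and escape-selection rules.

    Boundary conventions: a bout with max bend exactly at the cutoff is a
    turn (forward requires strictly less); an escape first bend exactly at
    60 degrees is not selected ("above 60" read strictly); a fish with
    exactly 30 bouts passes QC ("fewer than 30" read strictly).
    """

    cutoff_deg: float = 25.0
    escape_latency_ms: float = 30.0
    escape_bend_deg: float = 60.0
    min_bouts: int = 30


@dataclass
class EscapeResult:
    """Outcome of escape selection for one trial."""

    trial_id: str
    selected: bool
    latency_ms: float = float("nan")
    cbend_deg: float = float("nan")
    counterbend_deg: float = float("nan")
    bout: pd.Series | None = None
    contaminated: bool = False


def classify_bout(max_bend_deg: float,
                  cutoff_deg: float = 25.0) -> str:
    """``"forward"`` iff the maximal |bend| is strictly below the cutoff,
    ``"turn"`` otherwise."""
    return "forward" if max_bend_deg < cutoff_deg else "turn"


def classify_bouts(bout_table: pd.DataFrame,
                   params: ClassifyParams = ClassifyParams()) -> pd.DataFrame:
    """Append a ``category`` column to a bout table."""
    out = bout_table.copy()
    out["category"] = np.where(out["max_bend_deg"] < params.cutoff_deg,
                               "forward", "turn")
    return out


def select_escape(bouts: pd.DataFrame, stim_time_s: float,
                  params: ClassifyParams = ClassifyParams(),
                  trial_id: str = "trial0") -> EscapeResult:
    """Select the escape response of one trial.

    ``bouts`` is the trial's time-ordered bout table.  The first bout
    starting after the stimulus with latency below 30 ms and |first bend|
    above 60 degrees is selected; its latency is the bout-onset time
    minus the stimulus time, in ms.  A bout overlapping the stimulus
    marks the trial as contaminated by spontaneous motion (not selected).
    """
    for _, b in bouts.sort_values("onset_s").iterrows():
        onset = b["onset_s"]
        if onset <= stim_time_s:
            offset = b.get("offset_s", onset + b["duration_s"])
            if offset > stim_time_s:
                return EscapeResult(trial_id, False, contaminated=True)
            continue
        latency = (onset - stim_time_s) * 1000.0
        if latency >= params.escape_latency_ms:
            return EscapeResult(trial_id, False)
        if not abs(b["first_bend_deg"]) > params.escape_bend_deg:
            continue
        return EscapeResult(
            trial_id, True, latency_ms=latency,
            cbend_deg=abs(b["first_bend_deg"]),
            counterbend_deg=abs(b["second_bend_deg"]),
            bout=b,
        )
    return EscapeResult(trial_id, False)


def _escape_row(res: EscapeResult) -> dict:
    row = {"trial_id": res.trial_id, "selected": res.selected,
           "contaminated": res.contaminated}
    if res.selected:
        b = res.bout
        row.update({
            "latency_ms": res.latency_ms, "cbend_deg": res.cbend_deg,
            "counterbend_deg": res.counterbend_deg,
            "distance_mm": b["distance_mm"], "duration_s": b["duration_s"],
            "speed_mm_s": b["speed_mm_s"], "n_osc": b["n_osc"],
            "tbf_hz": b["tbf_hz"],
        })
    return row


def summarize_fish(
    bouts: pd.DataFrame | None,
    escapes: list[EscapeResult] | None = None,
    *,
    fish_id: str,
    clutch: str = "",
    genotype: str = "",
    recording_duration_s: float = 300.0,
    params: ClassifyParams = ClassifyParams(),
) -> dict:
    """Aggregate one fish: per-category medians of the slow-swim
    parameters, per-fish means of the escape parameters, QC flag.

    Fish with fewer than ``min_bouts`` slow-swim bouts fail QC; fish with
    zero selected escape trials get NaN escape fields (they drop out of
    the escape comparison only).
    """
    row: dict = {"fish_id": fish_id, "clutch": clutch, "genotype": genotype}
    if bouts is not None:
        if "category" not in bouts.columns:
            bouts = classify_bouts(bouts, params)
        row["n_bouts"] = int(len(bouts))
        row["bout_rate_hz"] = len(bouts) / recording_duration_s
        row["qc_pass"] = len(bouts) >= params.min_bouts
        for cat, pre in (("forward", "fwd"), ("turn", "turn")):
            sub = bouts[bouts["category"] == cat]
            row[f"n_{pre}"] = int(len(sub))
            for p in SLOW_PARAMS:
                row[f"{pre}_{p}"] = float(sub[p].median()) if len(sub) else np.nan
    if escapes is not None:
        selected = [r for r in escapes if r.selected]
        row["n_trials"] = len(escapes)
        row["n_selected"] = len(selected)
        tab = pd.DataFrame([_escape_row(r) for r in selected])
        for p in ESCAPE_PARAMS:
            row[f"esc_{p}"] = float(tab[p].mean()) if len(tab) else np.nan
    return row


def summarize_cohort(rows: list[dict]) -> pd.DataFrame:
    """Stack per-fish summaries into the fish-summary table."""
    return pd.DataFrame(rows)


def category_ratio(bouts_or_summaries: pd.DataFrame,
                   by: str = "genotype") -> pd.DataFrame:
    """Pooled forward/turn fractions per genotype.

    Accepts either a classified bout table carrying a ``genotype`` column
    or a fish-summary table (``n_fwd``/``n_turn`` counts of QC-passing
    fish).  Fractions sum to 1 within each group.
    """
    df = bouts_or_summaries
    if "category" in df.columns:
        counts = (df.groupby([by, "category"]).size().unstack(fill_value=0)
                  .reindex(columns=["forward", "turn"], fill_value=0))
    else:
        use = df[df["qc_pass"]] if "qc_pass" in df.columns else df
        counts = use.groupby(by)[["n_fwd", "n_turn"]].sum()
        counts.columns = ["forward", "turn"]
    total = counts.sum(axis=1)
    out = counts.div(total, axis=0)
    out.columns = ["frac_forward", "frac_turn"]
    out["n_bouts"] = total
    return out
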