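"""Categorisation, escape selection, QC and aggregation rules."""

import numpy as np
import pandas as pd
import pytest

from larvaswim import (ClassifyParams, category_ratio, classify_bout,
                       classify_bouts, select_escape, summarize_cohort,
                       summarize_fish)


def escape_bouts(rows):
    """Minimal time-ordered bout table for one escape trial."""
    df = pd.DataFrame(rows)
    df["offset_s"] = df["onset_s"] + df["duration_s"]
    return df


ESC_ROW = dict(duration_s=0.22, distance_mm=9.0, speed_mm_s=41.0,
               n_osc=8, tbf_hz=37.0, second_bend_deg=-46.0)


class TestClassifyBout:
    @pytest.mark.parametrize("max_bend,expected", [
        (10.0, "forward"),   # small symmetric bends
        (60.0, "turn"),      # large initial bend
        (25.0, "turn"),      # boundary: forward is strictly below cutoff
        (24.999, "forward"),
    ])
    def test_cutoff_rule(self, max_bend, expected):
        assert classify_bout(max_bend) == expected

    def test_partition_is_exhaustive_and_exclusive(self, mut_fish):
        from larvaswim import analyze_trace, simulate_slow_session
        trace, _ = simulate_slow_session(mut_fish, 30.0, 100.0, rng=2)
        bouts = classify_bouts(analyze_trace(trace, rate=100.0))
        assert set(bouts.category) <= {"forward", "turn"}
        assert bouts.category.notna().all()


class TestSelectEscape:
    def test_fast_large_bend_selected_with_latency(self):
        bouts = escape_bouts([dict(onset_s=0.2054, first_bend_deg=101.0,
                                   **ESC_ROW)])
        res = select_escape(bouts, 0.2)
        assert res.selected
        assert res.latency_ms == pytest.approx(5.4)
        assert res.cbend_deg == pytest.approx(101.0)
        assert res.counterbend_deg == pytest.approx(46.0)

    def test_late_bout_not_selected(self):
        bouts = escape_bouts([dict(onset_s=0.235, first_bend_deg=101.0,
                                   **ESC_ROW)])
        assert not select_escape(bouts, 0.2).selected

    def test_small_first_bend_not_selected(self):
        bouts = escape_bouts([dict(onset_s=0.205, first_bend_deg=50.0,
                                   **ESC_ROW)])
        assert not select_escape(bouts, 0.2).selected

    def test_bend_exactly_sixty_not_selected(self):
        bouts = escape_bouts([dict(onset_s=0.205, first_bend_deg=60.0,
                                   **ESC_ROW)])
        assert not select_escape(bouts, 0.2).selected

    def test_bout_overlapping_stimulus_flags_contamination(self):
        bouts = escape_bouts([
            dict(onset_s=0.15, first_bend_deg=80.0, **ESC_ROW),
            dict(onset_s=0.41, first_bend_deg=101.0, **ESC_ROW),
        ])
        res = select_escape(bouts, 0.2)
        assert not res.selected
        assert res.contaminated

    def test_selection_is_idempotent(self):
        bouts = escape_bouts([dict(onset_s=0.2054, first_bend_deg=-101.0,
                                   **ESC_ROW)])
        r1 = select_escape(bouts, 0.2)
        r2 = select_escape(bouts.sample(frac=1, random_state=0), 0.2)
        assert r1.selected and r2.selected
        assert r1.latency_ms == r2.latency_ms

    def test_counterbend_opposite_sign_on_synthetic_escapes(self, cohort):
        """On simulated escapes, the selected bout's second bend always
        opposes its first bend."""
        from larvaswim import analyze_trace, iter_escape_trials
        n = 0
        for fish, t, trace, gt in iter_escape_trials(cohort.head(3),
                                                     n_trials=5, seed=6):
            bt = analyze_trace(trace, rate=650.0)
            bt = bt.assign(offset_s=bt.offset_frame / 650.0)
            res = select_escape(bt, 0.2)
            if res.selected:
                b = res.bout
                assert np.sign(b.second_bend_deg) == -np.sign(b.first_bend_deg)
                n += 1
        assert n >= 10


class TestSummarizeFish:
    def bout_table(self, n, distances=None):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "max_bend_deg": np.full(n, 10.0),
            "distance_mm": distances if distances is not None
            else rng.uniform(0.3, 0.8, n),
            "duration_s": np.full(n, 0.27),
            "speed_mm_s": np.full(n, 2.0),
            "median_bend_deg": np.full(n, 2.8),
            "n_osc": np.full(n, 3),
            "tbf_hz": np.full(n, 11.7),
        })

    @pytest.mark.parametrize("n,qc", [(29, False), (30, True), (31, True)])
    def test_qc_boundary_at_thirty_bouts(self, n, qc):
        row = summarize_fish(self.bout_table(n), fish_id="f")
        assert row["qc_pass"] is qc

    def test_forward_median_distance(self):
        tab = self.bout_table(3, distances=np.array([0.4, 0.5, 0.9]))
        row = summarize_fish(tab, fish_id="f")
        assert row["fwd_distance_mm"] == pytest.approx(0.5)
        assert row["n_fwd"] == 3 and row["n_turn"] == 0

    def test_no_selected_escape_gives_nan_escape_fields(self):
        from larvaswim import EscapeResult
        escapes = [EscapeResult("t0", False), EscapeResult("t1", False)]
        row = summarize_fish(None, escapes, fish_id="f")
        assert row["n_selected"] == 0
        assert np.isnan(row["esc_latency_ms"])


class TestCategoryRatio:
    def test_all_forward(self):
        bouts = pd.DataFrame({"genotype": ["mut"] * 5,
                              "category": ["forward"] * 5})
        out = category_ratio(bouts)
        assert out.loc["mut", "frac_forward"] == 1.0
        assert out.loc["mut", "frac_turn"] == 0.0

    def test_printed_ratio_arithmetic(self):
        bouts = pd.DataFrame({
            "genotype": ["mut"] * 10000,
            "category": ["forward"] * 7534 + ["turn"] * 2466,
        })
        out = category_ratio(bouts)
        assert out.loc["mut", "frac_forward"] == pytest.approx(0.7534)
        assert out.loc["mut", "frac_turn"] == pytest.approx(0.2466)
        assert out.loc["mut", ["frac_forward", "frac_turn"]].sum() == 1.0

    def test_generator_ratio_matches_configured_probability(self, cohort):
        """Pooled forward fraction tracks p_forward within binomial error."""
        from larvaswim import analyze_trace, simulate_slow_session
        tables = []
        for k, (_, fish) in enumerate(
                cohort[cohort.genotype == "wt"].head(4).iterrows()):
            trace, _ = simulate_slow_session(fish, 120.0, 100.0, rng=50 + k)
            bt = classify_bouts(analyze_trace(trace, rate=100.0,
                                              fish_id=fish["fish_id"]))
            bt["genotype"] = "wt"
            tables.append(bt)
        bouts = pd.concat(tables)
        p = cohort[cohort.genotype == "wt"].head(4)["p_forward"].mean()
        out = category_ratio(bouts)
        n = out.loc["wt", "n_bouts"]
        se = np.sqrt(p * (1 - p) / n)
        assert out.loc["wt", "frac_forward"] == pytest.approx(p, abs=3 * se)
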