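"""Geometric trajectory analysis: baseline anchoring, invariances, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trajdope as td
from trajdope.cohort import CohortDesign, EffectProfile, generate_cohort, inject_effect
from trajdope.gta import (
    GtaTransformer,
    fit_baseline_stats,
    gta_transform,
    mean_trajectory_deviation,
    trend_summary,
)
from trajdope.panel import LongitudinalPanel, PanelValidationError
from trajdope.schema import AnalyteDef, Block


def two_subject_panel(values):
    """values: dict (subject, day) -> value for one analyte 'A'."""
    rows = [
        (s, "EPO" if s == "S1" else "EGH", d, "A", v, False)
        for (s, d), v in values.items()
    ]
    rec = pd.DataFrame(
        rows, columns=["subject_id", "arm", "day", "analyte", "value", "below_lod"]
    )
    schema = [AnalyteDef("A", Block.CBC, "", None, 5.0, 0.2, 0.05)]
    return LongitudinalPanel(schema=schema, records=rec)


class TestBaselineStats:
    def test_sample_sd_with_n_minus_1(self):
        panel = two_subject_panel({("S1", 0): 4.0, ("S2", 0): 6.0})
        stats = fit_baseline_stats(panel)
        assert stats.sigma["A"] == pytest.approx(np.sqrt(2.0))
        assert stats.baseline.loc["S1", "A"] == 4.0

    def test_constant_baseline_errors_unless_floored(self):
        panel = two_subject_panel({("S1", 0): 4.0, ("S2", 0): 4.0})
        with pytest.raises(PanelValidationError, match="degenerate"):
            fit_baseline_stats(panel)
        t = GtaTransformer(sd_floor=1.0).fit(panel)
        assert t.baseline_stats_.sigma["A"] == 1.0

    def test_missing_baseline_names_subject_and_analyte(self):
        panel = two_subject_panel(
            {("S1", 0): 4.0, ("S2", 0): np.nan, ("S2", 4): 5.0}
        )
        with pytest.raises(PanelValidationError, match="S2.*'A'"):
            fit_baseline_stats(panel)

    def test_recovers_generator_baseline_sd(self):
        from trajdope.cohort import baseline_sd

        schema = [AnalyteDef("A", Block.CBC, "", None, 10.0, 0.2, 0.05)]
        design = CohortDesign(n_subjects_per_arm=500, days=(0, 4), schema=schema)
        stats = fit_baseline_stats(generate_cohort(design))
        assert stats.sigma["A"] == pytest.approx(baseline_sd(schema[0]), rel=0.1)


class TestTransform:
    def test_deviation_in_baseline_sd_units(self):
        panel = two_subject_panel(
            {("S1", 0): 5.0, ("S1", 4): 7.0, ("S2", 0): 5.0 + np.sqrt(8.0)}
        )
        # sigma = sd({5, 5+sqrt(8)}) = 2
        g = GtaTransformer().fit_transform(panel)
        val = g.records.set_index(["subject_id", "day"])["value"]
        assert val[("S1", 4)] == pytest.approx(1.0)

    def test_all_baseline_samples_map_to_exact_zero(self, gta_panel):
        day0 = gta_panel.records[gta_panel.records.day == 0]["value"]
        assert (day0 == 0.0).all()

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        a=st.floats(min_value=0.01, max_value=100.0),
        b=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_affine_invariance_per_analyte(self, a, b):
        panel = two_subject_panel(
            {("S1", 0): 5.0, ("S1", 4): 7.5, ("S2", 0): 6.0, ("S2", 4): 4.0}
        )
        g0 = GtaTransformer().fit_transform(panel).records["value"].to_numpy()
        rec = panel.records.copy()
        rec["value"] = a * rec["value"] + b
        g1 = (
            GtaTransformer()
            .fit_transform(LongitudinalPanel(schema=panel.schema, records=rec))
            .records["value"]
            .to_numpy()
        )
        np.testing.assert_allclose(g1, g0, atol=1e-9)

    def test_unfitted_analyte_rejected(self, filtered_panel, default_panel):
        stats = fit_baseline_stats(filtered_panel)
        with pytest.raises(PanelValidationError, match="absent"):
            gta_transform(default_panel, stats)

    def test_exact_left_inverse_of_effect_step_without_noise(self):
        # noise_cv = 0: injecting s SD (using the fitted sigma) shifts the
        # GTA value at the matching cells to exactly s
        schema = [AnalyteDef("A", Block.CBC, "", None, 10.0, 0.3, 0.0)]
        design = CohortDesign(n_subjects_per_arm=5, days=(0, 4, 11), schema=schema)
        panel = generate_cohort(design)
        stats = fit_baseline_stats(panel)
        shifted = inject_effect(
            panel, EffectProfile("A", "EGH", {4: 0.7}), dict(stats.sigma)
        )
        g = gta_transform(shifted, stats).records
        cell = g[(g.arm == "EGH") & (g.day == 4)]["value"]
        np.testing.assert_allclose(cell, 0.7, atol=1e-12)
        rest = g[(g.arm == "EPO") | (g.day != 4)]["value"]
        np.testing.assert_allclose(rest, 0.0, atol=1e-12)


class TestTrendSummary:
    def test_mean_sd_n_per_cell(self):
        panel = two_subject_panel(
            {("S1", 0): 1.0, ("S1", 4): 1.0, ("S2", 0): 3.0, ("S2", 4): 2.0}
        )
        # group by class: day 0 pools both arms as CONTROL
        agg = trend_summary(panel, grouping="class")
        row = agg[(agg.group == "CONTROL") & (agg.day == 0)].iloc[0]
        assert row["mean"] == 2.0
        assert row["sd"] == pytest.approx(np.sqrt(2.0))
        assert row["n"] == 2

    def test_single_sample_cell_reports_sd_zero(self):
        panel = two_subject_panel({("S1", 0): 1.0, ("S1", 4): 2.5, ("S2", 0): 2.0})
        agg = trend_summary(panel, grouping="arm")
        row = agg[(agg.group == "EPO") & (agg.day == 4)].iloc[0]
        assert row["mean"] == 2.5 and row["sd"] == 0.0 and row["n"] == 1

    def test_eosinophil_fraction_rises_in_egh_arm(self, gta_panel):
        agg = trend_summary(gta_panel, grouping="arm")
        eo = agg[(agg.analyte == "EO%") & (agg.group == "EGH")]
        base = eo[eo.day == 0]["mean"].iloc[0]
        assert (eo[eo.day > 0]["mean"] > base).all()


class TestMeanTrajectoryDeviation:
    def test_identical_groups_give_zero(self, gta_panel):
        post = [(s, d) for s, d in gta_panel.sample_keys() if d > 0]
        assert mean_trajectory_deviation(gta_panel, post, post) == 0.0

    def test_uniform_offset_is_recovered_exactly(self, gta_panel):
        arms = gta_panel.arms_by_subject()
        post = [(s, d) for s, d in gta_panel.sample_keys() if d > 0]
        a = [k for k in post if arms[k[0]] == "EPO"]
        rec = gta_panel.records.copy()
        mask = rec.day > 0
        shifted = rec.copy()
        shifted.loc[mask, "value"] = rec.loc[mask, "value"] + 0.3
        g2 = td.GtaPanel(schema=gta_panel.schema, records=shifted)
        # same group keys, values offset by +0.3 in the second panel
        merged = td.GtaPanel(
            schema=gta_panel.schema,
            records=pd.concat(
                [
                    rec[[k in set(a) for k in zip(rec.subject_id, rec.day)]],
                    shifted[
                        [k in set(a) for k in zip(shifted.subject_id, shifted.day)]
                    ].assign(subject_id=lambda d: d.subject_id + "_off"),
                ]
            ).reset_index(drop=True),
        )
        b = [(s + "_off", d) for s, d in a]
        assert mean_trajectory_deviation(merged, a, b) == pytest.approx(0.3)

    def test_matches_bruteforce_loop_oracle(self, gta_panel):
        rng = np.random.default_rng(0)
        post = [(s, d) for s, d in gta_panel.sample_keys() if d > 0]
        pick = rng.permutation(len(post))
        a = [post[i] for i in pick[:15]]
        b = [post[i] for i in pick[15:30]]
        got = mean_trajectory_deviation(gta_panel, a, b)

        rec = gta_panel.records
        lookup = rec.set_index(["subject_id", "day", "analyte"])["value"]
        analytes = sorted(set(rec.analyte))
        days = sorted({d for _, d in post})
        diffs = []
        for analyte in analytes:
            for day in days:
                va = [lookup[(s, d, analyte)] for s, d in a if d == day]
                vb = [lookup[(s, d, analyte)] for s, d in b if d == day]
                if va and vb:
                    diffs.append(abs(np.mean(va) - np.mean(vb)))
        assert got == pytest.approx(np.mean(diffs), abs=1e-12)

    def test_baseline_samples_rejected(self, gta_panel):
        keys = gta_panel.sample_keys()
        with pytest.raises(PanelValidationError, match="post-baseline"):
            mean_trajectory_deviation(gta_panel, keys, keys)
        with pytest.raises(PanelValidationError, match="empty"):
            mean_trajectory_deviation(gta_panel, [], keys)


class TestEffectRecovery:
    def test_injected_shift_recovered_at_large_n(self):
        # one analyte, zero effects, inject 1.0 SD at day 4 into EGH
        schema = [AnalyteDef("A", Block.CBC, "", None, 10.0, 0.2, 0.05)]
        design = CohortDesign(n_subjects_per_arm=200, days=(0, 4, 11), schema=schema)
        panel = generate_cohort(design)
        from trajdope.cohort import baseline_sd

        shifted = inject_effect(
            panel, EffectProfile("A", "EGH", {4: 1.0}), baseline_sd(schema[0])
        )
        g = td.GtaTransformer().fit_transform(shifted).records
        cell = g[(g.arm == "EGH") & (g.day == 4)]["value"]
        se = cell.std(ddof=1) / np.sqrt(len(cell))
        assert cell.mean() == pytest.approx(1.0, abs=3 * se + 0.02)
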