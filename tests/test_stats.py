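"""Signal-detection statistics, reliability, and comparison utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prtddm.stats import (
    behavioral_summary,
    discriminability,
    group_compare,
    median_age_split,
    response_bias,
    rt_speed_contrast,
    split_half_reliability,
    symptom_correlation,
)
from prtddm.task import SubjectData


class TestResponseBias:
    def test_worked_example(self):
        want = 0.5 * np.log10((80.5 * 40.5) / (20.5 * 60.5))
        assert response_bias(80, 20, 60, 40) == pytest.approx(want, abs=1e-12)
        assert response_bias(80, 20, 60, 40) == pytest.approx(0.210, abs=5e-4)

    @given(st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_counts_are_unbiased(self, x, y):
        assert response_bias(x, y, x, y) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_counts(self):
        assert response_bias(0, 0, 0, 0) == 0.0

    def test_natural_log_option(self):
        got = response_bias(80, 20, 60, 40, base=np.e)
        assert got == pytest.approx(0.5 * np.log((80.5 * 40.5) / (20.5 * 60.5)))


class TestDiscriminability:
    def test_worked_example(self):
        want = 0.5 * np.log10((82.5 * 77.5) / (18.5 * 23.5))
        assert discriminability(82, 18, 77, 23) == pytest.approx(want, abs=1e-12)
        assert discriminability(82, 18, 77, 23) == pytest.approx(0.584, abs=5e-4)

    def test_chance_performance_is_zero(self):
        assert discriminability(50, 50, 50, 50) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_performance(self):
        assert discriminability(100, 0, 100, 0) == pytest.approx(2.303, abs=5e-4)

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(0, 100),
           st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_bias_plus_discriminability_identity(self, rc, ri, lc, li):
        # the lean terms cancel: sum depends only on the rich counts
        total = response_bias(rc, ri, lc, li) + discriminability(rc, ri, lc, li)
        want = np.log10((rc + 0.5) / (ri + 0.5))
        assert total == pytest.approx(want, abs=1e-10)


def _make_subject(rows):
    df = pd.DataFrame(rows)
    df["block"] = np.repeat([1, 2], len(df) // 2) if len(df) % 2 == 0 else 1
    df["trial"] = np.arange(1, len(df) + 1)
    df["mouth"] = "short"
    df["reward_scheduled"] = False
    df["reward"] = 0
    df["correct"] = df["response"] == df["stimulus"]
    return SubjectData("t", df)


class TestRtSpeedContrast:
    def test_uniform_accuracy_zero_interaction(self):
        rows = []
        for i in range(200):
            rows.append(
                {
                    "stimulus": "rich" if i % 2 else "lean",
                    "response": "rich" if i % 2 else "lean",
                    "rt": 0.3 + 0.002 * i,
                }
            )
        out = rt_speed_contrast(_make_subject(rows))
        assert out.loc["fast", "contrast"] == pytest.approx(0.0)
        assert out.loc["slow", "contrast"] == pytest.approx(0.0)

    def test_fast_only_bias_detected(self):
        # rich responses dominate fast trials regardless of stimulus
        rows = []
        for i in range(200):
            stim = "rich" if i % 2 else "lean"
            fast = i < 40
            resp = "rich" if fast else stim
            rows.append({"stimulus": stim, "response": resp,
                         "rt": (0.25 if fast else 0.5) + 0.001 * i})
        out = rt_speed_contrast(_make_subject(rows))
        assert out.loc["fast", "contrast"] > 0.9
        assert out.loc["slow", "contrast"] == pytest.approx(0.0, abs=1e-9)

    def test_sparse_cells_flagged(self):
        rows = [
            {"stimulus": "rich" if i % 20 else "lean", "response": "rich",
             "rt": 0.3 + 0.01 * i}
            for i in range(40)
        ]
        out = rt_speed_contrast(_make_subject(rows))
        assert not out.loc["fast", "reliable"]


class TestSplitHalfReliability:
    def test_spearman_brown_formula(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        rep = split_half_reliability(x, y)
        assert rep.spearman_brown == pytest.approx(2 * rep.r / (1 + rep.r), abs=1e-12)
        assert rep.spearman_brown >= rep.r  # boost property for r >= 0

    def test_identical_halves(self):
        x = np.arange(10.0)
        rep = split_half_reliability(x, x)
        assert rep.r == pytest.approx(1.0)
        assert rep.spearman_brown == pytest.approx(1.0)
        assert rep.icc == pytest.approx(1.0)

    def test_independent_halves_near_zero(self):
        rng = np.random.default_rng(3)
        rep = split_half_reliability(rng.normal(size=3000), rng.normal(size=3000))
        assert abs(rep.spearman_brown) < 0.1

    def test_icc_matches_pingouin_reference(self):
        rng = np.random.default_rng(5)
        subj = rng.normal(size=40)
        x = subj + rng.normal(scale=0.5, size=40)
        y = subj + 0.2 + rng.normal(scale=0.5, size=40)
        rep = split_half_reliability(x, y)
        import pingouin as pg

        long = pd.DataFrame(
            {
                "s": np.tile(np.arange(40), 2),
                "r": np.repeat(["a", "b"], 40),
                "v": np.concatenate([x, y]),
            }
        )
        want = pg.intraclass_corr(long, targets="s", raters="r", ratings="v")
        want = want.set_index("Type")
        key = "ICC(A,1)" if "ICC(A,1)" in want.index else "ICC2"
        assert rep.icc == pytest.approx(float(want.loc[key, "ICC"]), abs=1e-12)

    def test_zero_variance_flagged(self):
        rep = split_half_reliability(np.ones(5), np.arange(5.0))
        assert rep.flag == "zero variance"
        assert np.isnan(rep.r)


class TestGroupCompare:
    def test_identical_groups(self):
        out = group_compare({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out["t"] == pytest.approx(0.0, abs=1e-12)

    def test_welch_textbook_formula(self):
        x = np.array([1.1, 2.3, 0.7])
        y = np.array([2.0, 3.5, 2.9])
        out = group_compare({"a": x, "b": y})
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t_ref = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        assert out["t"] == pytest.approx(t_ref, abs=1e-10)

    def test_cohens_d_sign(self):
        out = group_compare({"hi": [3.0, 4.0, 5.0], "lo": [1.0, 2.0, 3.0]})
        assert out["cohens_d"] > 0

    def test_two_groups_required(self):
        with pytest.raises(ValueError):
            group_compare({"a": [1, 2]})


class TestSymptomCorrelation:
    def test_perfect_correlation(self):
        v = [1.0, 2.0, 3.0, 4.0]
        out = symptom_correlation(v, v)
        assert out["r"] == pytest.approx(1.0)

    def test_degenerate_flagged(self):
        out = symptom_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert out["flag"] == "degenerate variance"


class TestBehavioralSummary:
    def test_pooled_average_uses_session_counts(self, sim_subject):
        summ = behavioral_summary(sim_subject, average="pooled")
        from prtddm.stats import accuracy_counts

        rc, ri, lc, li = accuracy_counts(sim_subject.trials)
        assert summ.table.loc["average", "response_bias"] == pytest.approx(
            response_bias(rc, ri, lc, li)
        )
        assert summ.bias_change == pytest.approx(
            summ.table.loc["block2", "response_bias"]
            - summ.table.loc["block1", "response_bias"]
        )

    def test_mean_average_mode(self, sim_subject):
        summ = behavioral_summary(sim_subject, average="mean")
        want = (
            summ.table.loc["block1", "response_bias"]
            + summ.table.loc["block2", "response_bias"]
        ) / 2
        assert summ.table.loc["average", "response_bias"] == pytest.approx(want)


def test_median_age_split_ties_go_young():
    ages = np.array([15, 17, 19, 19, 24, 30])
    young = median_age_split(ages)
    assert list(young) == [True, True, True, True, False, False]
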