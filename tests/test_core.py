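"""Action-DDM equations, WFPT likelihood, and the variant lattice."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from prtddm.core import (
    ActionDDMParams,
    make_variant,
    q_update,
    subject_loglik,
    trial_latents,
    wfpt_logpdf,
)
from prtddm.task import SubjectData


# --- independent reference implementations (test-side oracles) ------------

def ref_wfpt_pdf_lower(u, v, a, z):
    """Reference WFPT density at the lower boundary.

    Deliberately independent of the package's adaptive series switching:
    fixed generous term counts, small-time series below w=2 and
    large-time series above.
    """
    if u <= 0:
        return 0.0
    w = u / a**2
    if w < 2.0:
        k = np.arange(-60, 61)
        f = np.sum((z + 2 * k) * np.exp(-((z + 2 * k) ** 2) / (2 * w)))
        f /= np.sqrt(2 * np.pi * w**3)
    else:
        k = np.arange(1, 201)
        f = np.pi * np.sum(
            k * np.exp(-(k**2) * np.pi**2 * w / 2) * np.sin(k * np.pi * z)
        )
    return f * np.exp(-v * a * z - v**2 * u / 2) / a**2


def loop_loglik(trials, p):
    """Naive trial-by-trial Python re-implementation of the likelihood."""
    qr = ql = 0.0
    total = 0.0
    for _, row in trials.iterrows():
        dq = qr - ql
        z = 1.0 / (1.0 + np.exp(-p.B_z * dq))
        s = 1.0 if row["stimulus"] == "rich" else -1.0
        v = s * p.v_intercept + p.B_v * dq
        if row["response"] != "none":
            u = row["rt"] - p.t
            if row["response"] == "rich":
                total += np.log(ref_wfpt_pdf_lower(u, -v, p.a, 1 - z))
            else:
                total += np.log(ref_wfpt_pdf_lower(u, v, p.a, z))
            r = row["reward"]
            if row["response"] == "rich":
                qr += p.alpha * (r - qr)
            else:
                ql += p.alpha * (r - ql)
    return total


class TestQUpdate:
    def test_delta_rule(self):
        assert q_update(0.2, 1, 0.5) == pytest.approx(0.6, abs=1e-12)

    @given(st.floats(0, 1), st.integers(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_zero_learning_identity(self, q, r):
        assert q_update(q, r, 0.0) == q

    @given(st.floats(0, 1), st.integers(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_q_stays_in_unit_interval(self, q, r, alpha):
        out = q_update(q, r, alpha)
        assert 0.0 <= out <= 1.0
        if q == r:
            assert out == q


class TestTrialLatents:
    def test_symmetric_values_center_start(self, base_params):
        lat = trial_latents(0.4, 0.4, base_params, "rich")
        assert lat.z_t == pytest.approx(0.5)
        assert lat.delta_q == 0.0
        assert lat.v_t == pytest.approx(base_params.v_intercept)

    def test_start_point_softmax(self):
        p = ActionDDMParams(alpha=0.1, B_v=0.0, B_z=2.0, v_intercept=1.0, a=1.0, t=0.2)
        lat = trial_latents(0.6, 0.2, p, "rich")
        assert lat.z_t == pytest.approx(1 / (1 + np.exp(-0.8)), abs=1e-10)
        assert lat.z_t == pytest.approx(0.6900, abs=1e-4)

    def test_signed_drift(self):
        p = ActionDDMParams(alpha=0.1, B_v=0.5, B_z=0.0, v_intercept=1.5, a=1.0, t=0.2)
        lat = trial_latents(0.4, 0.0, p, "rich")
        assert lat.v_t == pytest.approx(1.7, abs=1e-12)
        lat_lean = trial_latents(0.4, 0.0, p, "lean")
        assert lat_lean.v_t == pytest.approx(-1.5 + 0.2, abs=1e-12)

    def test_literal_sign_convention(self):
        p = ActionDDMParams(alpha=0.1, B_v=0.5, B_z=0.0, v_intercept=1.5, a=1.0, t=0.2)
        lat = trial_latents(0.4, 0.0, p, "lean", literal_sign=True)
        assert lat.v_t == pytest.approx(-(1.5 + 0.2), abs=1e-12)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99), st.floats(0.1, 5))
    @settings(max_examples=100, deadline=None)
    def test_bz_monotonically_biases_start(self, qr, ql, bz):
        if abs(qr - ql) < 1e-6:
            return
        lo = ActionDDMParams(alpha=0.1, B_v=0.0, B_z=bz, v_intercept=1.0, a=1.0, t=0.2)
        hi = ActionDDMParams(alpha=0.1, B_v=0.0, B_z=bz + 0.5, v_intercept=1.0, a=1.0, t=0.2)
        z_lo = trial_latents(qr, ql, lo).z_t
        z_hi = trial_latents(qr, ql, hi).z_t
        if qr > ql:
            assert z_hi > z_lo
        else:
            assert z_hi < z_lo
        assert 0.0 < z_lo < 1.0


class TestWFPT:
    def test_symmetry_at_zero_drift(self):
        for rt in (0.4, 0.7, 1.5):
            up = wfpt_logpdf(rt, "upper", 0.0, 1.2, 0.5, 0.2)
            lo = wfpt_logpdf(rt, "lower", 0.0, 1.2, 0.5, 0.2)
            assert up == pytest.approx(lo, abs=1e-12)

    @pytest.mark.parametrize(
        "v,a,z", [(0.0, 1.0, 0.5), (1.0, 1.5, 0.5), (2.0, 1.0, 0.3), (-1.5, 2.0, 0.7)]
    )
    def test_total_mass_one(self, v, a, z):
        mass = sum(
            quad(
                lambda u: np.exp(wfpt_logpdf(u + 0.0, b, v, a, z, 0.0)),
                1e-6, 30, limit=200,
            )[0]
            for b in ("upper", "lower")
        )
        assert mass == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("v,a,z", [(0.5, 0.8, 0.6), (1.0, 1.5, 0.5), (3.0, 2.5, 0.4)])
    def test_matches_reference_series(self, v, a, z):
        # density agreement with the independent fixed-term implementation
        for u in np.geomspace(0.01, 5.0, 25):
            ref = ref_wfpt_pdf_lower(u, v, a, z)
            got = np.exp(wfpt_logpdf(u, "lower", v, a, z, 0.0))
            assert got == pytest.approx(ref, abs=1e-6)

    def test_impossible_rt_is_neg_inf(self):
        assert wfpt_logpdf(0.1, "upper", 1.0, 1.0, 0.5, 0.2) == -np.inf

    def test_invalid_boundary_rejected(self):
        with pytest.raises(ValueError):
            wfpt_logpdf(0.5, "top", 1.0, 1.0, 0.5, 0.2)


class TestSubjectLoglik:
    def test_matches_naive_loop(self, sim_subject, base_params):
        got = subject_loglik(sim_subject, base_params)
        want = loop_loglik(sim_subject.trials, base_params)
        assert got == pytest.approx(want, rel=1e-9, abs=1e-7)

    def test_lesion_reduces_to_plain_ddm(self, sim_subject):
        p = ActionDDMParams(alpha=0.0, B_v=0.0, B_z=0.0, v_intercept=1.4, a=1.1, t=0.25)
        total, lat = subject_loglik(sim_subject, p, return_latents=True)
        assert (lat["z_t"] == 0.5).all()
        direct = 0.0
        for _, row in sim_subject.trials.iterrows():
            if row["response"] == "none":
                continue
            s = 1.0 if row["stimulus"] == "rich" else -1.0
            b = "upper" if row["response"] == "rich" else "lower"
            direct += wfpt_logpdf(row["rt"], b, s * 1.4, 1.1, 0.5, 0.25)
        assert total == pytest.approx(direct, rel=1e-10)

    def test_single_trial_initialization(self, base_params):
        df = pd.DataFrame(
            {
                "block": [1], "trial": [1], "stimulus": ["rich"], "mouth": ["short"],
                "reward_scheduled": [True], "response": ["rich"], "rt": [0.55],
                "correct": [True], "reward": [1],
            }
        )
        total = subject_loglik(SubjectData("one", df), base_params)
        want = wfpt_logpdf(0.55, "upper", base_params.v_intercept, base_params.a,
                           0.5, base_params.t)
        assert total == pytest.approx(want, rel=1e-12)

    def test_q_values_bounded(self, sim_subject, base_params):
        _, lat = subject_loglik(sim_subject, base_params, return_latents=True)
        assert ((lat["q_rich"] >= 0) & (lat["q_rich"] <= 1)).all()
        assert ((lat["q_lean"] >= 0) & (lat["q_lean"] <= 1)).all()

    def test_non_chronological_rejected(self, sim_subject, base_params):
        df = sim_subject.trials.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError):
            subject_loglik(df, base_params)


class TestVariants:
    def test_unknown_name_lists_valid(self):
        with pytest.raises(ValueError, match="no_value_drift"):
            make_variant("bogus")

    @pytest.mark.parametrize(
        "name,fixed", [("no_value_drift", {"B_v": 0.0}), ("no_value_start", {"B_z": 0.0}),
                       ("unweighted_drift", {"B_v": 1.0}), ("unweighted_start", {"B_z": 1.0})]
    )
    def test_nesting_equivalence(self, sim_subject, base_params, name, fixed):
        variant = make_variant(name)
        restricted = variant.constrain(base_params)
        from dataclasses import replace

        full_at_restriction = replace(base_params, **fixed)
        assert subject_loglik(sim_subject, restricted) == pytest.approx(
            subject_loglik(sim_subject, full_at_restriction), rel=1e-12
        )

    def test_shared_b_ties_weights(self, sim_subject, base_params):
        v = make_variant("shared_B")
        p = v.constrain(base_params)
        assert p.B_z == p.B_v
        # shared B at 0 is the plain DDM
        from dataclasses import replace

        zero = v.constrain(replace(base_params, B_v=0.0))
        plain = replace(base_params, B_v=0.0, B_z=0.0)
        assert subject_loglik(sim_subject, zero) == pytest.approx(
            subject_loglik(sim_subject, plain), rel=1e-12
        )
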