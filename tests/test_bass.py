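"""Closed-form Bass curves against independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from rxdiffusion.bass import (
    EXTERNAL_DOMINANT,
    INTERNAL_DOMINANT,
    adjusted_r2,
    adoption_time,
    bass_adoption_rate,
    bass_cumulative,
    classify_adoption,
    peak_time,
    BassParameters,
)

pq = st.tuples(
    st.floats(min_value=1e-3, max_value=0.3),
    st.floats(min_value=0.0, max_value=0.3),
)


def ode_cumulative(p, q, t, **kw):
    """Independent oracle: integrate dF/dt = (p + qF)(1 - F) from F(0)=0."""
    if t == 0:
        return 0.0
    sol = solve_ivp(
        lambda _, F: (p + q * F) * (1.0 - F),
        [0.0, t],
        [0.0],
        rtol=1e-10,
        atol=1e-12,
        **kw,
    )
    return float(sol.y[0, -1])


class TestCumulative:
    def test_starts_at_zero(self):
        assert bass_cumulative(0.05, 0.0, 0.0) == 0.0
        assert bass_cumulative(0.05, 0.05, 0.0) == 0.0

    def test_pure_exponential_when_q_zero(self):
        # half-life of the remaining pool: F = 1 - exp(-pt)
        assert bass_cumulative(0.1, 0.0, math.log(2) / 0.1) == pytest.approx(0.5, abs=1e-12)

    def test_equal_forces_matches_ode_oracle(self):
        # for p = q the solution is tanh(pt); checked against the ODE
        t, p = 10.0, 0.05
        expected = ode_cumulative(p, p, t)
        assert expected == pytest.approx(math.tanh(p * t), abs=1e-8)
        assert bass_cumulative(p, p, t) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("p", [1e-3, 1e-2, 0.05, 0.2])
    @pytest.mark.parametrize("q", [0.0, 0.01, 0.1, 0.3])
    def test_agrees_with_ode_on_grid(self, p, q):
        for t in (1.0, 10.0, 60.0, 300.0, 600.0):
            assert bass_cumulative(p, q, t) == pytest.approx(
                ode_cumulative(p, q, t), abs=1e-6
            )

    @settings(derandomize=True, max_examples=50)
    @given(pq=pq)
    def test_strictly_increasing_to_one(self, pq):
        p, q = pq
        # span ten characteristic times: deep into saturation but still
        # resolvable in double precision
        t = np.linspace(0, 10.0 / (p + q), 400)
        F = bass_cumulative(p, q, t)
        assert np.all(np.diff(F) > 0)
        assert F[-1] > 0.85
        assert np.all(F < 1.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bass_cumulative(0.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            bass_cumulative(-0.1, 0.1, 1.0)
        with pytest.raises(ValueError):
            bass_cumulative(0.1, 0.1, -1.0)


class TestAdoptionRate:
    def test_rate_at_onset_is_p(self):
        assert bass_adoption_rate(0.05, 0.0, 0.0) == pytest.approx(0.05)
        assert bass_adoption_rate(0.02, 0.3, 0.0) == pytest.approx(0.02)

    def test_peak_location_matches_grid_search(self):
        p, q = 0.01, 0.1
        t_star = math.log(q / p) / (p + q)  # ~20.93 months
        grid = np.arange(0, 300, 0.01)
        argmax = grid[np.argmax(bass_adoption_rate(p, q, grid))]
        assert argmax == pytest.approx(t_star, abs=0.02)
        assert peak_time(p, q) == pytest.approx(t_star)

    def test_peak_at_zero_when_external_dominant(self):
        assert peak_time(0.1, 0.05) == 0.0
        assert peak_time(0.1, 0.1) == 0.0

    def test_rate_integrates_to_one(self):
        p, q = 0.02, 0.1
        t = np.linspace(0, 2000, 200_001)
        integral = np.trapezoid(bass_adoption_rate(p, q, t), t)
        assert integral == pytest.approx(1.0, abs=1e-6)


class TestAdoptionTime:
    def test_equal_forces_closed_form(self):
        # bisection oracle frozen: ln(39)/0.1
        assert adoption_time(0.05, 0.05, 0.95) == pytest.approx(
            math.log(39) / 0.1, abs=1e-9
        )

    def test_pure_exponential(self):
        assert adoption_time(0.1, 0.0, 0.95) == pytest.approx(math.log(20) / 0.1)

    def test_small_fraction_limit(self):
        assert adoption_time(0.05, 0.1, 1e-12) == pytest.approx(0.0, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(pq=pq, f=st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_inverts_cumulative(self, pq, f):
        p, q = pq
        t_f = adoption_time(p, q, f)
        assert bass_cumulative(p, q, t_f) == pytest.approx(f, abs=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(pq=pq, f=st.sampled_from([0.5, 0.9, 0.95]))
    def test_monotone_decreasing_in_p_and_q(self, pq, f):
        p, q = pq
        t0 = adoption_time(p, q, f)
        assert adoption_time(p * 1.1, q, f) < t0
        assert adoption_time(p, q + 0.01, f) < t0

    def test_monotone_increasing_in_f(self):
        times = [adoption_time(0.01, 0.08, f) for f in (0.5, 0.9, 0.95, 0.99)]
        assert times == sorted(times)
        assert len(set(times)) == 4

    def test_domain_errors(self):
        for f in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                adoption_time(0.05, 0.05, f)


class TestAdjustedR2:
    def test_perfect_fit(self):
        y = [1.0, 2.0, 5.0, 3.0, 7.0, 4.0]
        assert adjusted_r2(y, y, k=3) == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        # direct formula: RSS = 0.01+0.01+0.04+0.04 = 0.10, TSS = 5
        # R2 = 0.98 ; adj = 1 - 0.02 * 3 / (4 - 3 - 1) -> n - k - 1 = 0
        with pytest.raises(ValueError):
            adjusted_r2(obs, pred, k=3)  # too few points for k = 3
        expected = 1.0 - (0.10 / 5.0) * (4 - 1) / (4 - 1 - 1)
        assert adjusted_r2(obs, pred, k=1) == pytest.approx(expected)

    def test_null_model_is_nonpositive(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=200)
        pred = np.full(200, obs.mean())
        assert adjusted_r2(obs, pred, k=3) == pytest.approx(0.0, abs=0.02)
        assert adjusted_r2(obs, pred, k=3) < 0  # adjusted strictly below 0

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 4))
    def test_never_exceeds_plain_r2(self, seed, k):
        rng = np.random.default_rng(seed)
        obs = rng.normal(size=30)
        pred = obs + rng.normal(scale=0.5, size=30)
        tss = np.sum((obs - obs.mean()) ** 2)
        plain = 1 - np.sum((obs - pred) ** 2) / tss
        assert adjusted_r2(obs, pred, k=k) <= plain + 1e-12

    def test_constant_observed_is_undefined(self):
        with pytest.raises(ValueError):
            adjusted_r2([2.0] * 10, [2.0] * 10, k=3)


class TestClassification:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.587, INTERNAL_DOMINANT),   # esomeprazole-like
            (3.537, EXTERNAL_DOMINANT),   # tiotropium-like
            (1.0, INTERNAL_DOMINANT),     # evenly-distributed forces pool internal
        ],
    )
    def test_ratio_threshold(self, ratio, expected):
        q = 0.05
        assert classify_adoption(ratio * q, q) == expected

    def test_parameters_carry_classification_and_ratio(self):
        params = BassParameters(p=0.02, q=0.0, m=100.0)
        assert params.pq_ratio == math.inf
        assert params.classification == EXTERNAL_DOMINANT
        with pytest.raises(ValueError):
            BassParameters(p=0.0, q=0.1, m=1.0)
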