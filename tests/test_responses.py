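"""Response-curve math: single curves, pooled multivariate responses, and
the bilinear up/down combination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellgrammar.responses import (
    BehaviorResponse,
    CurveForm,
    ResponseCurve,
    RuleTerm,
    aggregate_response,
    evaluate_behavior,
    evaluate_curve,
    hill,
)

positive = st.floats(min_value=1e-3, max_value=1e3)


class TestEvaluateCurve:
    @pytest.mark.parametrize(
        "form,half_max,power,s,expected",
        [
            ("hill", 5.0, 4.0, 5.0, 0.5),       # midpoint by construction
            ("hill", 5.0, 4.0, 0.0, 0.0),       # zero numerator
            ("hill", 5.0, 4.0, 10.0, 16.0 / 17.0),  # (10/5)^4/(1+(10/5)^4)
            ("linear_capped", 2.0, 1.0, 2.0, 0.5),
            ("linear_capped", 2.0, 1.0, 0.0, 0.0),
            ("step", 3.0, 1.0, 2.999, 0.0),
            ("step", 3.0, 1.0, 3.0, 1.0),
        ],
    )
    def test_known_values(self, form, half_max, power, s, expected):
        curve = ResponseCurve(CurveForm(form), half_max, power)
        assert evaluate_curve(curve, s) == pytest.approx(expected, rel=1e-12)

    def test_output_bounded_below_one(self):
        curve = ResponseCurve(CurveForm.HILL, 1.0, 2.0)
        assert evaluate_curve(curve, 1e12) < 1.0
        lin = ResponseCurve(CurveForm.LINEAR_CAPPED, 1.0, 1.0)
        assert evaluate_curve(lin, 1e12) < 1.0

    def test_hill_strictly_increasing(self):
        s = np.linspace(0.01, 50, 200)
        vals = hill(s, 5.0, 3.0)
        assert np.all(np.diff(vals) > 0)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            hill(-1.0, 5.0, 4.0)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            ResponseCurve(CurveForm.HILL, half_max=-5.0)
        with pytest.raises(ValueError):
            ResponseCurve(CurveForm.HILL, half_max=1.0, hill_power=0.0)

    def test_large_power_no_overflow(self):
        # (s/h)^p would overflow double precision without log-space handling
        v = hill(1e6, 1.0, 200.0)
        assert 0.999 <= v < 1.0 and np.isfinite(v)


class TestAggregateResponse:
    def test_single_term_midpoint(self):
        terms = [RuleTerm("oxygen", 5.0, 4.0)]
        assert aggregate_response(terms, {"oxygen": 5.0}) == pytest.approx(0.5)

    def test_two_terms_at_half_max_gives_two_thirds(self):
        terms = [RuleTerm("a", 2.0, 3.0), RuleTerm("b", 7.0, 1.5)]
        got = aggregate_response(terms, {"a": 2.0, "b": 7.0})
        assert got == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_zero_signals_and_empty_terms(self):
        terms = [RuleTerm("a", 2.0, 3.0)]
        assert aggregate_response(terms, {"a": 0.0}) == 0.0
        assert aggregate_response([], {}) == 0.0

    def test_missing_signal_names_it(self):
        with pytest.raises(KeyError, match="oxygen"):
            aggregate_response([RuleTerm("oxygen", 5.0, 4.0)], {"glucose": 1.0})

    def test_dead_gating_skips_live_only_terms(self):
        terms = [RuleTerm("a", 2.0, 3.0, applies_to_dead=False),
                 RuleTerm("b", 7.0, 1.5, applies_to_dead=True)]
        sig = {"a": 2.0, "b": 7.0}
        assert aggregate_response(terms, sig, dead=True) == pytest.approx(0.5)
        assert aggregate_response(terms, sig, dead=False) == pytest.approx(2 / 3)

    def test_step_term_contributes_all_or_nothing(self):
        terms = [RuleTerm("a", 2.0, 3.0, form=CurveForm.STEP)]
        assert aggregate_response(terms, {"a": 1.9}) == 0.0
        assert aggregate_response(terms, {"a": 2.1}) == pytest.approx(1.0, abs=1e-5)


def _single_up(b0, bM, half_max, power):
    return BehaviorResponse("b", base_value=b0, max_value=bM,
                            up_terms=[RuleTerm("s", half_max, power)])


class TestEvaluateBehavior:
    def test_no_signal_returns_base(self):
        resp = BehaviorResponse(
            "b", base_value=3.0, max_value=9.0, min_value=1.0,
            up_terms=[RuleTerm("u", 1.0, 2.0)], down_terms=[RuleTerm("d", 1.0, 2.0)],
        )
        assert evaluate_behavior(resp, {"u": 0.0, "d": 0.0}) == pytest.approx(3.0)

    def test_saturating_up_signal_reaches_max(self):
        resp = _single_up(1.0, 7.0, 2.0, 3.0)
        got = evaluate_behavior(resp, {"s": 2.0e6})
        assert got == pytest.approx(7.0, rel=1e-6)

    def test_printed_rule_midpoint(self):
        # saturation 0.0005 with base 0: the midpoint value is half of it
        resp = _single_up(0.0, 0.0005, 5.0, 4.0)
        assert evaluate_behavior(resp, {"s": 5.0}) == pytest.approx(0.00025)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(b0=st.floats(-5, 5), bM=st.floats(-5, 5), h=positive, p=st.floats(0.3, 8),
           s=st.floats(0, 1e3))
    def test_single_rule_reduces_to_hill_curve(self, b0, bM, h, p, s):
        resp = _single_up(b0, bM, h, p)
        expected = b0 + (bM - b0) * hill(s, h, p)
        assert evaluate_behavior(resp, {"s": s}) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(data=st.data())
    def test_bounds_monotonicity_order_independence(self, data):
        n_up = data.draw(st.integers(1, 3))
        n_down = data.draw(st.integers(0, 3))
        ups = [RuleTerm(f"u{i}", data.draw(positive), data.draw(st.floats(0.5, 6)))
               for i in range(n_up)]
        downs = [RuleTerm(f"d{i}", data.draw(positive), data.draw(st.floats(0.5, 6)))
                 for i in range(n_down)]
        b0 = data.draw(st.floats(-2, 2))
        bM = data.draw(st.floats(-2, 2))
        bm = data.draw(st.floats(-2, 2)) if downs else None
        resp = BehaviorResponse("b", b0, bM, bm, ups, downs)
        signals = {t.signal: data.draw(st.floats(0, 100)) for t in ups + downs}
        val = evaluate_behavior(resp, signals)
        lo = min([b0, bM] + ([bm] if downs else []))
        hi = max([b0, bM] + ([bm] if downs else []))
        assert lo - 1e-9 <= val <= hi + 1e-9
        # order independence
        resp_perm = BehaviorResponse("b", b0, bM, bm, ups[::-1], downs[::-1])
        assert evaluate_behavior(resp_perm, signals) == pytest.approx(val, abs=1e-14)
        # extensibility: a term whose signal is 0 changes nothing
        resp_ext = BehaviorResponse("b", b0, bM, bm,
                                    ups + [RuleTerm("extra", 1.0, 2.0)], downs)
        assert evaluate_behavior(resp_ext, {**signals, "extra": 0.0}) == \
            pytest.approx(val, abs=1e-14)

    def test_monotone_in_each_signal_direction(self):
        resp = BehaviorResponse(
            "b", base_value=1.0, max_value=5.0, min_value=0.1,
            up_terms=[RuleTerm("u", 2.0, 3.0)], down_terms=[RuleTerm("d", 1.0, 2.0)],
        )
        for d in (0.0, 0.5, 3.0):
            vals = [evaluate_behavior(resp, {"u": u, "d": d}) for u in np.linspace(0, 20, 30)]
            assert np.all(np.diff(vals) >= -1e-12)
        for u in (0.0, 2.0, 50.0):
            vals = [evaluate_behavior(resp, {"u": u, "d": d}) for d in np.linspace(0, 20, 30)]
            assert np.all(np.diff(vals) <= 1e-12)

    def test_vectorized_signals(self):
        resp = _single_up(0.0, 1.0, 2.0, 2.0)
        s = np.array([0.0, 2.0, 1e9])
        got = evaluate_behavior(resp, {"s": s})
        assert got == pytest.approx([0.0, 0.5, 1.0], abs=1e-6)
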