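import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from adaptsim import (
    Scenario,
    TwoByTwoTable,
    analyse_trial,
    evaluate_decisions,
    fit_binary_logistic,
    pims_defaults,
    run_trial,
    select_interim,
    simulate_trial_data,
)


def glm_oracle(table, ci_level=0.95):
    """IRLS logistic regression of outcome on treatment, via statsmodels.

    Encodes the 2x2 table as frequency-weighted rows, so the Wald summary
    is exactly what a per-participant glm fit would report.  Returns the
    log odds ratio, log CI bounds and p-value.
    """
    y = np.array([1.0, 0.0, 1.0, 0.0])
    x = sm.add_constant(np.array([1.0, 1.0, 0.0, 0.0]))
    w = np.array([table.a, table.b, table.c, table.d], dtype=float)
    fit = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=w).fit(
        tol=1e-12, maxiter=500
    )
    lci, uci = fit.conf_int(alpha=1 - ci_level)[1]
    return fit.params[1], lci, uci, fit.pvalues[1]


def test_symmetric_table_gives_unit_odds_ratio():
    est = fit_binary_logistic(TwoByTwoTable(a=10, b=90, c=10, d=90))
    assert est.odds_ratio == pytest.approx(1.0)
    assert est.p_value == pytest.approx(1.0)
    assert est.lci < 1.0 < est.uci
    assert not est.degenerate


def test_closed_form_matches_irls_fit_on_the_worked_table():
    """Log odds ratio, log CI bounds and p agree with IRLS to 1e-6."""
    table = TwoByTwoTable(a=12, b=280, c=30, d=262)
    est = fit_binary_logistic(table)
    log_or, log_lci, log_uci, p = glm_oracle(table)
    assert math.log(est.odds_ratio) == pytest.approx(log_or, abs=1e-6)
    assert math.log(est.lci) == pytest.approx(log_lci, abs=1e-6)
    assert math.log(est.uci) == pytest.approx(log_uci, abs=1e-6)
    assert est.p_value == pytest.approx(p, abs=1e-6)


def test_zero_cell_table_is_degenerate_never_significant():
    est = fit_binary_logistic(TwoByTwoTable(a=0, b=100, c=10, d=90))
    assert est.degenerate
    assert est.p_value == 1.0
    assert math.isnan(est.odds_ratio)


def test_empty_arm_is_an_error():
    with pytest.raises(ValueError, match="arm"):
        TwoByTwoTable(a=0, b=0, c=10, d=90)
    with pytest.raises(ValueError, match="non-negative"):
        TwoByTwoTable(a=-1, b=1, c=1, d=1)


@given(
    a=st.integers(1, 200),
    b=st.integers(1, 200),
    c=st.integers(1, 200),
    d=st.integers(1, 200),
)
def test_or_closed_form_and_label_swap_invariance(a, b, c, d):
    t = TwoByTwoTable(a=a, b=b, c=c, d=d)
    est = fit_binary_logistic(t)
    assert est.odds_ratio == pytest.approx((a / b) / (c / d))
    assert est.lci <= est.odds_ratio <= est.uci
    swapped = fit_binary_logistic(TwoByTwoTable(a=c, b=d, c=a, d=b))
    assert swapped.odds_ratio == pytest.approx(1.0 / est.odds_ratio)
    assert swapped.p_value == pytest.approx(est.p_value)


@pytest.mark.parametrize(
    "interim_p, final_p, expected",
    [
        (0.001, 0.5, (1, 0, 1, 1)),  # flip-flop: interim win not confirmed
        (0.5, 0.5, (0, 0, 0, 0)),
        (0.001, 0.001, (1, 1, 1, 0)),
        (0.5, 0.001, (0, 1, 1, 0)),
        (0.005, 0.5, (0, 0, 0, 0)),  # boundary: strict comparison
        (0.5, 0.045, (0, 0, 0, 0)),
        (None, 0.001, (0, 1, 1, 0)),  # interim never reached
    ],
)
def test_decision_rules(params, interim_p, final_p, expected):
    interim = _est(interim_p) if interim_p is not None else None
    assert evaluate_decisions(interim, _est(final_p), params) == expected


def _est(p):
    from adaptsim.analysis import EffectEstimate

    return EffectEstimate(odds_ratio=1.0, lci=0.5, uci=2.0, p_value=p)


def test_analyse_trial_result_row_algebra(params, rng):
    """stop/flipflop algebra and the sample-size rule hold for simulated trials."""
    scenario = Scenario("Larger difference", 0.10, 0.03)
    seen_interim_stop = False
    for seed in range(60):
        _, res = run_trial(params, scenario, seed)
        assert res.stop == max(res.interim_stop, res.final_stop)
        assert res.flipflop == res.interim_stop * (1 - res.final_stop)
        if res.interim_stop == 1:
            seen_interim_stop = True
            assert res.sample_size < params.n
        else:
            assert res.sample_size == params.n
        # both analyses always computed (post-processing design)
        assert not math.isnan(res.final_p)
        assert not math.isnan(res.interim_p)
    assert seen_interim_stop  # the large effect makes early stops common


def test_counts_reflect_interim_data_when_stopped_early(params):
    scenario = Scenario("Larger difference", 0.10, 0.03)
    for seed in range(200):
        data, res = run_trial(params, scenario, seed)
        if res.interim_stop == 1:
            sub = data[data["interim_flag"] == 1]
            assert res.nevents0 == sub.loc[sub["trt"] == 0, "event"].sum()
            assert res.nevents1 == sub.loc[sub["trt"] == 1, "event"].sum()
            assert res.sample_size == len(sub)
            break
    else:
        pytest.fail("no early-stopping trial found")


def test_unannotated_data_is_rejected(params, rng):
    data = simulate_trial_data(params, Scenario("Null", 0.10, 0.10), rng)
    from adaptsim.interim import InterimSelection

    with pytest.raises(ValueError, match="annotated"):
        analyse_trial(data, InterimSelection(reached=False), params)
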