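"""Sampling distributions, PSA reproducibility, CEAC properties and tornado
ordering."""

import numpy as np
import pandas as pd
import pytest

from endocea.economics import run_base_case
from endocea.parameters import DistributionSpec
from endocea.sensitivity import (
    PAYER_TORNADO_RANGES,
    SOCIETAL_TORNADO_RANGES,
    CEACCurve,
    PSAResult,
    ceac,
    one_way,
    psa_summary,
    run_psa,
    sample_parameters,
    set_parameter,
    tornado,
)


# ------------------------------------------------------------- distributions


def test_beta_moment_matching_recovers_mean():
    """Beta matched to the recurrence rate's 95% range keeps its mean."""
    spec = DistributionSpec("beta", 0.222, 0.206, 0.239, domain=(0, 1))
    rng = np.random.default_rng(0)
    draws = spec.sample(rng, size=100_000)
    assert draws.mean() == pytest.approx(0.222, abs=0.005)
    assert ((draws >= 0) & (draws <= 1)).all()


def test_lognormal_quantiles_match_published_ci():
    """The OR 0.40 spec reproduces the published 95% CI (0.2, 0.7)."""
    spec = DistributionSpec("lognormal", 0.40, 0.2, 0.7, domain=(0, np.inf))
    rng = np.random.default_rng(1)
    draws = spec.sample(rng, size=200_000)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    assert lo == pytest.approx(0.2, rel=0.10)
    assert hi == pytest.approx(0.7, rel=0.10)


def test_normal_cv_spec_sd():
    spec = DistributionSpec("normal", 0.06, cv=0.2, domain=(0, 1))
    assert spec.sd == pytest.approx(0.012)


def test_fixed_family_returns_base(mp, cp):
    dists = {"u_dys": DistributionSpec("fixed", 0.637)}
    rng = np.random.default_rng(0)
    mp2, cp2, sampled = sample_parameters(mp, cp, dists, rng)
    assert mp2 == mp
    assert sampled == {"u_dys": 0.637}


def test_unknown_family_rejected():
    with pytest.raises(ValueError):
        DistributionSpec("gamma", 1.0, cv=0.2)


def test_samples_respect_domain_truncation():
    spec = DistributionSpec("normal", 0.871, cv=0.2, domain=(0.0, 1.0))
    rng = np.random.default_rng(2)
    draws = spec.sample(rng, size=50_000)
    assert draws.max() <= 1.0
    assert draws.min() >= 0.0


# -------------------------------------------------------------------- PSA


def test_psa_reproducible_bit_identical(mp, cp, dists):
    psa1 = run_psa(mp, cp, dists, n=20, seed=123)
    psa2 = run_psa(mp, cp, dists, n=20, seed=123)
    pd.testing.assert_frame_equal(psa1.draws, psa2.draws)


def test_psa_draws_independent_of_n(mp, cp, dists):
    """Per-draw substreams: the first draws are identical whatever n is."""
    small = run_psa(mp, cp, dists, n=5, seed=9)
    large = run_psa(mp, cp, dists, n=10, seed=9)
    pd.testing.assert_frame_equal(small.draws, large.draws.iloc[:5])


def test_all_fixed_dists_equal_base_case(mp, cp):
    fixed = {"u_dys": DistributionSpec("fixed", 0.637)}
    psa = run_psa(mp, cp, fixed, n=1, seed=0)
    base_ce = run_base_case(mp, cp)["ce"]
    assert psa.draws.loc[0, "inc_cost"] == pytest.approx(base_ce.inc_cost)
    assert psa.draws.loc[0, "inc_effect"] == pytest.approx(base_ce.inc_effect)


def test_vanishing_dispersion_converges_to_base(mp, cp):
    tiny = {
        "visit_cost_dys": DistributionSpec("lognormal", 7_529.0, cv=1e-6),
        "p_recurrence": DistributionSpec("beta", 0.222, cv=1e-3, domain=(0, 1)),
    }
    psa = run_psa(mp, cp, tiny, n=30, seed=4)
    base_ce = run_base_case(mp, cp)["ce"]
    assert psa.draws["inc_cost"].mean() == pytest.approx(base_ce.inc_cost, rel=1e-3)
    assert psa.draws["inc_effect"].mean() == pytest.approx(base_ce.inc_effect, rel=1e-3)


def test_psa_requires_positive_n(mp, cp, dists):
    with pytest.raises(ValueError):
        run_psa(mp, cp, dists, n=0)


# -------------------------------------------------------------------- CEAC


def _fake_psa(inc_cost, inc_effect):
    df = pd.DataFrame(
        {
            "iteration": range(len(inc_cost)),
            "inc_cost": inc_cost,
            "inc_effect": inc_effect,
            "smv": np.zeros(len(inc_cost)),
        }
    )
    return PSAResult(draws=df, n=len(df), seed=0)


def test_ceac_all_dominant_draws():
    psa = _fake_psa([-100.0] * 10, [1.0] * 10)
    curve = ceac(psa, wtp_grid=[0, 50_000, 5_000_000])
    assert (curve.acceptance == 1.0).all()


def test_ceac_monotone_when_effect_positive(mp, cp, dists):
    psa = run_psa(mp, cp, dists, n=40, seed=11)
    assert (psa.draws["inc_effect"] > 0).all()
    curve = ceac(psa)
    assert (np.diff(curve.acceptance) >= 0).all()


def test_ceac_threshold_crossing():
    """Acceptance jumps from 0 to 1 as WTP passes the draws' common ICER."""
    psa = _fake_psa([200.0] * 5, [2.0] * 5)  # ICER = 100 everywhere
    curve = ceac(psa, wtp_grid=[50, 100, 150])
    assert list(curve.acceptance) == [0.0, 0.0, 1.0]


def test_summary_constant_draws_zero_width():
    psa = _fake_psa([500.0] * 10, [2.0] * 10)
    s = psa_summary(psa)
    lo, hi = s["inc_cost"]["percentile_ci"]
    assert lo == hi == 500.0
    assert s["inc_cost"]["sd"] == 0.0


def test_normal_ci_coverage():
    """The normal-theory CI of the mean covers a known truth ~95% of the
    time over repeated seeds."""
    truth = 10.0
    hits = 0
    reps = 300
    for rep in range(reps):
        rng = np.random.default_rng(rep)
        x = rng.normal(truth, 2.0, size=50)
        psa = _fake_psa(x, np.ones(50))
        lo, hi = psa_summary(psa)["inc_cost"]["normal_ci_of_mean"]
        hits += lo <= truth <= hi
    assert 0.90 <= hits / reps <= 0.99


# ------------------------------------------------------------------ tornado


def test_one_way_endpoints_bracket_base(mp, cp):
    entry = one_way(mp, cp, "p_cure_dys", 0.643, 0.957, outcome="icer")
    assert entry.spread > 0
    assert entry.base_within_endpoints


def test_one_way_no_pathway_zero_spread(mp, cp):
    """The incidence schedule has no pathway when the cohort starts
    symptomatic and WELL is empty."""
    entry = one_way(mp, cp, "incidence_dysmenorrhea", 0.0008, 0.007, outcome="icer")
    assert entry.spread == pytest.approx(0.0, abs=1e-9)


def test_one_way_invalid_inputs(mp, cp):
    with pytest.raises(KeyError, match="not_a_parameter"):
        one_way(mp, cp, "not_a_parameter", 0.1, 0.2)
    with pytest.raises(ValueError):
        one_way(mp, cp, "p_cure_dys", 0.9, 0.1)


def test_tornado_sorted_and_order_invariant(mp, cp):
    ranges = {k: PAYER_TORNADO_RANGES[k] for k in list(PAYER_TORNADO_RANGES)[:4]}
    shuffled = dict(reversed(list(ranges.items())))
    t1 = tornado(mp, cp, ranges, outcome="icer")
    t2 = tornado(mp, cp, shuffled, outcome="icer")
    assert [e.parameter for e in t1] == [e.parameter for e in t2]
    spreads = [e.spread for e in t1]
    assert spreads == sorted(spreads, reverse=True)


def test_default_range_sets_have_published_cardinality(mp, cp):
    assert len(PAYER_TORNADO_RANGES) == 10
    assert len(SOCIETAL_TORNADO_RANGES) == 7


def test_degenerate_ranges_zero_spread(mp, cp):
    entries = tornado(mp, cp, {"p_cure_dys": (0.8, 0.8), "u_dys": (0.637, 0.637)})
    assert all(e.spread == pytest.approx(0.0, abs=1e-9) for e in entries)


def test_single_range_single_entry(mp, cp):
    entries = tornado(mp, cp, {"discount_rate": (0.01, 0.05)}, outcome="smv")
    assert len(entries) == 1
    assert entries[0].parameter == "discount_rate"


def test_widest_payer_bar_is_intervention_cure_rate(mp, cp):
    """The published headline: the dysmenorrhea cure rate under intervention
    dominates the payer-perspective tornado."""
    entries = tornado(mp, cp, outcome="icer")
    assert entries[0].parameter == "p_cure_dys"
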