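"""Markov engine: conservation, absorption, dominance, matrix-power oracle
and an individual-level microsimulation cross-check."""

import dataclasses

import numpy as np
import pytest

from endocea.cohort import (
    HealthState,
    ModelConstructionError,
    Strategy,
    build_transition_matrix,
    cumulative_endometriosis,
    microsimulate,
    prevalence_counts,
    run_cohort,
    transition_matrices,
)
from endocea.parameters import AgeSchedule, ModelParameters
from endocea.synthetic import make_population

WELL, DYS, E12, E34, CURED, DEAD = (
    HealthState.WELL,
    HealthState.DYSMENORRHEA,
    HealthState.ENDO_I_II,
    HealthState.ENDO_III_IV,
    HealthState.CURED,
    HealthState.DEAD,
)

ZERO_MORT = AgeSchedule(((0.0, 0.0),))
FLAT = lambda v: AgeSchedule(((0.0, v),))  # noqa: E731


@pytest.mark.parametrize("strategy", list(Strategy))
def test_rows_sum_to_one_every_age(mp, strategy):
    P, _ = transition_matrices(mp, strategy)
    assert np.allclose(P.sum(axis=2), 1.0, atol=1e-12)
    assert (P >= 0).all() and (P <= 1).all()


def test_dysmenorrhea_row_uses_published_progression(mp):
    """The annual progression input is 18.4%, reduced on the hazard scale by
    the OR 0.40 under intervention (before within-cycle competition)."""
    assert mp.p_progress_dys_to_endo12 == 0.184
    P_sc = build_transition_matrix(mp, Strategy.SELF_CARE, 12)
    P_in = build_transition_matrix(mp, Strategy.INTERVENTION, 12)
    # under competition the realized one-cycle entry is below the marginal one
    assert 0 < P_in[DYS, E12] < P_sc[DYS, E12] <= 0.184
    # hazard-scale effect: log-survival ratio of the progression channel
    # equals the OR where competition is removed
    quiet = dataclasses.replace(
        mp, p_cure_dys=0.0, p_selfcare_remission_dys=0.0, mortality=ZERO_MORT
    )
    p_sc = build_transition_matrix(quiet, Strategy.SELF_CARE, 12)[DYS, E12]
    p_in = build_transition_matrix(quiet, Strategy.INTERVENTION, 12)[DYS, E12]
    assert p_sc == pytest.approx(0.184, abs=1e-12)
    assert np.log1p(-p_in) / np.log1p(-p_sc) == pytest.approx(0.40, rel=1e-10)


def test_age_outside_range_rejected(mp):
    with pytest.raises(ModelConstructionError):
        build_transition_matrix(mp, Strategy.SELF_CARE, 60)


def test_initialization(mp):
    trace = run_cohort(mp, Strategy.SELF_CARE)
    assert trace.occupancy[0, DYS] == 1.0
    assert trace.occupancy[0].sum() == 1.0
    well_start = dataclasses.replace(mp, start_state="WELL")
    trace = run_cohort(well_start, Strategy.SELF_CARE)
    assert trace.occupancy[0, WELL] == 1.0


def test_no_disease_flow_without_incidence(mp):
    quiet = dataclasses.replace(
        mp, start_state="WELL", incidence_dysmenorrhea=FLAT(0.0)
    )
    trace = run_cohort(quiet, Strategy.SELF_CARE)
    well_dead = trace.occupancy[:, [WELL, DEAD]].sum(axis=1)
    assert np.allclose(well_dead, 1.0, atol=1e-12)


def test_conservation_without_mortality(mp):
    immortal = dataclasses.replace(mp, mortality=ZERO_MORT)
    for strategy in Strategy:
        trace = run_cohort(immortal, strategy)
        alive = trace.occupancy[:, :DEAD].sum(axis=1)
        assert np.allclose(alive, 1.0, atol=1e-12)


@pytest.mark.parametrize("strategy", list(Strategy))
def test_death_is_absorbing_and_monotone(mp, strategy):
    trace = run_cohort(mp, strategy)
    dead = trace.occupancy[:, DEAD]
    assert (np.diff(dead) >= -1e-15).all()
    assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)


def test_intervention_dominates_on_endometriosis(mp, trace_sc, trace_int):
    """With both ORs < 1 the intervention's cumulative onset is below the
    self-care one at every cycle."""
    cum_sc = trace_sc.events["endo_onset"].cumsum().to_numpy()
    cum_int = trace_int.events["endo_onset"].cumsum().to_numpy()
    assert (cum_int <= cum_sc + 1e-15).all()
    assert cumulative_endometriosis(trace_int) < cumulative_endometriosis(trace_sc)


def test_zero_progression_gives_zero_onset(mp):
    none = dataclasses.replace(mp, p_progress_dys_to_endo12=0.0)
    trace = run_cohort(none, Strategy.SELF_CARE)
    assert cumulative_endometriosis(trace) == 0.0
    assert trace.occupancy[:, [E12, E34]].sum() == 0.0


def test_single_channel_entry_matches_annual_probability(mp):
    """With no competing exits the one-cycle ENDO entry equals the published
    18.4% exactly, so half the mass yields 0.092 new cases."""
    quiet = dataclasses.replace(
        mp, p_cure_dys=0.0, p_selfcare_remission_dys=0.0, mortality=ZERO_MORT
    )
    trace = run_cohort(quiet, Strategy.SELF_CARE)
    assert trace.events.loc[0, "endo_onset"] == pytest.approx(0.184, abs=1e-12)
    assert 0.5 * trace.events.loc[0, "endo_onset"] == pytest.approx(0.092, abs=1e-12)


def test_matrix_power_oracle(mp):
    """With age-constant inputs the recursion must equal the matrix power."""
    flat = dataclasses.replace(
        mp,
        mortality=FLAT(0.0003),
        incidence_dysmenorrhea=FLAT(0.004),
        visit_prop_endo=FLAT(0.02),
        visit_prop_dys=FLAT(0.2),
    )
    for strategy in Strategy:
        P, _ = transition_matrices(flat, strategy)
        assert np.allclose(P, P[0])  # age-constant indeed
        trace = run_cohort(flat, strategy)
        v0 = trace.occupancy[0]
        for k in (1, 5, 23):
            expected = v0 @ np.linalg.matrix_power(P[0], k)
            assert np.allclose(trace.occupancy[k], expected, atol=1e-13)


def test_first_onset_never_exceeds_one(mp, trace_sc):
    assert 0.0 < cumulative_endometriosis(trace_sc) <= 1.0
    naive = trace_sc.endo_naive
    assert (np.diff(naive) <= 1e-15).all()  # naive pool only shrinks


@pytest.mark.parametrize("strategy", list(Strategy))
def test_microsimulation_cross_check(mp, strategy):
    """A seeded individual-level simulation reproduces the deterministic
    occupancy within 3 Monte-Carlo standard errors."""
    n = 100_000
    sim = microsimulate(mp, strategy, n=n, seed=7)
    det = run_cohort(mp, strategy).occupancy
    se = np.sqrt(np.clip(det * (1 - det), 0, None) / n)
    assert (np.abs(sim - det) <= 3 * se + 1e-9).all()


def test_prevalence_scaling(trace_sc, pop):
    df, total = prevalence_counts(trace_sc, pop)
    # scaling identity per age
    age0 = int(trace_sc.ages[0])
    expected = df.loc[df.age == age0, "prevalence"].iloc[0] * pop.count(age0, age0)
    assert df.loc[df.age == age0, "count"].iloc[0] == pytest.approx(expected)
    assert total == pytest.approx(df["count"].sum())
    assert total > 0


def test_prevalence_missing_age_errors(trace_sc):
    small = make_population(age_groups=[(12, 20)])
    with pytest.raises(KeyError):
        prevalence_counts(trace_sc, small)


def test_trace_export_is_tidy(trace_sc):
    df = trace_sc.to_frame()
    assert set(df.columns) == {"cycle", "age", "strategy", "state", "occupancy"}
    assert len(df) == (trace_sc.horizon + 1) * 6
    per_cycle = df.groupby("cycle")["occupancy"].sum()
    assert np.allclose(per_cycle, 1.0, atol=1e-12)
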