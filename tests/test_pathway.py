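"""Unit and property tests for the six-state repair kinetics model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dpcrepair import (
    Condition,
    PathwayState,
    RateSet,
    STATE_ORDER,
    StateDistribution,
    build_generator,
    population_summary,
    propagate_exact,
    simulate_gillespie,
)
from dpcrepair.pathway import crosslink_present, k48_tagged, k63_tagged

from conftest import random_condition, random_rateset


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())


class TestStatePredicates:
    def test_crosslink_present_only_before_proteolysis(self):
        expect = {
            PathwayState.NASCENT: True,
            PathwayState.K63_TAGGED: True,
            PathwayState.K48_K63_TAGGED: True,
            PathwayState.PROTEOLYZED: False,
            PathwayState.NER_REPAIRED: False,
            PathwayState.HR_REPAIRED: False,
        }
        assert {s: crosslink_present(s) for s in STATE_ORDER} == expect

    def test_k48_states_are_subset_of_k63_states(self):
        for s in STATE_ORDER:
            if k48_tagged(s):
                assert k63_tagged(s)


class TestBuildGenerator:
    def test_stall_condition_has_single_transition(self):
        """Without NER and without a homologous donor, the only open move is
        the initial K63 tagging — the lesion stalls there."""
        gen = build_generator(
            RateSet(), Condition(ner_functional=False, donor="heterologous")
        )
        off = gen.matrix - np.diag(np.diag(gen.matrix))
        nz = np.argwhere(off > 0)
        assert nz.tolist() == [[PathwayState.NASCENT.value,
                                PathwayState.K63_TAGGED.value]]

    def test_ner_chain_well_formed(self):
        gen = build_generator(
            RateSet(
                k63_rate=1, k48_rate=1, proteolysis_rate=1,
                ner_excision_rate=1, hr_rate=1,
            ),
            Condition(ner_functional=True, donor="none"),
        )
        q = gen.matrix
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        off = q - np.diag(np.diag(q))
        assert int((off > 0).sum()) == 4  # linear 4-step chain, no HR branch

    def test_sprtn_toggle_never_changes_rates(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            rates, cond = random_rateset(rng), random_condition(rng)
            a = build_generator(rates, cond)
            b = build_generator(
                rates,
                Condition(**{**cond.__dict__, "sprtn_deficient": not cond.sprtn_deficient}),
            )
            np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_condition_gates(self):
        rates = RateSet()
        hr = build_generator(rates, Condition(ner_functional=False, donor="homologous"))
        assert hr.rate(PathwayState.K63_TAGGED, PathwayState.HR_REPAIRED) == rates.hr_rate
        assert hr.rate(PathwayState.K63_TAGGED, PathwayState.K48_K63_TAGGED) == 0.0
        b02 = build_generator(
            rates,
            Condition(ner_functional=False, donor="homologous", rad51_inhibited=True),
        )
        assert b02.rate(PathwayState.K63_TAGGED, PathwayState.HR_REPAIRED) == \
            pytest.approx(rates.hr_rate * rates.b02_factor)
        r341 = build_generator(rates, Condition(ogg1_variant="R341"))
        assert r341.rate(PathwayState.NASCENT, PathwayState.K63_TAGGED) == \
            pytest.approx(rates.k63_rate * rates.k341r_ub_factor)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            RateSet(k63_rate=-1.0)
        with pytest.raises(ValueError):
            RateSet(b02_factor=1.5)


class TestPropagateExact:
    def test_zero_time_is_identity(self, nascent):
        gen = build_generator(RateSet(), Condition())
        out = propagate_exact(gen, 0.0, nascent)
        np.testing.assert_allclose(out.occupancy, nascent.occupancy)

    def test_two_state_chain_matches_exponential_decay(self, stall_condition):
        """Stalled chain: p(K63, t) = 1 - exp(-k63 t), closed form."""
        rates = RateSet(k63_rate=0.9)
        gen = build_generator(rates, stall_condition)
        init = StateDistribution.point_mass(PathwayState.NASCENT)
        for t in (0.1, 0.7, 2.0, 5.0):
            out = propagate_exact(gen, t, init)
            assert out.fraction(PathwayState.K63_TAGGED) == \
                pytest.approx(1.0 - np.exp(-0.9 * t), abs=1e-12)

    def test_stalled_chain_converges_to_k63(self, stall_condition, nascent):
        gen = build_generator(RateSet(), stall_condition)
        out = propagate_exact(gen, 1e4 / RateSet().k63_rate, nascent)
        assert out.fraction(PathwayState.K63_TAGGED) == pytest.approx(1.0, abs=1e-6)
        assert population_summary(out).repaired_fraction == 0.0

    def test_equal_rate_chain_matches_poisson_stages(self, ner_condition, nascent):
        """With all four NER-chain rates equal to lam, the state index at time
        t is a Poisson(lam*t) count censored at 4; the absorbing state follows
        the Erlang(4, lam) CDF. Independent oracle: scipy gamma/poisson."""
        lam = 1.3
        rates = RateSet(
            k63_rate=lam, k48_rate=lam, proteolysis_rate=lam, ner_excision_rate=lam,
        )
        gen = build_generator(rates, ner_condition)
        for t in (0.3, 1.0, 2.5):
            out = propagate_exact(gen, t, nascent)
            mu = lam * t
            for j, state in enumerate(STATE_ORDER[:4]):
                assert out.fraction(state) == pytest.approx(
                    sps.poisson.pmf(j, mu), abs=1e-9
                )
            assert out.fraction(PathwayState.NER_REPAIRED) == pytest.approx(
                sps.gamma.cdf(t, a=4, scale=1 / lam), abs=1e-9
            )

    def test_distinct_rate_hr_chain_matches_hypoexponential(self, hr_condition, nascent):
        """Repaired fraction of the two-step HR chain equals the
        hypoexponential CDF 1 - (k2 e^{-k1 t} - k1 e^{-k2 t})/(k2 - k1)."""
        k1, k2 = 1.8, 0.6
        gen = build_generator(RateSet(k63_rate=k1, hr_rate=k2), hr_condition)
        for t in (0.5, 1.0, 3.0):
            out = propagate_exact(gen, t, nascent)
            expect = 1.0 - (k2 * np.exp(-k1 * t) - k1 * np.exp(-k2 * t)) / (k2 - k1)
            assert out.fraction(PathwayState.HR_REPAIRED) == pytest.approx(
                expect, abs=1e-10
            )

    def test_rejects_bad_time(self, nascent):
        gen = build_generator(RateSet(), Condition())
        with pytest.raises(ValueError):
            propagate_exact(gen, float("nan"), nascent)
        with pytest.raises(ValueError):
            propagate_exact(gen, -1.0, nascent)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), t=st.floats(0.0, 20.0))
    def test_probability_conserved_and_monotone(self, seed, t):
        """Propagation conserves probability; repaired and removed fractions
        never decrease in time (both are absorbing-set masses)."""
        rng = np.random.default_rng(seed)
        gen = build_generator(random_rateset(rng), random_condition(rng))
        init = StateDistribution.point_mass(PathwayState.NASCENT)
        grid = np.linspace(0.0, max(t, 1e-3), 8)
        prev_rep, prev_rem = -1.0, -1.0
        for tk in grid:
            out = propagate_exact(gen, float(tk), init)
            assert abs(out.occupancy.sum() - 1.0) < 1e-9
            s = population_summary(out)
            assert s.repaired_fraction >= prev_rep - 1e-12
            assert s.removed_fraction >= prev_rem - 1e-12
            prev_rep, prev_rem = s.repaired_fraction, s.removed_fraction


class TestGillespie:
    def test_all_rates_zero_stays_nascent(self, nascent):
        gen = build_generator(
            RateSet(k63_rate=0, k48_rate=0, proteolysis_rate=0,
                    ner_excision_rate=0, hr_rate=0),
            Condition(),
        )
        out = simulate_gillespie(gen, 5.0, 500, seed=3)
        assert out.occupancy[PathwayState.NASCENT.value] == 500

    def test_same_seed_reproduces_counts(self):
        gen = build_generator(RateSet(), Condition(ner_functional=True))
        a = simulate_gillespie(gen, 1.0, 2000, seed=42)
        b = simulate_gillespie(gen, 1.0, 2000, seed=42)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_counts_sum_to_population(self):
        gen = build_generator(RateSet(), Condition(donor="homologous"))
        out = simulate_gillespie(gen, 2.0, 777, seed=0)
        assert out.occupancy.sum() == 777

    def test_matches_matrix_exponential(self, nascent):
        """Stochastic counts agree with exact propagation (the oracle) in
        total-variation distance at n = 10,000."""
        rng = np.random.default_rng(2024)
        for _ in range(3):
            gen = build_generator(random_rateset(rng), random_condition(rng))
            exact = propagate_exact(gen, 1.0, nascent)
            emp = simulate_gillespie(gen, 1.0, 10_000, rng)
            assert tv_distance(exact.fractions, emp.fractions) < 0.02

    def test_mg132_toggle_is_noop_without_ner(self):
        """With NER absent the chain never reaches the proteolysis step, so
        proteasome inhibition cannot change anything (same seed, same counts)."""
        rates = RateSet()
        for drug in (False, True):
            cond = Condition(ner_functional=False, donor="homologous",
                             proteasome_inhibited=drug)
            out = simulate_gillespie(build_generator(rates, cond), 2.0, 3000, seed=9)
            if drug:
                np.testing.assert_array_equal(out.occupancy, ref)
            else:
                ref = out.occupancy


class TestPopulationSummary:
    @pytest.mark.parametrize(
        "fractions, expect",
        [
            ({PathwayState.NASCENT: 1.0},
             dict(repaired=0, removed=0, pan=0, k48=0, k63=0)),
            ({PathwayState.PROTEOLYZED: 1.0},
             dict(repaired=0, removed=1, pan=0, k48=0, k63=0)),
            ({PathwayState.K63_TAGGED: 0.5, PathwayState.HR_REPAIRED: 0.5},
             dict(repaired=0.5, removed=0.5, pan=0.5, k48=0, k63=0.5)),
            ({PathwayState.K48_K63_TAGGED: 1.0},
             dict(repaired=0, removed=0, pan=1, k48=1, k63=1)),
        ],
    )
    def test_summary_fractions(self, fractions, expect):
        s = population_summary(StateDistribution.from_fractions(fractions))
        assert s.repaired_fraction == pytest.approx(expect["repaired"])
        assert s.removed_fraction == pytest.approx(expect["removed"])
        assert s.pan_ub_fraction == pytest.approx(expect["pan"])
        assert s.k48_fraction == pytest.approx(expect["k48"])
        assert s.k63_fraction == pytest.approx(expect["k63"])
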