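"""Trial simulation: matching contract, endpoint identities, scenarios."""

import numpy as np
import pytest

from sctrials.assessment import benchmark_inclusion
from sctrials.models.reference import (
    BiasedOraclePredictor,
    NoisyOraclePredictor,
    OraclePredictor,
)
from sctrials.simulation import (
    MatchingError,
    MatchTolerances,
    ScenarioError,
    TrialSimulation,
)

from conftest import make_pair


def _crafted_pool():
    """Small pool with controlled covariates for matching-rule checks."""
    spec = [
        ("A1", 50.0, "female", "C5", "B"),
        ("A2", 54.0, "female", "C7", "B"),  # eligible for A1
        ("A3", 56.0, "female", "C5", "B"),  # age gap 6 from A1
        ("A4", 50.0, "male", "C5", "B"),    # sex mismatch with A1
        ("A5", 50.0, "female", "T4", "B"),  # NLI gap > 2 from A1
        ("A6", 50.0, "female", "C5", "C"),  # AIS mismatch with A1
    ]
    records = []
    for pid, age, sex, nli, ais in spec:
        rec = make_pair(pid=pid, ais=ais, nli=nli)
        rec.age_at_injury = age
        rec.sex = sex
        records.append(rec)
    return benchmark_inclusion(records)


class TestTolerances:
    def test_negative_tolerances_rejected(self):
        with pytest.raises(ValueError):
            MatchTolerances(age_years=-1)

    def test_eligibility_rules(self):
        sim = TrialSimulation(_crafted_pool(), OraclePredictor())
        pid = {sim.pool[i].patient_id: i for i in range(len(sim.pool))}
        assert sim.pair_within_tolerance(pid["A1"], pid["A2"])  # all within
        assert not sim.pair_within_tolerance(pid["A1"], pid["A3"])  # age 6 > 5
        assert not sim.pair_within_tolerance(pid["A1"], pid["A4"])  # sex exact
        assert not sim.pair_within_tolerance(pid["A1"], pid["A5"])  # NLI 9 > 2
        assert not sim.pair_within_tolerance(pid["A1"], pid["A6"])  # AIS exact

    def test_unmatchable_members_are_not_drawable(self):
        sim = TrialSimulation(_crafted_pool(), OraclePredictor())
        pid = {sim.pool[i].patient_id: i for i in range(len(sim.pool))}
        # A1 and A2 match each other; the rest have no counterpart at all
        assert sim.matchable[pid["A1"]] and sim.matchable[pid["A2"]]
        assert not sim.matchable[pid["A4"]]


@pytest.fixture(scope="module")
def oracle_sim(small_instances):
    return TrialSimulation(small_instances, OraclePredictor())


class TestDraw:
    def test_draw_with_replacement_exceeds_pool(self, oracle_sim):
        rng = np.random.default_rng(0)
        drawn = oracle_sim.draw_control(400, rng)
        assert len(drawn) == 400 and len(set(drawn.tolist())) <= len(oracle_sim.pool)

    def test_pure_ais_a_mix(self, oracle_sim):
        rng = np.random.default_rng(1)
        drawn = oracle_sim.draw_control(50, rng, ais_mix={"A": 1.0})
        assert (oracle_sim.ais[drawn] == 0).all()

    def test_same_seed_same_cohort(self, oracle_sim):
        d1 = oracle_sim.draw_control(30, np.random.default_rng(7))
        d2 = oracle_sim.draw_control(30, np.random.default_rng(7))
        assert np.array_equal(d1, d2)

    def test_impossible_mix_raises(self):
        pool = [i for i in _crafted_pool() if i.early.ais == "B"]
        sim = TrialSimulation(pool, OraclePredictor())
        with pytest.raises(ScenarioError):
            sim.draw_control(10, np.random.default_rng(0), ais_mix={"D": 1.0})


class TestReplicates:
    def test_oracle_synthetic_delta_is_exactly_zero(self, oracle_sim):
        for k in range(20):
            rep = oracle_sim.run_replicate(40, np.random.default_rng(k))
            assert rep.delta_lems_synthetic == 0.0
            assert rep.tolerance_violations == 0

    def test_twin_pool_with_zero_tolerance_gives_zero_randomized_delta(self):
        records = []
        for i in range(12):
            for twin in ("a", "b"):
                rec = make_pair(pid=f"T{i}{twin}", ais="C", nli="C6", caudal_motor=2)
                rec.age_at_injury = 40.0 + i
                records.append(rec)
        pool = benchmark_inclusion(records)
        sim = TrialSimulation(
            pool, OraclePredictor(), tolerances=MatchTolerances(0.0, 0)
        )
        rep = sim.run_replicate(12, np.random.default_rng(0))
        assert rep.delta_lems_randomized == 0.0

    def test_constant_bias_shifts_synthetic_delta_by_ten_k(self, small_instances):
        k = 0.3
        sim = TrialSimulation(small_instances, BiasedOraclePredictor(bias=k))
        rep = sim.run_replicate(40, np.random.default_rng(4))
        assert rep.delta_lems_synthetic == pytest.approx(-10 * k)

    def test_treatment_effect_shifts_both_deltas_linearly(self, small_instances):
        tau = 2.5
        sim = TrialSimulation(small_instances, NoisyOraclePredictor(0.5, seed=1))
        base = sim.run_replicate(40, np.random.default_rng(9))
        shifted = sim.run_replicate(
            40, np.random.default_rng(9), treatment_effect=tau
        )
        assert shifted.delta_lems_randomized == pytest.approx(
            base.delta_lems_randomized + tau
        )
        assert shifted.delta_lems_synthetic == pytest.approx(
            base.delta_lems_synthetic + tau
        )

    def test_matching_failure_names_the_member(self):
        pool = _crafted_pool()
        sim = TrialSimulation(pool, OraclePredictor())
        lone = [i for i in range(len(sim.pool))
                if sim.pool[i].patient_id == "A4"]
        with pytest.raises(MatchingError, match="NLI C5"):
            sim.match_zero_treatment(np.array(lone), np.random.default_rng(0))


class TestRepeatAndSweep:
    def test_repeat_is_reproducible_and_complete(self, oracle_sim):
        s1 = oracle_sim.repeat(n_trials=25, size=30, seed=5)
        s2 = oracle_sim.repeat(n_trials=25, size=30, seed=5)
        assert s1.replicates.equals(s2.replicates)
        assert len(s1.replicates) == 25 and s1.failures == 0
        assert (s1.replicates["delta_synthetic"] == 0).all()

    def test_randomized_spread_shrinks_with_cohort_size(self, small_instances):
        sim = TrialSimulation(small_instances, OraclePredictor())
        sd = {
            n: sim.repeat(n_trials=60, size=n, seed=2)
            .replicates["delta_randomized"].std()
            for n in (20, 80)
        }
        assert sd[80] < sd[20]

    def test_summary_table_shape(self, oracle_sim):
        summ = oracle_sim.repeat(n_trials=10, size=20, seed=0)
        table = summ.summary()
        assert set(table["control_type"]) == {"randomized", "synthetic"}
        assert (table["p95"] >= table["median"]).all()

    def test_scenario_sweep_is_tidy(self, small_instances):
        sim = TrialSimulation(small_instances, NoisyOraclePredictor(0.5, seed=3))
        table = sim.scenario_sweep(
            sizes=(20, 40), ais_mixes={"emsci": None},
            plegia_options=("tetraplegia",), n_trials=15, size=20, seed=0,
        )
        assert set(table["scenario_kind"]) == {"size", "ais_mix", "plegia"}
        by_kind = table[table["scenario_kind"] == "size"]
        assert len(by_kind) == 4  # 2 sizes x 2 control types
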