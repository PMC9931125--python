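"""Truth-table compliance, annealing sampler, and ensemble assembly."""

import numpy as np
import pytest

from moanet import (
    ActivityProfile,
    SolutionWeights,
    TrainingConfig,
    TruthTableRule,
    ValidationError,
    build_ensemble,
    network_from_edges,
    rule_complied,
    sample_solution,
    solution_accuracy,
    write_ensemble,
    load_ensemble,
)
from moanet.training import RuleEngine, effective_rules, random_weights


def profile_of(**activities):
    return ActivityProfile(activities)


class TestRuleCompliance:
    def test_majority_with_margin_complies(self):
        rule = TruthTableRule("r", (("S", 1),), (("X", 1), ("Y", -1)))
        assert rule_complied(profile_of(S=1, X=0.6, Y=-0.2), rule, f=0.5, epsilon=0.1)

    def test_all_below_magnitude_fails(self):
        rule = TruthTableRule("r", (("S", 1),), (("X", 1), ("Y", -1)))
        assert not rule_complied(profile_of(S=1, X=0.05, Y=-0.05), rule)

    def test_boundary_magnitude_inclusive(self):
        rule = TruthTableRule("r", (("S", 1),), (("X", 1),))
        assert rule_complied(profile_of(S=1, X=0.1), rule, epsilon=0.1)

    def test_exact_half_fraction_not_enough(self):
        rule = TruthTableRule("r", (("S", 1),), (("X", 1), ("Y", -1)))
        assert not rule_complied(profile_of(S=1, X=0.6, Y=0.6), rule, f=0.5)


class TestSolutionAccuracy:
    def test_counting_fraction(self):
        # two rules on a two-edge fork; weights satisfy one of them
        net = network_from_edges([("S", "X"), ("S", "Y")])
        w = SolutionWeights(np.array([0.9, 0.01]))
        rules = [
            TruthTableRule("good", (("S", 1),), (("X", 1),)),
            TruthTableRule("bad", (("S", 1),), (("Y", 1),)),
        ]
        assert solution_accuracy(net, w, rules) == pytest.approx(0.5)

    def test_zero_weight_network_scores_zero(self):
        net = network_from_edges([("S", "X")])
        w = SolutionWeights(np.array([0.0]))
        rules = [TruthTableRule("r", (("S", 1),), (("X", 1),))]
        assert solution_accuracy(net, w, rules) == 0.0

    def test_planted_weights_fully_comply(self, small_fixture):
        fix = small_fixture
        acc = solution_accuracy(
            fix.network, fix.ground_truth.weights, list(fix.rules),
            TrainingConfig(), fix.drugs,
        )
        assert acc == 1.0

    def test_bioflags_appended_to_drug_rules(self, small_fixture):
        fix = small_fixture
        rules = effective_rules(list(fix.rules), fix.drugs)
        by_id = {r.rule_id: r for r in rules}
        for drug in fix.drugs:
            if not drug.bioflags:
                continue
            resp = dict(by_id[f"rule_{drug.name}"].response)
            for protein, sign in drug.bioflags:
                assert resp[protein] == sign

    def test_engine_matches_reference_accuracy(self, small_fixture):
        fix = small_fixture
        cfg = TrainingConfig()
        engine = RuleEngine(fix.network, list(fix.rules), cfg, fix.drugs)
        rng = np.random.default_rng(3)
        for _ in range(5):
            w = random_weights(fix.network, rng)
            engine.set_weights(w)
            ref = solution_accuracy(
                fix.network, SolutionWeights(w), list(fix.rules), cfg, fix.drugs
            )
            assert engine.accuracy() == pytest.approx(ref)


class TestSampling:
    def test_same_seed_identical_weights(self, small_fixture, quick_config):
        fix = small_fixture
        a = sample_solution(fix.network, list(fix.rules), quick_config, 7, fix.drugs)
        b = sample_solution(fix.network, list(fix.rules), quick_config, 7, fix.drugs)
        assert np.array_equal(a.weights, b.weights)
        assert a.accuracy == b.accuracy

    def test_zero_iterations_returns_initial_accuracy(self, small_fixture):
        fix = small_fixture
        cfg = TrainingConfig(n_iterations=0, seed=0)
        sol = sample_solution(fix.network, list(fix.rules), cfg, 11, fix.drugs)
        rng = np.random.default_rng(11)
        w0 = random_weights(fix.network, rng)
        assert np.array_equal(sol.weights, w0)
        ref = solution_accuracy(
            fix.network, SolutionWeights(w0), list(fix.rules), cfg, fix.drugs
        )
        assert sol.accuracy == pytest.approx(ref)

    def test_prior_signs_respected(self, small_fixture, quick_config):
        fix = small_fixture
        sol = sample_solution(fix.network, list(fix.rules), quick_config, 3, fix.drugs)
        priors = fix.network.prior_sign_array()
        constrained = priors != 0
        assert np.all(np.sign(sol.weights[constrained]) == priors[constrained])

    def test_annealing_reliably_reaches_retention_accuracy(self, small_fixture):
        """On the planted fixture, >= 80% of seeded runs pass 0.9 accuracy."""
        fix = small_fixture
        cfg = TrainingConfig(n_iterations=2000)
        engine = RuleEngine(fix.network, list(fix.rules), cfg, fix.drugs)
        accs = [
            sample_solution(fix.network, list(fix.rules), cfg, seed, fix.drugs, engine).accuracy
            for seed in range(20)
        ]
        assert np.mean([a >= 0.9 for a in accs]) >= 0.8


class TestEnsemble:
    def test_build_retains_only_above_threshold(self, small_fixture, quick_config):
        fix = small_fixture
        ens = build_ensemble(fix.network, list(fix.rules), quick_config, fix.drugs)
        assert len(ens) == quick_config.target_size
        assert min(s.accuracy for s in ens.solutions) > quick_config.retention_threshold
        assert quick_config.retention_threshold < ens.mean_accuracy <= 1.0

    def test_reproducible_given_seed(self, small_fixture, quick_config):
        fix = small_fixture
        a = build_ensemble(fix.network, list(fix.rules), quick_config, fix.drugs)
        b = build_ensemble(fix.network, list(fix.rules), quick_config, fix.drugs)
        assert [s.accuracy for s in a.solutions] == [s.accuracy for s in b.solutions]
        for sa, sb in zip(a.solutions, b.solutions):
            assert np.array_equal(sa.weights, sb.weights)

    def test_target_size_one(self, small_fixture, quick_config):
        fix = small_fixture
        cfg = TrainingConfig(**{**quick_config.to_dict(), "target_size": 1})
        assert len(build_ensemble(fix.network, list(fix.rules), cfg, fix.drugs)) == 1

    def test_near_perfect_threshold_retains_only_perfect(self, small_fixture, quick_config):
        fix = small_fixture
        cfg = TrainingConfig(
            **{**quick_config.to_dict(), "retention_threshold": 1 - 1e-9,
               "target_size": 3, "n_iterations": 2000}
        )
        ens = build_ensemble(fix.network, list(fix.rules), cfg, fix.drugs)
        assert all(s.accuracy == 1.0 for s in ens.solutions)

    def test_impossible_threshold_raises(self):
        # a 1-edge network that cannot satisfy two contradictory rules
        net = network_from_edges([("S", "X")])
        rules = [
            TruthTableRule("r1", (("S", 1),), (("X", 1),)),
            TruthTableRule("r2", (("S", 1),), (("X", -1),)),
        ]
        cfg = TrainingConfig(target_size=2, max_attempts=5, n_iterations=50,
                             retention_threshold=0.9)
        with pytest.raises(ValidationError, match="no solution"):
            build_ensemble(net, rules, cfg)

    def test_exceeds_weight_shuffled_null(self, small_fixture, quick_config):
        """Trained mean accuracy beats shuffled-weight null ensembles."""
        fix = small_fixture
        ens = build_ensemble(fix.network, list(fix.rules), quick_config, fix.drugs)
        rng = np.random.default_rng(99)
        cfg = quick_config
        null_accs = []
        for _ in range(50):
            base = ens.solutions[int(rng.integers(len(ens)))].weights.copy()
            rng.shuffle(base)
            null_accs.append(
                solution_accuracy(
                    fix.network, SolutionWeights(base), list(fix.rules), cfg, fix.drugs
                )
            )
        # permutation p-value: fraction of null accuracies >= trained mean
        p = (1 + sum(a >= ens.mean_accuracy for a in null_accs)) / (1 + len(null_accs))
        assert p < 0.05

    def test_round_trip_through_tsv(self, small_fixture, quick_config, tmp_path):
        fix = small_fixture
        ens = build_ensemble(fix.network, list(fix.rules), quick_config, fix.drugs)
        write_ensemble(ens, fix.network, tmp_path)
        loaded = load_ensemble(fix.network, tmp_path)
        assert len(loaded) == len(ens)
        for sa, sb in zip(ens.solutions, loaded.solutions):
            assert np.allclose(sa.weights, sb.weights)
            assert sa.accuracy == pytest.approx(sb.accuracy)
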