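"""Reversal scoring, T/W-Signals, synergy, modulation classes, MoA paths."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moanet import (
    ActivityProfile,
    DrugProfile,
    Effector,
    Motive,
    SolutionWeights,
    ValidationError,
    assess_synergy,
    combination_stimulus,
    effector_heatmap,
    extract_moa,
    is_reversed,
    modulation_class,
    motive_impact,
    network_from_edges,
    t_signal,
    w_signal,
)
from moanet.characterization import DiseaseCharacterization
from moanet.metrics import is_anti_reversed


class TestReversal:
    @pytest.mark.parametrize(
        "activity,sign,expected",
        [
            (-0.10, +1, True),   # boundary inclusive
            (-0.05, +1, False),  # below magnitude
            (+0.5, +1, False),   # same direction as disease
            (+0.10, -1, True),
            (0.0, +1, False),
            (0.0, -1, False),
        ],
    )
    def test_reversal_rule(self, activity, sign, expected):
        assert is_reversed(activity, sign, 0.1) is expected

    def test_anti_reversal_mirrors_disease_direction(self):
        assert is_anti_reversed(0.3, +1)
        assert not is_anti_reversed(-0.3, +1)
        assert not is_anti_reversed(0.05, +1)


class TestMotiveImpact:
    def motive(self, signs):
        return Motive("M", tuple(Effector(f"P{i}", s) for i, s in enumerate(signs)))

    def test_counts_and_percentage(self):
        motive = self.motive([+1, +1, +1, +1])
        profile = ActivityProfile({"P0": -0.5, "P1": -0.2, "P2": -0.15, "P3": 0.0})
        imp = motive_impact(profile, motive)
        assert (imp.n_eff, imp.n_anti) == (3, 0)
        assert imp.pct_reversed == pytest.approx(75.0)

    def test_null_profile_all_zero(self):
        motive = self.motive([+1, -1])
        profile = ActivityProfile({"P0": 0.0, "P1": 0.0})
        imp = motive_impact(profile, motive)
        assert (imp.n_eff, imp.n_anti, imp.t_signal) == (0, 0, 0.0)
        assert imp.w_signal == 0.0

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(42)
        signs = rng.choice([-1, 1], size=10)
        acts = rng.uniform(-1, 1, size=10)
        motive = self.motive(signs.tolist())
        profile = ActivityProfile({f"P{i}": float(a) for i, a in enumerate(acts)})
        imp = motive_impact(profile, motive, 0.1)
        n_eff = sum(
            1 for s, a in zip(signs, acts) if abs(a) >= 0.1 and np.sign(a) == -s
        )
        n_anti = sum(
            1 for s, a in zip(signs, acts) if abs(a) >= 0.1 and np.sign(a) == s
        )
        t = float(np.mean([-s * a for s, a in zip(signs, acts)]))
        assert (imp.n_eff, imp.n_anti) == (n_eff, n_anti)
        assert imp.t_signal == pytest.approx(t)
        assert imp.w_signal == pytest.approx(
            ((1 + n_eff) / (1 + n_anti)) * (n_eff / 10) + t
        )

    def test_missing_effector_is_error(self):
        with pytest.raises(ValidationError, match="lacks"):
            motive_impact(ActivityProfile({"P0": 0.1}), self.motive([1, 1]))


class TestSignals:
    def test_t_signal_single_effector(self):
        motive = Motive("M", (Effector("X", +1),))
        assert t_signal(ActivityProfile({"X": -0.6}), motive) == pytest.approx(0.6)

    def test_t_signal_odd_in_profile(self):
        motive = Motive("M", (Effector("X", +1), Effector("Y", -1)))
        p = ActivityProfile({"X": -0.3, "Y": 0.8})
        n = ActivityProfile({"X": 0.3, "Y": -0.8})
        assert t_signal(p, motive) == pytest.approx(-t_signal(n, motive))

    @pytest.mark.parametrize(
        "n_eff,n_anti,bed_p,t,expected",
        [
            (3, 1, 4, 0.2, 1.7),
            (0, 2, 4, 0.3, 0.3),   # no reversal: W reduces to T
            (4, 0, 4, 1.0, 6.0),
        ],
    )
    def test_w_signal_values(self, n_eff, n_anti, bed_p, t, expected):
        assert w_signal(n_eff, n_anti, bed_p, t) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        bed_p=st.integers(2, 50),
        t=st.floats(-1, 1, allow_nan=False),
        data=st.data(),
    )
    def test_w_signal_monotone(self, bed_p, t, data):
        n_eff = data.draw(st.integers(1, bed_p - 1))
        n_anti = data.draw(st.integers(0, bed_p - n_eff - 1))
        w = w_signal(n_eff, n_anti, bed_p, t)
        assert w_signal(n_eff + 1, n_anti, bed_p, t) > w
        assert w_signal(n_eff, n_anti + 1, bed_p, t) < w


class TestCombination:
    def test_union_of_targets(self):
        dxm = DrugProfile("DXM", (("NR3C1", "act"), ("NR0B1", "act")))
        tcz = DrugProfile("TCZ", (("IL6RA", "inh"),))
        stim = combination_stimulus(dxm, tcz)
        assert stim.clamped == {"NR3C1": +1, "NR0B1": +1, "IL6RA": -1}

    def test_idempotent_self_combination(self):
        drug = DrugProfile("D", (("A", "act"),))
        assert combination_stimulus(drug, drug).clamped == {"A": +1}

    def test_conflicting_shared_target_is_error(self):
        a = DrugProfile("A", (("P", "act"),))
        b = DrugProfile("B", (("P", "inh"),))
        with pytest.raises(ValidationError, match="conflicting"):
            combination_stimulus(a, b)

    @pytest.mark.parametrize(
        "w_a,w_b,w_ab,label",
        [
            (1.0, 1.2, 2.0, "synergistic"),
            (1.0, 1.2, 1.2, "additive-or-sub-additive"),  # strict inequality
            (0.0, 0.0, 0.0, "additive-or-sub-additive"),
        ],
    )
    def test_synergy_rule(self, w_a, w_b, w_ab, label):
        assert assess_synergy(w_a, w_b, w_ab).label == label

    @settings(derandomize=True, max_examples=30)
    @given(
        w_a=st.floats(-3, 3, allow_nan=False),
        w_b=st.floats(-3, 3, allow_nan=False),
        w_ab=st.floats(-3, 3, allow_nan=False),
    )
    def test_synergy_symmetric_in_single_drugs(self, w_a, w_b, w_ab):
        assert (
            assess_synergy(w_a, w_b, w_ab).synergistic
            == assess_synergy(w_b, w_a, w_ab).synergistic
        )


class TestModulationClass:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (-0.6, -0.55, "both"),
            (-0.6, 0.0, "drug_a"),
            (0.0, 0.6, "drug_b"),
            (0.1, -0.1, "neither"),
            (0.9, 0.4, "drug_a"),   # both pass but differ by >= thr, A larger
            (0.35, 0.45, "both"),   # both pass, differ by < thr
        ],
    )
    def test_classes(self, a, b, expected):
        assert modulation_class(a, b, 0.3) == expected

    def test_heatmap_table_columns(self, small_fixture):
        fix = small_fixture
        proteins = sorted(
            {e.protein for m in fix.characterization.motives for e in m.effectors}
        )
        pa = ActivityProfile({p: 0.5 for p in proteins})
        pb = ActivityProfile({p: -0.5 for p in proteins})
        df = effector_heatmap(pa, pb, fix.characterization, "DrugA", "DrugB")
        assert set(df.columns) >= {
            "protein", "activity_DrugA", "activity_DrugB",
            "disease_sign", "motives", "modulated_by",
        }
        assert len(df) == len(proteins)


class TestExtractMoa:
    def test_single_strong_chain(self):
        net = network_from_edges([("A", "B"), ("B", "C")])
        sols = [SolutionWeights(np.array([1.0, 1.0])) for _ in range(4)]
        moa = extract_moa(net, sols, ["A"], ["C"], k=3, epsilon=0.1, max_len=3)
        assert moa.paths == (("A", "B", "C"),)
        assert moa.support[("A", "B")] == 1.0
        assert moa.support[("B", "C")] == 1.0

    def test_planted_path_outranks_rare_decoy(self):
        # planted route via B present in all solutions, decoy via D in 1/10
        net = network_from_edges([("A", "B"), ("B", "C"), ("A", "D"), ("D", "C")])
        sols = []
        for i in range(10):
            decoy = 1.0 if i == 0 else 0.01
            sols.append(SolutionWeights(np.array([1.0, 1.0, decoy, decoy])))
        moa = extract_moa(net, sols, ["A"], ["C"], k=2)
        assert moa.paths[0] == ("A", "B", "C")
        assert moa.support[("A", "B")] == 1.0
        assert moa.support[("A", "D")] == pytest.approx(0.1)

    def test_epsilon_above_all_weights_gives_empty(self):
        net = network_from_edges([("A", "B")])
        sols = [SolutionWeights(np.array([0.5]))]
        moa = extract_moa(net, sols, ["A"], ["B"], epsilon=0.9)
        assert moa.is_empty

    def test_path_length_capped(self):
        net = network_from_edges([("A", "B"), ("B", "C"), ("C", "D")])
        sols = [SolutionWeights(np.array([1.0, 1.0, 1.0]))]
        moa = extract_moa(net, sols, ["A"], ["D"], max_len=2)
        assert moa.is_empty

    def test_support_quantized_by_ensemble_size(self):
        net = network_from_edges([("A", "B")])
        sols = [
            SolutionWeights(np.array([1.0])),
            SolutionWeights(np.array([1.0])),
            SolutionWeights(np.array([0.01])),
        ]
        moa = extract_moa(net, sols, ["A"], ["B"])
        assert moa.support[("A", "B")] == pytest.approx(2 / 3)
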