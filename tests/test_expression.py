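import numpy as np
import pandas as pd
import pytest

from efmsig.expression import (ActivityModel, ExpressionMatrix,
                               call_absolute_states, call_probe_activity,
                               differential_states, storey_qvalues)
from efmsig.simulate import simulate_two_group

from .oracles import bh_adjusted, plain_t_bh_calls


def tiny_matrix(values, probes, samples, probe_to_gene, groups):
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples),
                            probe_to_gene, groups)


class TestProbeActivity:
    def test_bimodal_calls_match_component_labels(self):
        rng = np.random.default_rng(1)
        low = rng.normal(5, 1, size=3000)
        high = rng.normal(11, 1, size=3000)
        model = ActivityModel(k=3).fit(np.concatenate([low, high]))
        assert 6 < model.threshold_ < 10
        # all points clearly beyond the overlap region are called correctly
        assert not call_probe_activity(low[low < model.threshold_ - 0.5], model).any()
        assert call_probe_activity(high[high > model.threshold_ + 0.5], model).all()

    def test_all_below_threshold_inactive(self):
        assert not call_probe_activity([1.0, 2.0, 3.0], ActivityModel(
            fixed_threshold=5.0).fit([])).any()

    def test_value_at_threshold_is_inactive(self):
        model = ActivityModel(fixed_threshold=7.0).fit([])
        assert list(call_probe_activity([7.0, 7.0 + 1e-9], model)) == [False, True]

    def test_constant_matrix_falls_back_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            model = ActivityModel().fit(np.full(50, 4.2))
        assert model.threshold_ == pytest.approx(4.2)
        assert any("unidentifiable" in r.message for r in caplog.records)


class TestAbsoluteStates:
    @pytest.fixture()
    def three_probe_gene(self):
        # gene gA: 3 probes; gene gB: 2 probes, one flaky
        values = [[9, 9, 9], [9.5, 9, 9], [9, 9.5, 9],
                  [9, 9, 9], [2, 2, 9]]
        probes = ["pA1", "pA2", "pA3", "pB1", "pB2"]
        p2g = {"pA1": "gA", "pA2": "gA", "pA3": "gA", "pB1": "gB", "pB2": "gB"}
        samples = ["s1", "s2", "s3"]
        return tiny_matrix(values, probes, samples, p2g,
                           {s: "G" for s in samples})

    def test_all_probes_active_gives_plus_one(self, three_probe_gene):
        vec = call_absolute_states(three_probe_gene, "G",
                                   model=ActivityModel(fixed_threshold=5.0).fit([]))
        assert vec.states["gA"] == 1

    def test_mixed_probe_gives_zero_under_strict_rule(self, three_probe_gene):
        vec = call_absolute_states(three_probe_gene, "G",
                                   model=ActivityModel(fixed_threshold=5.0).fit([]))
        assert vec.states["gB"] == 0

    def test_relaxed_probe_fraction_rescues_flaky_probe(self):
        # 25 probes, 24 solidly active, one dead: strict rule says 0,
        # the 95% relaxation says highly expressed
        probes = [f"p{i}" for i in range(25)]
        values = [[9.0, 9.0]] * 24 + [[2.0, 2.0]]
        expr = tiny_matrix(values, probes, ["s1", "s2"],
                           {p: "g" for p in probes}, {"s1": "G", "s2": "G"})
        model = ActivityModel(fixed_threshold=5.0).fit([])
        assert call_absolute_states(expr, "G", model=model).states["g"] == 0
        assert call_absolute_states(expr, "G", probe_fraction=0.95,
                                    model=model).states["g"] == 1

    def test_plus_and_minus_sets_disjoint_and_monotone(self):
        rng = np.random.default_rng(5)
        n_genes, n_probes_per, n_samp = 40, 3, 6
        probes = [f"g{i}_p{j}" for i in range(n_genes) for j in range(n_probes_per)]
        p2g = {p: p.split("_")[0] for p in probes}
        values = rng.choice([3.0, 9.0], size=(len(probes), n_samp))
        expr = tiny_matrix(values, probes, [f"s{k}" for k in range(n_samp)],
                           p2g, {f"s{k}": "G" for k in range(n_samp)})
        model = ActivityModel(fixed_threshold=6.0).fit([])
        strict = call_absolute_states(expr, "G", model=model)
        plus = {g for g, s in strict.states.items() if s == 1}
        minus = {g for g, s in strict.states.items() if s == -1}
        assert not plus & minus
        for pf, sf in [(0.7, 1.0), (1.0, 0.7), (0.7, 0.7)]:
            relaxed = call_absolute_states(expr, "G", probe_fraction=pf,
                                           sample_fraction=sf, model=model)
            assert plus <= {g for g, s in relaxed.states.items() if s == 1}


class TestDifferentialStates:
    def test_identical_groups_all_zero(self):
        values = np.tile(np.arange(10, dtype=float)[:, None], (1, 6))
        probes = [f"g{i}_p" for i in range(10)]
        expr = tiny_matrix(values, probes, [f"s{k}" for k in range(6)],
                           {p: p[:-2] for p in probes},
                           {f"s{k}": ("A" if k < 3 else "B") for k in range(6)})
        vec, results = differential_states(expr, "A", "B")
        assert all(s == 0 for s in vec.states.values())
        assert all(r.effect == 0 for r in results)

    def test_label_swap_antisymmetry_exact(self):
        expr, _ = simulate_two_group(300, 30, 1.5, 0.8, seed=3)
        ab, _ = differential_states(expr, "A", "B")
        ba, _ = differential_states(expr, "B", "A")
        assert all(ab.states[g] == -ba.states[g] for g in ab.states)

    def test_planted_shift_recovered(self):
        expr, planted = simulate_two_group(2000, 100, 2.0, 0.5, seed=17)
        # the regime is easy: an independent plain t-test + BH finds it too
        oracle = plain_t_bh_calls(expr, "A", "B")
        assert sum(oracle[g] == 1 for g in planted) >= 95
        vec, _ = differential_states(expr, "A", "B", q_threshold=0.05)
        assert sum(vec.states[g] == 1 for g in planted) >= 95

    def test_small_group_rejected(self):
        expr, _ = simulate_two_group(10, 0, 0.0, 0.5, n_per_group=2, seed=0)
        sub = ExpressionMatrix(expr.values.iloc[:, [0, 2, 3]],
                               expr.probe_to_gene,
                               {s: expr.sample_groups[s]
                                for s in expr.values.columns[[0, 2, 3]]})
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_states(sub, "A", "B")

    def test_null_data_false_positive_rate_bounded(self):
        # no planted effect: across seeds, well under 5% of genes called
        fractions = []
        for seed in range(20):
            expr, _ = simulate_two_group(2000, 0, 0.0, 0.5, n_per_group=5,
                                         seed=100 + seed)
            vec, _ = differential_states(expr, "A", "B", q_threshold=0.05)
            fractions.append(np.mean([s != 0 for s in vec.states.values()]))
        assert max(fractions) <= 0.05


class TestStoreyQvalues:
    def test_all_ones_stay_ones(self):
        assert list(storey_qvalues([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    def test_empty_input(self):
        assert storey_qvalues([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])

    def test_pi0_one_equals_bh(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(5, 200))
            np.testing.assert_allclose(storey_qvalues(p, pi0=1.0),
                                       bh_adjusted(p), atol=1e-12)

    def test_ties_get_equal_q(self):
        q = storey_qvalues([0.01, 0.01, 0.5, 0.01], pi0=1.0)
        assert q[0] == q[1] == q[3]

    def test_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(29)
        p = np.concatenate([rng.beta(0.3, 4, 300), rng.uniform(size=700)])
        q = storey_qvalues(p)
        assert (q >= 0).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_monotone_bounded_hypothesis(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=100, derandomize=True, deadline=None)
        @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                        max_size=50))
        def check(p):
            q = storey_qvalues(p)
            assert (q >= 0).all() and (q <= 1).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-15).all()

        check()

    def test_estimated_pi0_never_exceeds_one(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(size=500)
        assert (storey_qvalues(p) <= 1.0).all()
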