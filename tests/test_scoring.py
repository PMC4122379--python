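from fractions import Fraction

import numpy as np
import pytest

from efmsig.efm import EFMCollection, FluxMode
from efmsig.projection import ReactionStateVector
from efmsig.scoring import (prominent_efms, score_collection, score_efm,
                            select_efms, venn_decompose)

from .oracles import hypergeom_upper_tail_by_enumeration, venn_regions_by_membership

F = Fraction


def mode(mid, *rids):
    return FluxMode(mid, {r: F(1) for r in rids})


def rstates(states, scenario="S", no_gpr=()):
    return ReactionStateVector(scenario, states, frozenset(no_gpr))


class TestScoreEFM:
    def test_no_high_reactions_p_is_one(self):
        rs = rstates({f"r{i}": (1 if i < 3 else 0) for i in range(10)})
        s = score_efm(mode("e", "r5", "r6", "r7"), rs)
        assert s.n_high_in_efm == 0 and s.p_value == 1.0

    def test_worked_example_one_thirtieth(self):
        # N=10 covered, K=4 high; support of 3, all high: p = 4/120 = 1/30
        rs = rstates({f"r{i}": (1 if i < 4 else 0) for i in range(10)})
        s = score_efm(mode("e", "r0", "r1", "r2"), rs)
        assert s.p_value == pytest.approx(1 / 30, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(53)
        for _ in range(30):
            N = int(rng.integers(3, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            states = {f"r{i}": (1 if i < K else 0) for i in range(N)}
            support = [f"r{i}" for i in rng.choice(N, size=n, replace=False)]
            s = score_efm(mode("e", *support), rstates(states))
            expected = hypergeom_upper_tail_by_enumeration(N, K, n, s.n_high_in_efm)
            assert s.p_value == pytest.approx(float(expected), abs=1e-12)

    def test_low_fraction_disqualifies(self):
        rs = rstates({"r0": -1, "r1": -1, "r2": 1, "r3": 1})
        s = score_efm(mode("e", "r0", "r1", "r2", "r3"), rs, tau_low=0.1)
        assert s.disqualified and "tau_low" in s.reason

    def test_empty_covered_support_disqualified_no_evidence(self):
        rs = rstates({"r0": 1, "r1": 0}, no_gpr=("r1",))
        s = score_efm(mode("e", "r1"), rs)
        assert s.disqualified and s.reason == "no evidence"

    def test_adding_high_reaction_never_raises_p(self):
        rs = rstates({f"r{i}": (1 if i < 6 else 0) for i in range(15)})
        base = score_efm(mode("e", "r0", "r10", "r11"), rs)
        bigger = score_efm(mode("e", "r0", "r1", "r10", "r11"), rs)
        assert bigger.p_value <= base.p_value


class TestSelection:
    def test_all_p_one_selects_nothing(self):
        rs = rstates({f"r{i}": 0 for i in range(8)})
        coll = EFMCollection([mode("a", "r0", "r1"), mode("b", "r2", "r3")],
                             [f"r{i}" for i in range(8)])
        sel = select_efms(score_collection(coll, rs))
        assert sel.selected == set()

    def test_lowering_threshold_never_enlarges_selection(self):
        rng = np.random.default_rng(59)
        N = 40
        states = {f"r{i}": int(rng.choice([0, 1], p=[0.7, 0.3])) for i in range(N)}
        modes = [mode(f"e{k}", *(f"r{i}" for i in
                                 rng.choice(N, size=4, replace=False)))
                 for k in range(30)]
        coll = EFMCollection(modes, list(states))
        scores = score_collection(coll, rstates(states))
        prev = None
        for thr in (0.5, 0.2, 0.1, 0.01):
            sel = select_efms(list(scores), thr).selected
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_all_disqualified_warns_and_empty(self, caplog):
        rs = rstates({"r0": -1, "r1": -1})
        coll = EFMCollection([mode("a", "r0", "r1")], ["r0", "r1"])
        with caplog.at_level("WARNING"):
            sel = select_efms(score_collection(coll, rs))
        assert sel.selected == set()
        assert any("disqualified" in r.message for r in caplog.records)

    def test_mixed_scenarios_rejected(self):
        a = score_efm(mode("e", "r0"), rstates({"r0": 1}, scenario="X"))
        b = score_efm(mode("e", "r0"), rstates({"r0": 1}, scenario="Y"))
        with pytest.raises(ValueError, match="mix"):
            select_efms([a, b])


class TestProminent:
    def test_intersection_cases(self):
        def sel(ids, mode_label):
            from efmsig.scoring import EFMScore, ScenarioSelection
            scores = [EFMScore(i, "s", 1, 1, 0, (4, 2), 0.5)
                      for i in ("a", "b", "c", "d")]
            return ScenarioSelection("s", set(ids), 0.2, mode_label, scores)

        assert prominent_efms(sel({"a", "b", "c"}, "characteristic"),
                              sel({"b", "c", "d"}, "differential")) == {"b", "c"}
        assert prominent_efms(sel({"a"}, "characteristic"),
                              sel({"d"}, "differential")) == set()
        assert prominent_efms(sel({"a", "b"}, "characteristic"),
                              sel({"a", "b"}, "differential")) == {"a", "b"}

    def test_mismatched_collections_rejected(self):
        from efmsig.scoring import EFMScore, ScenarioSelection
        s1 = ScenarioSelection("s", set(), 0.2, "characteristic",
                               [EFMScore("a", "s", 1, 1, 0, (2, 1), 0.5)])
        s2 = ScenarioSelection("s", set(), 0.2, "differential",
                               [EFMScore("b", "s", 1, 1, 0, (2, 1), 0.5)])
        with pytest.raises(ValueError, match="different"):
            prominent_efms(s1, s2)


class TestVenn:
    def test_three_identical_sets_single_region(self):
        s = {f"e{i}" for i in range(5)}
        report = venn_decompose({"A": s, "B": s, "C": s})
        assert report["regions"] == {"A∩B∩C": 5}

    def test_pairwise_minus_third_identity(self):
        # with |AD∩SQ| = 109 of which 53 lie in all three, the cancer-only
        # core AD∩SQ∖CN must count 56
        ad = {f"x{i}" for i in range(109)} | {f"a{i}" for i in range(20)}
        sq = {f"x{i}" for i in range(109)} | {f"s{i}" for i in range(30)}
        cn = {f"x{i}" for i in range(53, 109)} ^ {f"x{i}" for i in range(109)}
        cn |= {f"c{i}" for i in range(10)}  # x0..x52 plus CN-only members
        report = venn_decompose({"AD": ad, "SQ": sq, "CN": cn})
        assert report["regions"]["AD∩SQ∩CN"] == 53
        assert report["regions"]["AD∩SQ∖CN"] == 56

    def test_counts_partition_the_union(self):
        rng = np.random.default_rng(61)
        universe = [f"e{i}" for i in range(50)]
        sets = {name: set(rng.choice(universe, size=20, replace=False))
                for name in ("A", "B", "C")}
        report = venn_decompose(sets)
        assert sum(report["regions"].values()) == report["union_size"]
        oracle = venn_regions_by_membership(sets)
        assert sum(oracle.values()) == report["union_size"]
        # region-by-region agreement with the per-element oracle
        names = list(sets)
        for key, count in oracle.items():
            inside = [n for n, k in zip(names, key) if k]
            outside = [n for n, k in zip(names, key) if not k]
            label = "∩".join(inside) + "".join(f"∖{n}" for n in outside)
            assert report["regions"][label] == count

    def test_false_positive_flagging(self):
        # differential EFM "fp" is characteristic only in the opposing scenario
        report = venn_decompose(
            {"SQ": {"a", "b"}, "upSQ": {"a", "fp"}, "AD": {"fp", "c"}},
            differential="upSQ", characteristic="SQ", opposing="AD")
        assert report["false_positives"] == ["fp"]

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            venn_decompose({"A": {1}})
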