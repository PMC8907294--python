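"""Contribution maps, semantic values and term-pair similarity measures."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dag, term_pairs
from _measure_oracles import ORACLE_MEASURES, o_lin, o_resnik
from ontosim.annotation_io import GeneAnnotationSet
from ontosim.errors import DataError
from ontosim.obo_graph import RelationType
from ontosim.synth_fixtures import TOY, make_toy_ontology
from ontosim.term_semantics import (
    BOUNDED_MEASURES,
    MEASURES,
    WeightConfig,
    build_ic,
    contributions_down,
    contributions_up,
    pairwise_table,
    sim_baseline,
    sim_desc,
    sim_gontosim,
    sim_lin,
    sim_resnik,
    sv_max_path,
    sv_sum,
    term_similarity,
    wu_palmer,
)

A, B, C1, C2, R, D = (TOY[k] for k in ("A", "B", "C1", "C2", "R", "D"))
W = WeightConfig()


class TestWeightConfig:
    def test_defaults(self):
        assert (W.w_is_a, W.w_part_of, W.w_regulates) == (0.8, 0.6, 0.7)
        assert W.U == W.L == 0.5

    @pytest.mark.parametrize(
        "kwargs", [{"w_is_a": 0.0}, {"w_part_of": 1.2}, {"U": 0.7, "L": 0.5}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WeightConfig(**kwargs)

    def test_regulates_family_shares_weight(self):
        assert W.weight(RelationType.POSITIVELY_REGULATES) == W.w_regulates
        assert W.weight(RelationType.NEGATIVELY_REGULATES) == W.w_regulates


class TestContributions:
    def test_upward_root_zeroed(self, toy5):
        assert contributions_up(toy5, A).contributions == {A: 1.0, C1: 0.8, R: 0.0}

    def test_upward_root_counted(self, toy5):
        cmap = contributions_up(toy5, A, root_zeroed=False)
        assert cmap.contributions == {A: 1.0, C1: 0.8, R: pytest.approx(0.64)}

    def test_downward_with_cut(self, toy6):
        cmap = contributions_down(toy6, A, depth_cut=1)
        assert cmap.contributions == {A: 1.0, D: 0.8}

    def test_leaf_downward(self, toy5):
        assert contributions_down(toy5, A, depth_cut=5).contributions == {A: 1.0}

    @pytest.mark.parametrize("seed", range(10))
    def test_every_value_is_max_path_product(self, seed):
        from ontosim.synth_fixtures import oracle_contributions

        g = random_dag(seed, max_layers=4, max_per_layer=4)
        for a in sorted(g.terms):
            got = contributions_up(g, a).contributions
            want = oracle_contributions(g, a, "up")
            assert got.keys() == want.keys()
            for t in got:
                assert got[t] == pytest.approx(want[t], abs=1e-12)


class TestSemanticValues:
    def test_sum_modes(self, toy5):
        assert sv_sum(contributions_up(toy5, A)).value == pytest.approx(1.8)
        assert sv_sum(
            contributions_up(toy5, A, root_zeroed=False)
        ).value == pytest.approx(2.44)

    def test_singleton_root_wang_mode(self, toy5):
        assert sv_sum(contributions_up(toy5, R, root_zeroed=False)).value == 1.0

    def test_max_path_single_path(self, toy5):
        assert sv_max_path(toy5, A).value == pytest.approx(1.8)

    def test_max_path_picks_longer_diamond_path(self, diamond):
        # paths X-P1-R (1 + 0.8 + 0) vs X-P2-P1-R (1 + 0.8 + 0.64 + 0)
        assert sv_max_path(diamond, "X").value == pytest.approx(2.44)

    @pytest.mark.parametrize("seed", range(10))
    def test_max_path_never_exceeds_sum(self, seed):
        g = random_dag(seed)
        for t in g.terms:
            assert (
                sv_max_path(g, t).value
                <= sv_sum(contributions_up(g, t)).value + 1e-12
            )


class TestToyWorkedValues:
    """Hand-derivable values on the toy graph (verified against enumeration)."""

    @pytest.mark.parametrize(
        "measure, expected",
        [
            ("baseline", 1.6 / 3.6),
            ("wang", 2.88 / 4.88),
            ("baseline_lca", 2.0 / 3.6),
            ("tanimoto_baseline", 0.8 / 2.8),
            ("wu_palmer", 0.5),
        ],
    )
    def test_pairs_without_descendant(self, toy5, measure, expected):
        r = term_similarity(toy5, A, B, measure)
        assert r.total == pytest.approx(expected, abs=1e-12)
        assert r.total == pytest.approx(
            ORACLE_MEASURES[measure](toy5, A, B), abs=1e-12
        )

    @pytest.mark.parametrize(
        "measure, expected",
        [
            ("gontosim", 0.5),
            ("baseline_desc", 1.6 / 3.6),
            ("baseline", 1.6 / 3.6),  # unchanged by the extra descendant
        ],
    )
    def test_pairs_with_descendant(self, toy6, measure, expected):
        r = term_similarity(toy6, A, B, measure)
        assert r.total == pytest.approx(expected, abs=1e-12)
        assert r.total == pytest.approx(
            ORACLE_MEASURES[measure](toy6, A, B), abs=1e-12
        )

    def test_desc_component(self, toy5, toy6):
        assert sim_desc(toy6, A, B).total == pytest.approx(1.6 / 3.6, abs=1e-12)
        assert sim_desc(toy5, A, B).total == 0.0  # no common descendant

    def test_baseline_desc_mixing_weights(self, toy6):
        w73 = WeightConfig(U=0.7, L=0.3)
        # both components equal 0.4444..., so the mix does not move
        r = term_similarity(toy6, A, B, "baseline_desc", w=w73)
        assert r.total == pytest.approx(1.6 / 3.6, abs=1e-12)

    def test_ancestor_chain_lca_strictly_below_one(self, toy5):
        r = term_similarity(toy5, A, C1, "baseline_lca")
        assert 0.0 < r.total < 1.0

    def test_root_siblings_have_zero_lca_similarity(self, toy5):
        assert term_similarity(toy5, C1, C2, "baseline_lca").total == 0.0

    def test_literal_mixture_identical_leaf_scores_half(self, toy5):
        assert sim_gontosim(toy5, A, A).total == 1.0
        assert sim_gontosim(toy5, A, A, literal_mixture=True).total == 0.5


class TestAxioms:
    @pytest.mark.parametrize("measure", BOUNDED_MEASURES)
    def test_identity(self, toy6, measure):
        for t in (A, B, C1, R, D):
            assert term_similarity(toy6, t, t, measure).total == 1.0

    @pytest.mark.parametrize("measure", BOUNDED_MEASURES)
    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_bounds(self, measure, seed):
        g = random_dag(seed)
        for a, b in term_pairs(g, seed + 100, 10):
            ab = term_similarity(g, a, b, measure).total
            ba = term_similarity(g, b, a, measure).total
            assert ab == pytest.approx(ba, abs=1e-12)
            assert -1e-12 <= ab <= 1 + 1e-12


class TestWangEquivalence:
    def _reference_wang(self, g, a, b, w=W):
        """Independent recursive S-value implementation of Wang's measure."""

        def upward_set(t):
            out = {t}
            for p, _ in g.parents[t]:
                out |= upward_set(p)
            return out

        def svalues(anchor):
            dag = upward_set(anchor)
            s = {}

            def s_of(t):
                if t not in s:
                    s[t] = (
                        1.0
                        if t == anchor
                        else max(
                            w.weight(rel) * s_of(c)
                            for c, rel in g.children[t]
                            if c in dag
                        )
                    )
                return s[t]

            for t in dag:
                s_of(t)
            return s

        sa, sb = svalues(g.resolve(a)), svalues(g.resolve(b))
        inter = set(sa) & set(sb)
        return sum(sa[t] + sb[t] for t in inter) / (
            sum(sa.values()) + sum(sb.values())
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_baseline_without_root_zeroing_is_wang(self, seed):
        g = random_dag(seed)
        for a, b in term_pairs(g, seed + 7, 6):
            if a == b:
                continue
            mine = sim_baseline(g, a, b, root_zeroed=False).total
            assert mine == pytest.approx(self._reference_wang(g, a, b), abs=1e-12)


class TestInformationContent:
    @pytest.fixture()
    def corpus(self, toy5):
        # 4 genes: A,A,B,C2 -> counts: A 2, B 1, C1 3, C2 1, R 4
        sets = [
            GeneAnnotationSet("g1", {A}, "MF"),
            GeneAnnotationSet("g2", {A}, "MF"),
            GeneAnnotationSet("g3", {B}, "MF"),
            GeneAnnotationSet("g4", {C2}, "MF"),
        ]
        return sets, build_ic(sets, toy5)

    def test_root_ic_zero(self, toy5, corpus):
        _, ic = corpus
        assert ic.ic(R) == 0.0

    def test_hand_counted_frequencies(self, toy5, corpus):
        _, ic = corpus
        assert ic.ic(A) == pytest.approx(-math.log(2 / 4))
        assert ic.ic(C1) == pytest.approx(-math.log(3 / 4))
        assert ic.ic(C2) == pytest.approx(-math.log(1 / 4))

    def test_monotone_parent_to_child(self, toy5, corpus):
        _, ic = corpus
        for child, parent in ((A, C1), (C1, R), (C2, R)):
            assert ic.ic(child) >= ic.ic(parent)

    def test_resnik_lin_against_enumeration(self, toy5, corpus):
        sets, ic = corpus
        assert sim_resnik(ic, toy5, A, B) == pytest.approx(
            o_resnik(toy5, sets, A, B), abs=1e-12
        )
        assert sim_lin(ic, toy5, A, B) == pytest.approx(
            o_lin(toy5, sets, A, B), abs=1e-12
        )

    def test_resnik_root_mica_zero(self, toy5, corpus):
        _, ic = corpus
        assert sim_resnik(ic, toy5, C1, C2) == 0.0

    def test_lin_identity(self, toy5, corpus):
        _, ic = corpus
        assert sim_lin(ic, toy5, A, A) == pytest.approx(1.0)

    def test_empty_corpus_rejected(self, toy5):
        with pytest.raises(DataError):
            build_ic([], toy5)


class TestWuPalmer:
    def test_direct_root_children_score_zero(self, toy5):
        assert wu_palmer(toy5, C1, C2) == 0.0

    def test_uses_shortest_path_depth(self, diamond):
        # LCA(X, P1) = P1 at shortest depth 1; depth_shortest(X) = 2 (not 3)
        assert wu_palmer(diamond, "X", "P1") == pytest.approx(2 * 1 / (2 + 1))


class TestArbitraryWeightProperties:
    """Axioms must hold for any admissible weight configuration, not just
    the defaults."""

    @given(
        w_is_a=st.floats(0.05, 1.0),
        w_part_of=st.floats(0.05, 1.0),
        w_regulates=st.floats(0.05, 1.0),
        u=st.floats(0.0, 1.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_gontosim_axioms_under_any_weights(self, w_is_a, w_part_of,
                                               w_regulates, u):
        w = WeightConfig(w_is_a, w_part_of, w_regulates, U=u, L=1.0 - u)
        g = make_toy_ontology(include_descendant=True)
        ab = sim_gontosim(g, A, B, w).total
        ba = sim_gontosim(g, B, A, w).total
        assert ab == pytest.approx(ba, abs=1e-12)
        assert 0.0 <= ab <= 1.0
        assert sim_gontosim(g, A, A, w).total == 1.0
        cmap = contributions_up(g, A, w).contributions
        assert cmap[A] == 1.0
        assert all(0.0 <= v <= 1.0 for v in cmap.values())


class TestRegistry:
    def test_all_measures_registered(self):
        assert set(MEASURES) == {
            "gontosim", "baseline", "baseline_desc", "baseline_lca", "wang",
            "tanimoto_baseline", "tanimoto_gontosim", "resnik", "lin", "wu_palmer",
        }

    def test_unknown_measure_raises(self, toy5):
        with pytest.raises(DataError, match="unknown measure"):
            term_similarity(toy5, A, B, "nope")

    def test_ic_measure_requires_table(self, toy5):
        with pytest.raises(DataError, match="ICTable"):
            term_similarity(toy5, A, B, "resnik")

    def test_pairwise_table(self, toy6):
        df = pairwise_table(toy6, [(A, B), (A, A)], "gontosim")
        assert list(df.columns) == ["term_a", "term_b", "upward", "downward", "total"]
        assert df.shape == (2, 5)
        assert df.loc[0, "total"] == pytest.approx(0.5)
        assert df.loc[1, "total"] == 1.0
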