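"""DEC state space, rates, cladogenesis, likelihood, fitting, mapping."""

import itertools
import math
import random

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from phylodeco import dec
from phylodeco.trees import parse_newick

from conftest import balanced_ultrametric


@pytest.fixture(scope="module")
def space2():
    return dec.DECStateSpace(["a", "b"])


@pytest.fixture(scope="module")
def two_tip_tree():
    return parse_newick("(X:1.0,Y:1.5);")


@pytest.fixture(scope="module")
def two_tip_ranges():
    return dec.RangeMatrix(pd.DataFrame([[1, 0], [0, 1]], index=["X", "Y"],
                                        columns=["a", "b"]))


class TestStateSpace:
    @pytest.mark.parametrize("n_areas,expected", [(2, 3), (3, 7), (7, 127)])
    def test_observable_state_count(self, n_areas, expected):
        sp = dec.DECStateSpace([f"a{i}" for i in range(n_areas)])
        assert sp.n_observable == expected

    def test_null_range_is_index_zero(self, space2):
        assert space2.states[0] == 0
        assert space2.index[0] == 0


class TestReduceAreas:
    def test_no_autapomorphic_areas_unchanged(self):
        tab = pd.DataFrame([[1, 1], [1, 0], [0, 1]], index=list("xyz"),
                           columns=["a", "b"])
        rm = dec.RangeMatrix(tab)
        assert dec.reduce_areas(rm).table.equals(tab)

    def test_autapomorphic_column_removed(self):
        tab = pd.DataFrame([[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 1, 1]],
                           index=list("xyz"), columns=list("abcd"))
        # area b: only species x, which also holds a -> drop b
        # area d: only species z, which also holds c -> drop d
        out = dec.reduce_areas(dec.RangeMatrix(tab))
        assert list(out.table.columns) == ["a", "c"]

    def test_sole_area_of_a_species_retained(self):
        tab = pd.DataFrame([[1, 0], [0, 1], [0, 1]], index=list("xyz"),
                           columns=["a", "b"])
        out = dec.reduce_areas(dec.RangeMatrix(tab))
        assert "a" in out.table.columns  # x occupies only a


class TestBuildQ:
    def test_zero_rates_zero_matrix(self, space2):
        Q = dec.build_Q(dec.DECParams(0, 0), space2)
        assert np.allclose(Q, 0)

    def test_two_area_entries(self, space2):
        d, e = 0.3, 0.1
        Q = dec.build_Q(dec.DECParams(d, e), space2)
        i = space2.index
        assert Q[i[0b01], i[0b11]] == pytest.approx(d)      # {a} -> {a,b}
        assert Q[i[0b11], i[0b01]] == pytest.approx(e)      # {a,b} -> {a}
        assert Q[i[0b01], i[0b00]] == pytest.approx(e)      # {a} -> null
        assert Q[i[0b01], i[0b10]] == 0.0                   # no direct swap

    def test_dispersal_scales_with_range_size(self):
        sp = dec.DECStateSpace(list("abc"))
        Q = dec.build_Q(dec.DECParams(0.2, 0.0), sp)
        i = sp.index
        assert Q[i[0b011], i[0b111]] == pytest.approx(0.4)  # |r|=2 source

    def test_row_sums_zero_random_params(self):
        rng = random.Random(0)
        for _ in range(20):
            sp = dec.DECStateSpace([f"x{i}" for i in range(rng.randrange(2, 6))])
            Q = dec.build_Q(dec.DECParams(rng.uniform(0, 2), rng.uniform(0, 2)), sp)
            assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)


def brute_clado(parent, params, space):
    """Enumeration oracle over all ordered daughter pairs."""
    out = {}
    r = parent
    for s1, s2 in itertools.product(space.states[1:], repeat=2):
        w = 0.0
        if space.size(r) == 1 and s1 == r and s2 == r:
            w = 1.0
        elif space.size(r) > 1:
            if s2 == r and space.size(s1) == 1 and s1 & r:
                w += 1.0
            if s1 == r and space.size(s2) == 1 and s2 & r:
                w += 1.0
            if (s1 | s2) == r and (s1 & s2) == 0 and s1 and s2 \
                    and min(space.size(s1), space.size(s2)) == 1:
                w += 1.0
        if params.j > 0:
            if s2 == r and space.size(s1) == 1 and not (s1 & r):
                w += params.j
            if s1 == r and space.size(s2) == 1 and not (s2 & r):
                w += params.j
        if w:
            out[(s1, s2)] = w
    tot = sum(out.values())
    return {k: v / tot for k, v in out.items()}


class TestCladogenesis:
    def test_single_area_duplication(self, space2):
        ev = dec.cladogenesis_events(0b01, dec.DECParams(0.1, 0.1), space2)
        assert ev == {(0b01, 0b01): 1.0}

    def test_two_area_six_events(self, space2):
        ev = dec.cladogenesis_events(0b11, dec.DECParams(0.1, 0.1), space2)
        assert len(ev) == 6
        assert all(w == pytest.approx(1 / 6) for w in ev.values())

    def test_jump_dominates_at_large_j(self):
        sp = dec.DECStateSpace(list("abc"))
        ev = dec.cladogenesis_events(0b001, dec.DECParams(0.1, 0.1, j=1e6), sp)
        jump_mass = sum(w for (s1, s2), w in ev.items()
                        if (s1 == 0b001) != (s2 == 0b001) and not
                        ((s1 | s2) == 0b001))
        assert jump_mass > 0.999

    def test_matches_enumeration_oracle(self):
        for n_areas in (2, 3, 4):
            sp = dec.DECStateSpace([f"x{i}" for i in range(n_areas)])
            for parent in sp.states[1:]:
                for j in (0.0, 0.5):
                    params = dec.DECParams(0.1, 0.1, j)
                    mine = dec.cladogenesis_events(parent, params, sp)
                    oracle = brute_clado(parent, params, sp)
                    assert set(mine) == set(oracle)
                    for k in mine:
                        assert mine[k] == pytest.approx(oracle[k], abs=1e-12)
                    assert sum(mine.values()) == pytest.approx(1.0)

    def test_null_parent_rejected(self, space2):
        with pytest.raises(ValueError, match="null"):
            dec.cladogenesis_events(0, dec.DECParams(0.1, 0.1), space2)


class TestLikelihood:
    def test_frozen_tips_equal_prior_mass(self, space2):
        """d=e=0 with both tips in one area: likelihood is prior of that state."""
        tree = parse_newick("(X:1.0,Y:1.5);")
        rm = dec.RangeMatrix(pd.DataFrame([[1, 0], [1, 0]], index=["X", "Y"],
                                          columns=["a", "b"]))
        ll = dec.dec_loglik(tree, rm, dec.DECParams(0, 0))
        assert ll == pytest.approx(math.log(1 / 3))

    def test_matches_expm_oracle_on_grid(self, two_tip_tree, two_tip_ranges):
        def oracle(d, e):
            sp = dec.DECStateSpace(["a", "b"])
            Q = dec.build_Q(dec.DECParams(d, e), sp)
            idx = sp.index
            P1, P2 = expm(Q * 1.0), expm(Q * 1.5)
            like = 0.0
            for root in sp.states[1:]:
                ev = dec.cladogenesis_events(root, dec.DECParams(d, e), sp)
                acc = sum(w * P1[idx[s1], idx[0b01]] * P2[idx[s2], idx[0b10]]
                          for (s1, s2), w in ev.items())
                like += acc / 3
            return math.log(like)

        for d in (0.05, 0.1, 0.3, 0.6, 1.0):
            for e in (0.01, 0.05, 0.2, 0.5, 1.0):
                mine = dec.dec_loglik(two_tip_tree, two_tip_ranges,
                                      dec.DECParams(d, e))
                assert mine == pytest.approx(oracle(d, e), abs=1e-8)

    def test_area_relabeling_invariance(self):
        tree = balanced_ultrametric(3)
        rm, _ = dec.simulate_ranges(tree, list("abc"), dec.DECParams(0.3, 0.05),
                                    root_range=["a"], seed=1)
        ll = dec.dec_loglik(tree, rm, dec.DECParams(0.2, 0.04))
        perm = rm.table[["c", "a", "b"]]
        ll_perm = dec.dec_loglik(tree, dec.RangeMatrix(perm), dec.DECParams(0.2, 0.04))
        assert ll_perm == pytest.approx(ll, abs=1e-10)

    def test_decj_at_zero_equals_dec(self, two_tip_tree, two_tip_ranges):
        a = dec.dec_loglik(two_tip_tree, two_tip_ranges, dec.DECParams(0.3, 0.1, 0.0))
        b = dec.dec_loglik(two_tip_tree, two_tip_ranges, dec.DECParams(0.3, 0.1))
        assert a == pytest.approx(b, abs=1e-10)


class TestFit:
    def test_seeded_determinism(self):
        tree = balanced_ultrametric(3)
        rm, _ = dec.simulate_ranges(tree, list("ab"), dec.DECParams(0.3, 0.02),
                                    root_range=["a"], seed=5)
        f1 = dec.fit_dec(tree, rm, "DEC", seed=2)
        f2 = dec.fit_dec(tree, rm, "DEC", seed=2)
        assert f1.params.d == f2.params.d and f1.params.e == f2.params.e

    def test_decj_likelihood_dominates_dec(self):
        tree = balanced_ultrametric(3)
        rm, _ = dec.simulate_ranges(tree, list("abc"), dec.DECParams(0.3, 0.02),
                                    root_range=["b"], seed=7)
        f = dec.fit_dec(tree, rm, "DEC", seed=1)
        fj = dec.fit_dec(tree, rm, "DEC+J", seed=1)
        assert fj.loglik >= f.loglik - 1e-6
        assert fj.aic == pytest.approx(6 - 2 * fj.loglik)

    def test_dispersal_rate_rank_recovered(self):
        """d-hat rank-correlates with planted d across a 3-point grid."""
        tree = balanced_ultrametric(4)
        med = []
        for d_true in (0.05, 0.2, 0.6):
            ests = []
            for k in range(6):
                rm, _ = dec.simulate_ranges(tree, list("abc"),
                                            dec.DECParams(d_true, 0.01),
                                            root_range=["a"], seed=50 * k + 3)
                ests.append(dec.fit_dec(tree, rm, "DEC", seed=k).params.d)
            med.append(np.median(ests))
        assert med[0] < med[1] < med[2]


class TestForwardSimulation:
    def test_no_rates_no_events(self):
        tree = balanced_ultrametric(3)
        rm, log = dec.simulate_ranges(tree, ["a", "b"], dec.DECParams(0, 0),
                                      root_range=["a"], seed=0)
        assert log.events == []
        assert (rm.table["a"] == 1).all() and (rm.table["b"] == 0).all()

    def test_high_dispersal_fills_ranges(self):
        tree = balanced_ultrametric(3)
        rm, _ = dec.simulate_ranges(tree, ["a", "b"], dec.DECParams(5.0, 0.0),
                                    root_range=["a"], seed=1)
        assert rm.table.to_numpy().mean() > 0.9

    def test_seeded_reproducibility(self):
        tree = balanced_ultrametric(3)
        a = dec.simulate_ranges(tree, list("abc"), dec.DECParams(0.3, 0.05),
                                root_range=["a"], seed=11)
        b = dec.simulate_ranges(tree, list("abc"), dec.DECParams(0.3, 0.05),
                                root_range=["a"], seed=11)
        assert a[0].table.equals(b[0].table)
        assert a[1].events == b[1].events

    def test_extinction_retry_cap(self):
        tree = balanced_ultrametric(2)
        with pytest.raises(RuntimeError, match="lower e"):
            dec.simulate_ranges(tree, ["a", "b"], dec.DECParams(0.0, 50.0),
                                root_range=["a"], seed=0, max_retries=5)


class TestStochasticMap:
    def test_zero_dispersal_zero_counts(self):
        tree = balanced_ultrametric(3)
        rm = dec.RangeMatrix(pd.DataFrame(
            {"a": 1, "b": 0}, index=sorted(tree.tip_labels)))
        res = dec.stochastic_map(tree, rm, dec.DECParams(0.0, 0.0), n_maps=10, seed=0)
        assert np.allclose(res.dispersal_counts.to_numpy(), 0)

    def test_counts_nonnegative_and_seeded(self):
        tree = balanced_ultrametric(3)
        rm, _ = dec.simulate_ranges(tree, list("abc"), dec.DECParams(0.3, 0.02),
                                    root_range=["a"], seed=2)
        r1 = dec.stochastic_map(tree, rm, dec.DECParams(0.3, 0.02), n_maps=10, seed=4)
        r2 = dec.stochastic_map(tree, rm, dec.DECParams(0.3, 0.02), n_maps=10, seed=4)
        assert (r1.dispersal_counts.to_numpy() >= 0).all()
        assert r1.dispersal_counts.equals(r2.dispersal_counts)

    def test_uniformization_path_endpoint_consistency(self):
        """The uniformization sampler produces paths with the required endpoints."""
        sp = dec.DECStateSpace(["a", "b"])
        Q = dec.build_Q(dec.DECParams(0.4, 0.2), sp)
        P = expm(Q * 1.0)
        rng = random.Random(0)
        for _ in range(200):
            s, j = 1, 3  # {a} -> {a,b} in index space
            path = dec._sample_path_uniformization(Q, P, s, j, 1.0, rng)
            cur = s
            for _t, frm, to in path:
                assert frm == cur
                cur = to
            assert cur == j
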