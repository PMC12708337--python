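import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from mitocongruence.simulate import simulate_alignment
from mitocongruence.toptests import (
    CongruenceDecision,
    DEFAULT_AU_SCALES,
    TestConfig,
    au_from_bootstrap_proportions,
    au_test,
    bp_rell,
    elw,
    ild_test,
    kh_test,
    reciprocal_congruence,
    rell_resample,
    sh_test,
)
from mitocongruence.tree import sample_species_tree


def _two_tree_sll(rng, n=400, shift=0.0):
    base = np.log(rng.random(n)) - 2.0
    other = base + rng.normal(shift, 0.3, size=n)
    return np.vstack([base, other])


class TestRell:
    def test_identical_vectors_identical_totals(self, rng):
        v = np.log(rng.random(50)) - 1
        sll = np.vstack([v, v])
        totals = rell_resample(sll, 200, 1.0, seed=1)
        assert np.allclose(totals[:, 0], totals[:, 1])

    def test_two_site_exhaustive_draw_space(self):
        """With 2 sites the bootstrap draw space has 3 outcomes with
        probabilities 1/4, 1/2, 1/4; frequencies must match."""
        sll = np.array([[np.log(0.2), np.log(0.05)]])
        a, b = sll[0]
        totals = rell_resample(sll, 40000, 1.0, seed=2)[:, 0]
        expected = {2 * a: 0.25, a + b: 0.5, 2 * b: 0.25}
        for value, prob in expected.items():
            freq = np.isclose(totals, value).mean()
            sd = np.sqrt(prob * (1 - prob) / 40000)
            assert abs(freq - prob) < 4 * sd

    def test_bootstrap_mean_near_observed_total(self, rng):
        sll = _two_tree_sll(rng, n=300)
        totals = rell_resample(sll, 20000, 1.0, seed=3)
        for m in range(2):
            se = sll[m].std(ddof=1) * np.sqrt(300)
            boot_se = se / np.sqrt(20000)
            assert abs(totals[:, m].mean() - sll[m].sum()) < 4 * boot_se

    def test_scale_changes_draw_size(self, rng):
        sll = _two_tree_sll(rng, n=100)
        half = rell_resample(sll, 2000, 0.5, seed=4)
        full = rell_resample(sll, 2000, 1.0, seed=4)
        # half-size draws have roughly half the total magnitude
        assert abs(half.mean() / full.mean() - 0.5) < 0.05

    def test_rejects_bad_args(self, rng):
        sll = _two_tree_sll(rng, n=10)
        with pytest.raises(ValueError):
            rell_resample(sll, 0, 1.0)
        with pytest.raises(ValueError):
            rell_resample(sll, 10, 0.0)


class TestKhSh:
    def test_identical_vectors_give_p_one(self, rng):
        v = np.log(rng.random(80)) - 1
        sll = np.vstack([v, v])
        for weighted in (False, True):
            assert (kh_test(sll, 500, 1, weighted) == 1.0).all()
            assert (sh_test(sll, 500, 1, weighted) == 1.0).all()

    def test_sh_dominates_kh(self, rng):
        """Multiplicity correction: p_sh >= p_kh for every tree."""
        for rep in range(10):
            sll = np.vstack(
                [
                    np.log(rng.random(200)) - 2,
                    np.log(rng.random(200)) - 2,
                    np.log(rng.random(200)) - 2,
                ]
            )
            totals = rell_resample(sll, 1000, 1.0, seed=rep)
            p_kh = kh_test(sll, 1000, totals=totals)
            p_sh = sh_test(sll, 1000, totals=totals)
            assert (p_sh >= p_kh - 1e-12).all()

    def test_probabilities_in_unit_interval(self, rng):
        sll = _two_tree_sll(rng, shift=0.05)
        for f in (kh_test, sh_test):
            p = f(sll, 500, 7)
            assert ((0 <= p) & (p <= 1)).all()

    def test_strongly_dominated_tree_rejected(self, rng):
        sll = _two_tree_sll(rng, n=1000, shift=-0.1)
        # tree 1 is uniformly ~0.1 logL/site worse
        p = kh_test(sll, 2000, 11)
        assert p[1] < 0.01
        assert p[0] > 0.4


class TestElw:
    def test_symmetry_and_sum(self, rng):
        v = np.log(rng.random(100)) - 1
        w = elw(np.vstack([v, v]), 1000, 3)
        assert np.allclose(w, 0.5, atol=1e-12)
        sll = _two_tree_sll(rng, shift=0.02)
        w = elw(sll, 1000, 4)
        assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_dominant_tree_takes_all_weight(self, rng):
        base = np.log(rng.random(1000)) - 2
        sll = np.vstack([base + 0.1, base])
        w = elw(sll, 2000, 5)
        assert w[0] > 0.999


class TestAu:
    def test_symmetric_case_gives_half(self):
        bps = np.full((10, 2), 0.5)
        res = au_from_bootstrap_proportions(bps, DEFAULT_AU_SCALES, 10**5)
        assert np.allclose(res.p_values, 0.5, atol=1e-9)
        assert not res.fallback.any()

    def test_forward_model_recovery(self):
        """bp_r generated from known curvature (d, c) = (1.2, 0.3)
        recover p = 1 - Phi(0.9)."""
        d, c = 1.2, 0.3
        scales = np.asarray(DEFAULT_AU_SCALES)
        bps = 1.0 - ndtr(d * np.sqrt(scales) + c / np.sqrt(scales))
        res = au_from_bootstrap_proportions(
            bps[:, None], scales, 10**5
        )
        assert res.p_values[0] == pytest.approx(1 - ndtr(0.9), abs=0.02)

    def test_identical_vectors_nonrejecting(self, rng):
        v = np.log(rng.random(60)) - 1
        res = au_test(np.vstack([v, v]), 1000, seed=9)
        assert (res.p_values >= 0.5 - 1e-9).all()

    def test_degenerate_fallback_flagged(self, rng):
        base = np.log(rng.random(800)) - 2
        sll = np.vstack([base + 0.5, base])  # hopeless underdog
        res = au_test(sll, 500, seed=10)
        assert res.fallback[1]
        assert res.p_values[1] == 0.0


class TestIld:
    def test_copy_partition_gives_d_zero_p_one(self, tree6, mito_model):
        aln = simulate_alignment(tree6, mito_model, 150, seed=40)
        res = ild_test(aln, aln, n_permutations=19, seed=1)
        assert res.d_observed == 0
        assert res.p_value == 1.0

    def test_p_value_range_and_determinism(self, tree6, mito_model):
        a = simulate_alignment(tree6, mito_model, 120, seed=41)
        b = simulate_alignment(tree6, mito_model, 120, seed=42)
        r1 = ild_test(a, b, n_permutations=49, seed=3)
        r2 = ild_test(a, b, n_permutations=49, seed=3)
        assert 0 < r1.p_value <= 1
        assert r1.d_observed == r2.d_observed
        assert r1.p_value == r2.p_value

    def test_constant_partition_low_signal(self, tree6):
        from mitocongruence.alignment import Alignment

        taxa = sorted(tree6.leaf_labels())
        const = Alignment.from_sequences({t: "AAAA" for t in taxa})
        res = ild_test(const, const, n_permutations=9, seed=1)
        assert res.low_signal
        assert res.p_value == 1.0


class TestReciprocal:
    def test_copy_is_congruent_for_every_test(self, tree6, mito_model):
        aln = simulate_alignment(tree6, mito_model, 300, seed=50)
        cfg = TestConfig(b_reps=300, restarts=1, optimize_rates=False,
                        final_rounds=1, run_ild=True)
        res = reciprocal_congruence(aln, aln, cfg, seed=1)
        for test, dec in res.decisions.items():
            assert dec.call == "congruent", test

    def test_decision_three_state_logic(self):
        assert CongruenceDecision("p_au", True, True, 0.05).call == (
            "incongruent"
        )
        assert CongruenceDecision("p_au", False, False, 0.05).call == (
            "congruent"
        )
        assert CongruenceDecision("p_au", True, False, 0.05).call == (
            "ambiguous"
        )
        assert CongruenceDecision("p_au", False, True, 0.05).call == (
            "ambiguous"
        )


@settings(max_examples=15, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 2**16),
    n=st.integers(5, 120),
    shift=st.floats(-0.2, 0.2),
)
def test_battery_probability_invariants(seed, n, shift):
    """All p-values lie in [0,1]; bp-RELL and c-ELW normalize to 1."""
    rng = np.random.default_rng(seed)
    sll = _two_tree_sll(rng, n=n, shift=shift)
    totals = rell_resample(sll, 400, 1.0, seed=seed)
    assert bp_rell(sll, 400, totals=totals).sum() == pytest.approx(
        1.0, abs=1 / 400
    )
    assert elw(sll, 400, totals=totals).sum() == pytest.approx(
        1.0, abs=1e-6
    )
    for f in (kh_test, sh_test):
        p = f(sll, 400, seed, totals=totals)
        assert ((0 <= p) & (p <= 1)).all()
    p_au = au_test(sll, 200, seed=seed).p_values
    assert ((0 <= p_au) & (p_au <= 1)).all()
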