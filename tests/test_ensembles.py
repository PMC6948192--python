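"""Minimal-ensemble search, MEM weighting and R_G summaries."""

import numpy as np
import pytest

from saxsemble import (EnsembleModel, SaxsProfile, fit_weights, mem_weights,
                       rg_summary, search_minimal_ensemble)
from saxsemble.ensembles import _beam_search, _exhaustive, _prepare


def profile_from(pool, weights_by_index, noise=0.0, seed=0, sigma_frac=0.005):
    """Weighted mixture of pool component profiles as a data profile."""
    q = pool.q
    I = np.zeros(q.size)
    for i, w in weights_by_index.items():
        I += w * pool.component_profiles[i]
    s = sigma_frac * I[0] * np.ones(q.size)
    if noise:
        rng = np.random.default_rng(seed)
        I = I + rng.normal(scale=noise * I[0], size=q.size)
    return SaxsProfile(q, I, sigma=s)


class TestFitWeights:
    def test_pure_member_gets_all_weight(self, small_pool):
        data = profile_from(small_pool, {4: 1.0})
        we = fit_weights(small_pool.component_profiles, data)
        assert we.weights[4] == pytest.approx(1.0, abs=1e-6)
        assert we.score.chi2 == pytest.approx(0.0, abs=1e-10)

    def test_two_component_mixture_recovered(self, small_pool):
        iA = int(np.argmin(small_pool.rgs))
        iB = int(np.argmax(small_pool.rgs))
        data = profile_from(small_pool, {iA: 0.3, iB: 0.7}, noise=0.005, seed=1)
        we = fit_weights(small_pool.component_profiles[[iA, iB]], data,
                         member_indices=(iA, iB))
        assert we.weights[0] == pytest.approx(0.3, abs=0.05)
        assert we.weights[1] == pytest.approx(0.7, abs=0.05)

    def test_weights_are_simplex(self, small_pool):
        rng = np.random.default_rng(2)
        data = SaxsProfile(
            small_pool.q,
            np.abs(rng.normal(1, 0.3, small_pool.q.size)) + 0.1,
            sigma=np.full(small_pool.q.size, 0.05))
        we = fit_weights(small_pool.component_profiles, data)
        assert np.all(we.weights >= 0)
        assert we.weights.sum() == pytest.approx(1.0)

    def test_duplicate_members_tie_break_to_lowest_index(self, small_pool):
        dup = small_pool.component_profiles[[3, 3]]
        data = profile_from(small_pool, {3: 1.0})
        with pytest.warns(UserWarning):
            we = fit_weights(dup, data, member_indices=(3, 7))
        assert we.weights[0] == pytest.approx(1.0)
        assert we.weights[1] == 0.0


class TestMinimalEnsembleSearch:
    def test_beam_equals_exhaustive_on_15_pool(self, small_pool):
        data = profile_from(small_pool, {2: 0.6, 11: 0.4}, noise=0.002, seed=3)
        Aw, yw = _prepare(data, small_pool.component_profiles)
        ex = _exhaustive(Aw, yw, 2)
        beam = _beam_search(Aw, yw, 2, 100)
        for k in (1, 2):
            assert ex[k][0] == beam[k][0]
            assert ex[k][2] == pytest.approx(beam[k][2], rel=1e-10)

    def test_single_member_truth_selected_at_k1(self, small_pool):
        data = profile_from(small_pool, {6: 1.0}, noise=0.001, seed=4)
        ens = search_minimal_ensemble(small_pool, data, kmax=2)
        assert ens[1].member_indices == (6,)
        assert ens[1].score.chi2 < 1.0

    def test_chi2_non_increasing_in_k(self, medium_pool):
        data = profile_from(medium_pool, {0: 0.5, 30: 0.3, 59: 0.2},
                            noise=0.01, seed=5)
        ens = search_minimal_ensemble(medium_pool, data, kmax=6, force="beam")
        chi2s = [ens[k].score.chi2 for k in sorted(ens)]
        assert all(a >= b - 1e-12 for a, b in zip(chi2s, chi2s[1:]))

    def test_three_state_truth_recovered(self, medium_pool):
        # truth members span >= 3-fold R_G range; 1% noise
        order = np.argsort(medium_pool.rgs)
        members = [int(order[0]), int(order[30]), int(order[-1])]
        assert medium_pool.rgs[members[-1]] / medium_pool.rgs[members[0]] > 2
        w_true = {members[0]: 0.5, members[1]: 0.3, members[2]: 0.2}
        data = profile_from(medium_pool, w_true, noise=0.01, seed=6,
                            sigma_frac=0.01)
        ens = search_minimal_ensemble(medium_pool, data, kmax=3, force="beam")
        got = ens[3]
        rgs_got = sorted(medium_pool.rgs[list(got.member_indices)])
        rgs_true = sorted(medium_pool.rgs[members])
        for a, b in zip(rgs_got, rgs_true):
            assert a == pytest.approx(b, rel=0.05)
        w_got = {i: w for i, w in zip(got.member_indices, got.weights)}
        for i, w in w_true.items():
            near = [w_got.get(j, 0.0) for j in got.member_indices
                    if abs(medium_pool.rgs[j] - medium_pool.rgs[i])
                    <= 0.05 * medium_pool.rgs[i]]
            assert sum(near) == pytest.approx(w, abs=0.1)

    def test_kmax_clipped_with_warning(self, small_pool):
        data = profile_from(small_pool, {1: 1.0})
        with pytest.warns(UserWarning):
            ens = search_minimal_ensemble(small_pool, data, kmax=20,
                                          force="beam")
        assert max(ens) <= len(small_pool)


class TestMemWeights:
    def test_loose_target_returns_uniform_prior(self, small_pool):
        data = profile_from(small_pool, {4: 1.0}, noise=0.01, seed=7)
        mw = mem_weights(small_pool, data, chi2_target=1e8)
        np.testing.assert_allclose(mw.weights, 1.0 / len(small_pool))
        assert mw.entropy == pytest.approx(np.log(len(small_pool)))

    def test_entropy_monotone_in_target(self, medium_pool):
        data = profile_from(medium_pool, {0: 0.5, 30: 0.5}, noise=0.01,
                            seed=8, sigma_frac=0.01)
        ens = search_minimal_ensemble(medium_pool, data, kmax=2, force="beam")
        base = ens[2].score.chi2
        entropies = [mem_weights(medium_pool, data, chi2_target=t).entropy
                     for t in (base * 1.5, base * 4.0, base * 40.0)]
        assert entropies[0] <= entropies[1] <= entropies[2]

    def test_infeasible_target_rejected(self, small_pool):
        data = profile_from(small_pool, {4: 1.0}, noise=0.05, seed=9)
        with pytest.raises(ValueError, match="infeasible"):
            mem_weights(small_pool, data, chi2_target=1e-12)

    def test_chi2_constraint_met(self, medium_pool):
        data = profile_from(medium_pool, {5: 0.6, 50: 0.4}, noise=0.01,
                            seed=10, sigma_frac=0.01)
        ens = search_minimal_ensemble(medium_pool, data, kmax=2, force="beam")
        target = ens[2].score.chi2 * 1.2
        mw = mem_weights(medium_pool, data, chi2_target=target)
        assert mw.chi2_achieved <= target * (1.0 + 1e-3)
        assert np.all(mw.weights >= 0)
        assert mw.weights.sum() == pytest.approx(1.0)
        assert mw.entropy <= np.log(len(medium_pool)) + 1e-9


class TestRgSummary:
    def test_uniform_weights_mean(self):
        s = rg_summary(np.array([0.5, 0.5]), np.array([40.0, 60.0]), bins=5)
        assert s["mean_rg"] == pytest.approx(50.0)

    def test_skewed_weights_mean(self):
        s = rg_summary(np.array([0.9, 0.1]), np.array([40.0, 60.0]), bins=5)
        assert s["mean_rg"] == pytest.approx(42.0)

    def test_histogram_mass_is_one(self):
        rng = np.random.default_rng(11)
        w = rng.dirichlet(np.ones(50))
        rgs = rng.uniform(20, 80, 50)
        s = rg_summary(w, rgs, bins=10)
        assert s["hist"].sum() == pytest.approx(1.0)
        assert sum(s["percent"].values()) == pytest.approx(100.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rg_summary(np.array([1.0]), np.array([40.0, 60.0]))


class TestEnsembleModelFacade:
    def test_fit_and_summary(self, small_pool):
        data = profile_from(small_pool, {4: 0.7, 9: 0.3}, noise=0.005, seed=12)
        model = EnsembleModel(data, small_pool)
        res = model.fit(kmax=2)
        assert set(res.ensembles) == {1, 2}
        text = res.summary()
        assert "chi2" in text and "k" in text

    def test_mem_from_minimal_target(self, small_pool):
        data = profile_from(small_pool, {4: 0.7, 9: 0.3}, noise=0.005, seed=12)
        model = EnsembleModel(data, small_pool)
        res = model.fit(kmax=2)
        memres = model.fit_mem(minimal=res)
        assert memres.mem.chi2_achieved <= res.ensembles[2].score.chi2 * 1.001
        assert "R_G" in memres.summary()
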