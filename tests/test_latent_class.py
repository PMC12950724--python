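"""Latent class model: likelihood oracle, Gibbs correctness, diagnostics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrilcm.criteria import ValidationError
from nutrilcm.latent_class import (
    CrossClassTable,
    LCMParams,
    LCMPriors,
    PosteriorDraws,
    all_cell_probabilities,
    build_cross_class,
    cell_probability,
    converged,
    enforce_orientation,
    gelman_rubin,
    gibbs_fit,
    summarize,
)


def enumeration_oracle(pi, se, sp, pattern_bits):
    """Brute-force P(pattern): sum over the two latent classes explicitly."""
    total = 0.0
    for status in (0, 1):
        p_class = pi if status == 1 else 1 - pi
        p_obs = 1.0
        for k, y in enumerate(pattern_bits):
            p_pos = se[k] if status == 1 else 1 - sp[k]
            p_obs *= p_pos if y == 1 else 1 - p_pos
        total += p_class * p_obs
    return total


class TestCellProbability:
    def test_perfect_tests(self):
        p = LCMParams(0.3, (1, 1, 1), (1, 1, 1))
        assert cell_probability(p, (1, 1, 1)) == pytest.approx(0.3)
        assert cell_probability(p, (0, 0, 0)) == pytest.approx(0.7)
        assert cell_probability(p, (1, 0, 0)) == 0.0

    def test_coin_flip_tests_uniform(self):
        p = LCMParams(0.5, (0.5, 0.5, 0.5), (0.5, 0.5, 0.5))
        for idx in range(8):
            assert cell_probability(p, idx) == pytest.approx(0.125)

    def test_matches_enumeration_oracle_at_study_params(self):
        se, sp = (0.8, 0.84, 0.57), (0.99, 0.43, 0.81)
        p = LCMParams(0.25, se, sp)
        for bits in itertools.product((0, 1), repeat=3):
            expected = enumeration_oracle(0.25, se, sp, bits)
            assert cell_probability(p, bits) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=1000, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_random_params_sum_to_one_and_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pi = rng.uniform(0.01, 0.99)
        se = rng.uniform(0.01, 0.99, 3)
        sp = rng.uniform(0.01, 0.99, 3)
        params = LCMParams(pi, se, sp)
        probs = all_cell_probabilities(params)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        bits = tuple(int(b) for b in rng.integers(0, 2, 3))
        assert cell_probability(params, bits) == pytest.approx(
            enumeration_oracle(pi, se, sp, bits), abs=1e-12
        )

    def test_mirror_invariance(self):
        """Swapping classes (pi->1-pi, Se<->1-Sp) leaves every cell unchanged."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            pi, se, sp = rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95, 3), rng.uniform(0.05, 0.95, 3)
            a = all_cell_probabilities(LCMParams(pi, se, sp))
            b = all_cell_probabilities(LCMParams(1 - pi, 1 - sp, 1 - se))
            np.testing.assert_allclose(a, b, atol=1e-14)

    def test_invalid_probability_names_field(self):
        with pytest.raises(ValidationError, match="se\\[1\\]"):
            LCMParams(0.5, (0.5, 1.5, 0.5), (0.5, 0.5, 0.5))


class TestBuildCrossClass:
    def test_small_example(self):
        t = build_cross_class([(1, 1, 1), (0, 0, 0), (1, 1, 1)])
        assert t.counts[7] == 2 and t.counts[0] == 1 and t.counts.sum() == 3

    def test_pattern_index_convention(self):
        # (PG-SGA=1, ESPEN=0, GLIM=1) -> index 1 + 4 = 5
        t = build_cross_class([(1, 0, 1)])
        assert t.counts[5] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            build_cross_class([])

    def test_non_binary_rejected(self):
        with pytest.raises(ValidationError, match="patient 1"):
            build_cross_class([(0, 0, 0), (0, 2, 0)])

    def test_counts_match_cell_probabilities(self):
        params = LCMParams(0.25, (0.8, 0.84, 0.57), (0.99, 0.43, 0.81))
        probs = all_cell_probabilities(params)
        rng = np.random.default_rng(11)
        n = 10_000
        status = rng.random(n) < 0.25
        se, sp = np.array(params.se), np.array(params.sp)
        p_pos = np.where(status[:, None], se, 1 - sp)
        panels = (rng.random((n, 3)) < p_pos).astype(int)
        t = build_cross_class(panels)
        freq = t.counts / n
        se_freq = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(freq - probs) < 3 * se_freq + 1e-9)


class TestGibbs:
    def test_reproducible_given_seeds(self):
        table = CrossClassTable(3, [500, 60, 100, 40, 80, 30, 50, 140])
        d1 = gibbs_fit(table, chains=2, iterations=300, burn_in=100, seeds=(5, 6))
        d2 = gibbs_fit(table, chains=2, iterations=300, burn_in=100, seeds=(5, 6))
        np.testing.assert_array_equal(d1.draws, d2.draws)

    def test_iterations_must_exceed_burnin(self):
        table = CrossClassTable(3, [1] * 8)
        with pytest.raises(ValidationError):
            gibbs_fit(table, iterations=100, burn_in=100)

    def test_seed_count_must_match_chains(self):
        table = CrossClassTable(3, [1] * 8)
        with pytest.raises(ValidationError, match="seed"):
            gibbs_fit(table, chains=3, iterations=200, burn_in=50, seeds=(1,))

    def test_degenerate_all_positive_table(self):
        """All patients positive on all tests: prevalence posterior ~ 1."""
        counts = np.zeros(8, dtype=int)
        counts[7] = 500
        table = CrossClassTable(3, counts)
        draws = gibbs_fit(table, chains=3, iterations=2000, burn_in=500, seeds=(1, 2, 3))
        draws = enforce_orientation(draws)
        s = summarize(draws)
        assert s["prevalence"]["median"] > 0.9

    def test_k1_conjugate_closed_form(self):
        """With Se=Sp pinned at ~1 by a point-mass prior, the prevalence
        posterior must match the conjugate Beta(a+pos, b+neg)."""
        pos, neg = 70, 130
        table = CrossClassTable(1, [neg, pos])
        strong = np.array([[1e6, 1.0]])
        priors = LCMPriors(prevalence=(1.0, 1.0), se=strong, sp=strong)
        draws = gibbs_fit(
            table, priors, chains=3, iterations=30_000, burn_in=5_000, seeds=(1, 2, 3)
        )
        s = summarize(draws)["prevalence"]
        from scipy import stats

        post = stats.beta(1 + pos, 1 + neg)
        assert s["mean"] == pytest.approx(post.mean(), abs=0.01)
        assert s["cri_lower"] == pytest.approx(post.ppf(0.025), abs=0.015)
        assert s["cri_upper"] == pytest.approx(post.ppf(0.975), abs=0.015)

    def test_k2_flat_priors_warns_unidentifiable(self):
        table = CrossClassTable(2, [50, 20, 20, 50])
        with pytest.warns(UserWarning, match="not identifiable"):
            gibbs_fit(table, chains=2, iterations=200, burn_in=50, seeds=(1, 2))

    def test_k2_grid_posterior_oracle(self):
        """Gibbs marginal means match a brute-force grid posterior on a
        small K=2 table with one test pinned by strong priors."""
        rng = np.random.default_rng(3)
        pi_true, se1, sp1 = 0.4, 0.85, 0.9
        se2 = sp2 = 0.9
        probs = np.zeros(4)
        for idx in range(4):
            y = [(idx >> k) & 1 for k in range(2)]
            probs[idx] = enumeration_oracle(pi_true, (se1, se2), (sp1, sp2), y)
        counts = rng.multinomial(200, probs)
        table = CrossClassTable(2, counts)

        pin = np.array([[9000.0, 1000.0]])  # Beta mean 0.9, sd ~0.003
        priors = LCMPriors(prevalence=(1.0, 1.0), se=np.vstack([[1, 1], pin]), sp=np.vstack([[1, 1], pin]))
        draws = gibbs_fit(table, priors, chains=3, iterations=20_000, burn_in=5_000, seeds=(7, 8, 9))
        draws = enforce_orientation(draws)
        s = summarize(draws)

        # grid posterior over (pi, se1, sp1) with test 2 fixed at 0.9
        grid = np.linspace(0.005, 0.995, 100)
        P, SE, SP = np.meshgrid(grid, grid, grid, indexing="ij")
        logpost = np.zeros_like(P)
        for idx in range(4):
            y1, y2 = idx & 1, (idx >> 1) & 1
            p1 = np.where(y1, SE, 1 - SE)
            q1 = np.where(y1, 1 - SP, SP)
            p2 = se2 if y2 else 1 - se2
            q2 = (1 - sp2) if y2 else sp2
            cell = P * p1 * p2 + (1 - P) * q1 * q2
            logpost += counts[idx] * np.log(cell)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        gm = {
            "prevalence": float((w * P).sum()),
            "se_T1": float((w * SE).sum()),
            "sp_T1": float((w * SP).sum()),
        }
        for name in gm:
            assert s[name]["mean"] == pytest.approx(gm[name], abs=0.02), name

    def test_k_too_large_refused(self):
        table = CrossClassTable(13, [1] * 2**13)
        with pytest.raises(ValidationError, match="K > 12"):
            gibbs_fit(table, chains=2, iterations=100, burn_in=10, seeds=(1, 2))


class TestSummarize:
    def test_constant_draws(self):
        d = PosteriorDraws(np.full((2, 200, 7), 0.5), 3, 0, (1, 2))
        s = summarize(d)
        for row in s.values():
            assert row["mean"] == row["median"] == row["cri_lower"] == row["cri_upper"] == 0.5

    def test_uniform_grid_percentiles(self):
        grid = np.linspace(0.01, 0.99, 99)
        draws = np.tile(grid.reshape(1, -1, 1), (2, 1, 3))
        d = PosteriorDraws(draws, 1, 0, (1, 2))
        s = summarize(d)["prevalence"]
        lo = float(np.percentile(np.concatenate([grid, grid]), 2.5))
        hi = float(np.percentile(np.concatenate([grid, grid]), 97.5))
        assert s["cri_lower"] == pytest.approx(lo)
        assert s["cri_upper"] == pytest.approx(hi)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.beta(3, 2, size=(2, 500, 3))
        s1 = summarize(PosteriorDraws(x, 1, 0, (1, 2)))
        s2 = summarize(PosteriorDraws(1 - x, 1, 0, (1, 2)))
        for name1, name2 in zip(s1, s2):
            assert s1[name1]["mean"] == pytest.approx(1 - s2[name2]["mean"])
            assert s1[name1]["cri_lower"] == pytest.approx(1 - s2[name2]["cri_upper"])

    def test_too_few_draws_rejected(self):
        d = PosteriorDraws(np.full((2, 10, 3), 0.5), 1, 0, (1, 2))
        with pytest.raises(ValidationError):
            summarize(d)


class TestGelmanRubin:
    def test_identical_chains_formula(self):
        """Two identical chains: B=0 so R-hat = sqrt((n-1)/n) exactly."""
        rng = np.random.default_rng(2)
        x = rng.beta(2, 2, size=(1, 500, 3))
        d = PosteriorDraws(np.repeat(x, 2, axis=0), 1, 0, (1, 2))
        rep = gelman_rubin(d)
        n = 500
        for row in rep.values():
            assert row["B"] == pytest.approx(0.0, abs=1e-15)
            assert row["rhat"] == pytest.approx(np.sqrt((n - 1) / n), abs=1e-12)

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(4)
        d = PosteriorDraws(rng.beta(5, 5, size=(3, 10_000, 3)), 1, 0, (1, 2, 3))
        rep = gelman_rubin(d)
        for row in rep.values():
            assert row["rhat"] < 1.01
        assert converged(rep)

    def test_disjoint_constant_chains_infinite(self):
        draws = np.concatenate(
            [np.full((1, 100, 3), 0.2), np.full((1, 100, 3), 0.8)], axis=0
        )
        d = PosteriorDraws(draws, 1, 0, (1, 2))
        with pytest.warns(UserWarning, match="zero within-chain variance"):
            rep = gelman_rubin(d)
        assert all(np.isinf(row["rhat"]) for row in rep.values())
        assert not converged(rep)

    def test_single_chain_rejected(self):
        d = PosteriorDraws(np.full((1, 100, 3), 0.5), 1, 0, (1,))
        with pytest.raises(ValidationError, match="2 chains"):
            gelman_rubin(d)


class TestOrientation:
    def _random_draws(self, seed, n=400):
        rng = np.random.default_rng(seed)
        pi = rng.beta(3, 9, size=(2, n, 1))
        se = rng.beta(16, 4, size=(2, n, 3))
        sp = rng.beta(18, 2, size=(2, n, 3))
        return PosteriorDraws(np.concatenate([pi, se, sp], axis=2), 3, 0, (1, 2))

    def test_already_oriented_unchanged(self):
        d = self._random_draws(1)
        out = enforce_orientation(d)
        np.testing.assert_array_equal(out.draws, d.draws)
        assert out.orientation_flipped_fraction == 0.0

    def test_fully_mirrored_mapped_back(self):
        d = self._random_draws(2)
        mirrored = d.draws.copy()
        mirrored[:, :, 0] = 1 - d.draws[:, :, 0]
        mirrored[:, :, 1:4] = 1 - d.draws[:, :, 4:7]
        mirrored[:, :, 4:7] = 1 - d.draws[:, :, 1:4]
        out = enforce_orientation(PosteriorDraws(mirrored, 3, 0, (1, 2)))
        np.testing.assert_allclose(out.draws, d.draws, atol=1e-14)
        assert out.orientation_flipped_fraction == 1.0

    def test_mirror_preserves_likelihood(self):
        d = self._random_draws(3)
        mirrored = d.draws.copy()
        mirrored[:, :, 0] = 1 - d.draws[:, :, 0]
        mirrored[:, :, 1:4] = 1 - d.draws[:, :, 4:7]
        mirrored[:, :, 4:7] = 1 - d.draws[:, :, 1:4]
        for c, i in [(0, 0), (1, 17), (0, 250)]:
            a = all_cell_probabilities(
                LCMParams(d.draws[c, i, 0], d.draws[c, i, 1:4], d.draws[c, i, 4:7])
            )
            b = all_cell_probabilities(
                LCMParams(mirrored[c, i, 0], mirrored[c, i, 1:4], mirrored[c, i, 4:7])
            )
            np.testing.assert_allclose(a, b, atol=1e-14)

    def test_mixed_label_chains_repaired(self):
        """One chain mirrored, one not: after relabeling the chain means agree."""
        d = self._random_draws(4, n=2000)
        mixed = d.draws.copy()
        mixed[1, :, 0] = 1 - d.draws[1, :, 0]
        mixed[1, :, 1:4] = 1 - d.draws[1, :, 4:7]
        mixed[1, :, 4:7] = 1 - d.draws[1, :, 1:4]
        out = enforce_orientation(PosteriorDraws(mixed, 3, 0, (1, 2)))
        m0 = out.draws[0].mean(axis=0)
        m1 = out.draws[1].mean(axis=0)
        np.testing.assert_allclose(m0, m1, atol=0.03)
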