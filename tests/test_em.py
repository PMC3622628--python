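import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demixem.em import (
    EMConfig,
    LatentPosterior,
    SufficientStats,
    ZeroLikelihoodRead,
    batch_em_oracle,
    e_step_mixed,
    e_step_pure,
    interpolate_stats,
    m_step,
    run_online_em,
    run_single_em,
    step_size,
)
from demixem.model import (
    EffectiveLengths,
    FragmentModel,
    ModelParams,
    SamplingProfile,
    effective_lengths,
    rho_to_alpha,
)
from demixem.simulate import (
    SimConfig,
    generate_abundances,
    generate_catalog,
    generate_mixture,
    generate_reads,
)
from conftest import make_group


def params_2t(alpha_a, alpha_b, tau_a, tau_b, **kw):
    return ModelParams(
        alpha_a=SamplingProfile(np.asarray(alpha_a, dtype=float)),
        alpha_b=SamplingProfile(np.asarray(alpha_b, dtype=float)),
        tau_a=tau_a,
        tau_b=tau_b,
        **kw,
    )


class TestEStepPure:
    def test_single_candidate(self, unit_lengths):
        p = params_2t([0.5, 0.5], [0.5, 0.5], 0.5, 0.5)
        post = e_step_pure(make_group("r", [(1, 0, False)]), p, unit_lengths)
        np.testing.assert_array_equal(post.q, [1.0])

    def test_hand_example(self):
        # alpha = (0.5, 0.5), l_eff = (100, 200) -> posteriors 2/3, 1/3
        p = params_2t([0.5, 0.5], [0.5, 0.5], 0.5, 0.5)
        le = EffectiveLengths(np.array([100.0, 200.0]))
        post = e_step_pure(make_group("r", [(0, 0, False), (1, 0, False)]), p, le)
        np.testing.assert_allclose(post.q, [2.0 / 3.0, 1.0 / 3.0], atol=1e-12)

    def test_non_candidate_has_zero_posterior(self, unit_lengths):
        p = params_2t([0.5, 0.5], [0.5, 0.5], 0.5, 0.5)
        post = e_step_pure(make_group("r", [(0, 0, False)]), p, unit_lengths)
        assert 1 not in post.transcripts
        assert post.q.sum() == pytest.approx(1.0)

    def test_zero_likelihood_raises(self, unit_lengths):
        p = params_2t([1.0, 0.0], [0.5, 0.5], 0.5, 0.5)
        with pytest.raises(ZeroLikelihoodRead):
            e_step_pure(make_group("r", [(1, 0, False)]), p, unit_lengths)


class TestEStepMixed:
    def test_tau_b_zero_kills_b_posteriors(self, unit_lengths):
        p = params_2t([0.5, 0.5], [0.5, 0.5], 1.0, 0.0)
        post = e_step_mixed(make_group("r", [(0, 0, False), (1, 0, False)]), p, unit_lengths)
        np.testing.assert_array_equal(post.q_b, [0.0, 0.0])
        assert post.q_a.sum() == pytest.approx(1.0)

    def test_hand_example_joint_normalization(self, unit_lengths):
        p = params_2t([0.8, 0.2], [0.2, 0.8], 0.5, 0.5)
        post = e_step_mixed(make_group("r", [(0, 0, False), (1, 0, False)]), p, unit_lengths)
        np.testing.assert_allclose(post.q_a, [0.4, 0.1], atol=1e-12)
        np.testing.assert_allclose(post.q_b, [0.1, 0.4], atol=1e-12)
        assert post.q_a.sum() + post.q_b.sum() == pytest.approx(1.0)

    def test_equal_alphas_split_by_tau(self, unit_lengths):
        p = params_2t([0.3, 0.7], [0.3, 0.7], 0.25, 0.75)
        post = e_step_mixed(make_group("r", [(0, 0, False), (1, 0, False)]), p, unit_lengths)
        np.testing.assert_allclose(post.q_b / post.q_a, 3.0)


class TestInterpolateStats:
    def make_stats(self):
        return SufficientStats(
            q_p=np.array([0.6, 0.4]),
            q_ma=np.array([0.3, 0.2]),
            q_mb=np.array([0.1, 0.4]),
        )

    def test_sigma_one_first_step_is_mean(self):
        stats = self.make_stats()
        post = LatentPosterior(transcripts=np.array([0]), q=np.array([1.0]))
        out = interpolate_stats(stats, post, n=0, forget_sigma=1.0)
        np.testing.assert_allclose(out.q_p, [(0.6 + 1.0) / 2, 0.2])

    def test_fixed_point(self):
        stats = self.make_stats()
        post = LatentPosterior(transcripts=np.array([0, 1]), q=np.array([0.6, 0.4]))
        out = interpolate_stats(stats, post, n=7, forget_sigma=0.85)
        np.testing.assert_allclose(out.q_p, stats.q_p, atol=1e-15)

    def test_scalar_oracle_sigma_085(self):
        gamma = 5.0 ** (-0.85)  # independent closed form for n = 3
        assert step_size(3, 0.85) == pytest.approx(gamma, rel=1e-15)
        stats = self.make_stats()
        post = LatentPosterior(
            transcripts=np.array([0, 1]),
            q_a=np.array([0.5, 0.25]),
            q_b=np.array([0.0, 0.25]),
        )
        out = interpolate_stats(stats, post, n=3, forget_sigma=0.85)
        np.testing.assert_allclose(
            out.q_ma, (1 - gamma) * np.array([0.3, 0.2]) + gamma * np.array([0.5, 0.25])
        )
        np.testing.assert_allclose(
            out.q_mb, (1 - gamma) * np.array([0.1, 0.4]) + gamma * np.array([0.0, 0.25])
        )
        np.testing.assert_array_equal(out.q_p, stats.q_p)

    @given(
        st.integers(min_value=2, max_value=8),
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=0.51, max_value=1.0),
        st.integers(min_value=0, max_value=2**31),
        st.booleans(),
    )
    @settings(max_examples=60, deadline=None)
    def test_normalization_preserved_property(self, T, n, sigma, seed, mixed):
        rng = np.random.default_rng(seed)
        q_p = rng.dirichlet(np.ones(T))
        m = rng.dirichlet(np.ones(2 * T))
        stats = SufficientStats(q_p=q_p, q_ma=m[:T], q_mb=m[T:])
        k = int(rng.integers(1, T + 1))
        cands = rng.choice(T, size=k, replace=False)
        if mixed:
            qq = rng.dirichlet(np.ones(2 * k))
            post = LatentPosterior(transcripts=cands, q_a=qq[:k], q_b=qq[k:])
        else:
            post = LatentPosterior(transcripts=cands, q=rng.dirichlet(np.ones(k)))
        out = interpolate_stats(stats, post, n=n, forget_sigma=sigma)
        assert abs(out.q_p.sum() - 1.0) < 1e-12
        assert abs(out.q_ma.sum() + out.q_mb.sum() - 1.0) < 1e-12
        assert np.all(out.q_p >= 0) and np.all(out.q_ma >= 0) and np.all(out.q_mb >= 0)


class TestMStep:
    def test_flat_prior_tau_is_sum(self):
        stats = SufficientStats(
            q_p=np.array([0.5, 0.5]), q_ma=np.array([0.2, 0.1]), q_mb=np.array([0.3, 0.4])
        )
        params = m_step(stats, beta_a=1.0, beta_b=1.0, n_mixed=10)
        assert params.tau_a == pytest.approx(0.3, abs=1e-15)

    def test_hand_example(self):
        # beta = 5 each, N_m = 100, sum q_ma = 0.3 -> tau_a = 0.34 / 1.08
        stats = SufficientStats(
            q_p=np.array([0.5, 0.5]), q_ma=np.array([0.2, 0.1]), q_mb=np.array([0.3, 0.4])
        )
        params = m_step(stats, beta_a=5.0, beta_b=5.0, n_mixed=100)
        assert params.tau_a == pytest.approx(0.34 / 1.08, abs=1e-12)

    def test_alpha_profiles_sum_to_one(self, rng):
        T = 6
        q_p = rng.dirichlet(np.ones(T))
        m = rng.dirichlet(np.ones(2 * T))
        stats = SufficientStats(q_p=q_p, q_ma=m[:T], q_mb=m[T:])
        params = m_step(stats, beta_a=7.0, beta_b=3.0, n_mixed=50)
        assert params.alpha_a.alpha.sum() == pytest.approx(1.0, abs=1e-12)
        assert params.alpha_b.alpha.sum() == pytest.approx(1.0, abs=1e-12)
        assert params.tau_a + params.tau_b == 1.0

    def test_tau_b_floor_guard_holds_previous_alpha(self):
        stats = SufficientStats(
            q_p=np.array([0.5, 0.5]), q_ma=np.array([0.6, 0.4]), q_mb=np.array([0.0, 0.0])
        )
        prev = np.array([0.9, 0.1])
        params = m_step(stats, beta_a=1.0, beta_b=1.0, n_mixed=10, prev_alpha_b=prev)
        np.testing.assert_array_equal(params.alpha_b.alpha, prev)


def simulate_instance(T, n_pure, n_mixed, tau_b, seed, ambiguity=0.3, length_range=(200, 600), read_length=50):
    rng = np.random.default_rng(seed)
    config = SimConfig(
        n_transcripts=T, length_range=length_range, read_length=read_length,
        ambiguity=ambiguity, seed=seed,
    )
    catalog, blocks = generate_catalog(config, rng)
    rho_a, rho_b = generate_abundances(catalog, rng)
    frag = FragmentModel(150, 40)
    le = effective_lengths(catalog, frag)
    pure = generate_reads(catalog, blocks, rho_a, n_pure, frag, read_length, rng)
    mixed = generate_mixture(catalog, blocks, rho_a, rho_b, tau_b, n_mixed, frag, read_length, rng)
    return catalog, le, pure, mixed, rho_a, rho_b


class TestBatchOracle:
    def test_monotone_log_posterior(self):
        catalog, le, pure, mixed, _, _ = simulate_instance(4, 30, 30, 0.5, seed=3)
        res = batch_em_oracle(
            pure.to_alignment_groups(), mixed.to_alignment_groups(), catalog, le,
            priors=(3.0, 2.0), n_iter=100,
        )
        diffs = np.diff(res.trace)
        assert np.all(diffs >= -1e-9 * np.abs(res.trace[:-1]))

    def test_single_transcript_tau_goes_to_prior_mode(self):
        catalog, le, pure, mixed, _, _ = simulate_instance(
            1, 20, 20, 0.5, seed=4, ambiguity=0.0, length_range=(300, 300)
        )
        res = batch_em_oracle(
            pure.to_alignment_groups(), mixed.to_alignment_groups(), catalog, le,
            priors=(5.0, 3.0), n_iter=200,
        )
        np.testing.assert_array_equal(res.params.alpha_a.alpha, [1.0])
        # mixed reads are uninformative; tau converges to the Beta prior mode
        assert res.params.tau_a == pytest.approx(4.0 / 6.0, abs=1e-6)


class TestOnlineEM:
    def test_matches_batch_fixed_point_small_instance(self):
        # with sigma = 1 the effective EM time grows only like log(n), so the
        # online path cannot track a slowly contracting fixed point; sigma =
        # 0.6 gives polynomially growing effective time and tight agreement
        catalog, le, pure, mixed, _, _ = simulate_instance(5, 100, 100, 0.5, seed=9)
        pg, mg = pure.to_alignment_groups(), mixed.to_alignment_groups()
        n_m = len(mg)
        prior = (0.5, 0.5, 10.0)
        online = run_online_em(
            pg, mg, catalog, le, prior=prior,
            config=EMConfig(forget_sigma=0.6, epochs=1500, tol=1e-15, seed=2),
        )
        betas = (0.5 * 10.0 * n_m, 0.5 * 10.0 * n_m)
        batch = batch_em_oracle(pg, mg, catalog, le, priors=betas, n_iter=4000)
        assert online.params.tau_a == pytest.approx(batch.params.tau_a, abs=1e-3)
        np.testing.assert_allclose(
            online.params.alpha_a.alpha, batch.params.alpha_a.alpha, atol=1e-3
        )
        np.testing.assert_allclose(
            online.params.alpha_b.alpha, batch.params.alpha_b.alpha, atol=1e-3
        )

    def test_degenerate_mixture_prior_b_zero(self):
        catalog, le, pure, mixed, _, _ = simulate_instance(
            6, 80, 80, 0.0, seed=12, ambiguity=0.0
        )
        pg, mg = pure.to_alignment_groups(), mixed.to_alignment_groups()
        res = run_online_em(
            pg, mg, catalog, le, prior=(1.0, 0.0, 10.0),
            config=EMConfig(forget_sigma=1.0, epochs=4, seed=0),
        )
        assert res.params.tau_b == 0.0
        np.testing.assert_array_equal(res.stats.q_mb, np.zeros(6))
        # with unique alignments and sigma=1, running averages equal empirical
        # fractions, so alpha_a is the mean of the two per-sample fractions
        frac_p = pure.truth.counts_a / pure.truth.counts_a.sum()
        frac_m = mixed.truth.counts / mixed.truth.counts.sum()
        np.testing.assert_allclose(res.params.alpha_a.alpha, (frac_p + frac_m) / 2, atol=1e-2)

    def test_single_em_unique_alignments_closed_form(self):
        # empirical read-count fractions are the exact fixed point
        catalog, le, pure, _, _, _ = simulate_instance(
            8, 10_000, 10, 0.5, seed=21, ambiguity=0.0
        )
        groups = pure.to_alignment_groups()
        res = run_single_em(
            groups, catalog, le, EMConfig(forget_sigma=1.0, epochs=1, seed=0)
        )
        # with sigma=1 the running average is exact; the uniform start
        # contributes one pseudo-read
        n = len(groups)
        expected = (1.0 / catalog.size + pure.truth.counts) / (n + 1.0)
        np.testing.assert_allclose(res.alpha.alpha, expected, atol=1e-12)
        emp = pure.truth.counts / pure.truth.counts.sum()
        np.testing.assert_allclose(res.alpha.alpha, emp, atol=1e-4)

    def test_invariants_after_fit(self):
        catalog, le, pure, mixed, _, _ = simulate_instance(10, 300, 300, 0.6, seed=5)
        res = run_online_em(
            pure.to_alignment_groups(), mixed.to_alignment_groups(), catalog, le,
            prior=(0.4, 0.6, 10.0), config=EMConfig(epochs=3, seed=1),
        )
        assert res.params.tau_a + res.params.tau_b == 1.0
        assert res.params.alpha_a.alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.params.alpha_b.alpha.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.stats.q_p.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.stats.q_ma.sum() + res.stats.q_mb.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(res.trace) >= 1

    def test_empty_stream_errors(self, two_transcript_catalog):
        le = EffectiveLengths(np.array([50.0, 250.0]))
        g = make_group("r", [(0, 0, False)])
        with pytest.raises(ValueError):
            run_online_em([], [g], two_transcript_catalog, le, (0.5, 0.5, 10.0), EMConfig())
        with pytest.raises(ValueError):
            run_single_em([], two_transcript_catalog, le, EMConfig())

    def test_seed_reproducibility(self):
        catalog, le, pure, mixed, _, _ = simulate_instance(6, 200, 200, 0.5, seed=8)
        pg, mg = pure.to_alignment_groups(), mixed.to_alignment_groups()
        kwargs = dict(prior=(0.5, 0.5, 10.0), config=EMConfig(epochs=2, seed=77))
        r1 = run_online_em(pg, mg, catalog, le, **kwargs)
        r2 = run_online_em(pg, mg, catalog, le, **kwargs)
        assert r1.params.tau_b == r2.params.tau_b
        np.testing.assert_array_equal(r1.params.alpha_a.alpha, r2.params.alpha_a.alpha)
        assert r1.trace == r2.trace


class TestRecovery:
    def test_parameter_recovery_moderate_scale(self):
        tau_b = 0.6
        catalog, le, pure, mixed, rho_a, rho_b = simulate_instance(
            20, 10_000, 10_000, tau_b, seed=31, ambiguity=0.0,
            length_range=(400, 1500), read_length=75,
        )
        res = run_online_em(
            pure.to_alignment_groups(), mixed.to_alignment_groups(), catalog, le,
            prior=(1 - tau_b, tau_b, 10.0), config=EMConfig(epochs=6, seed=2, tol=1e-9),
        )
        assert res.params.tau_b == pytest.approx(tau_b, abs=0.02)
        alpha_a_true = rho_to_alpha(rho_a, le).alpha
        # empirical pure-sample fractions are the natural reference
        emp = (pure.truth.counts_a + mixed.truth.counts_a)
        emp = emp / emp.sum()
        np.testing.assert_allclose(res.params.alpha_a.alpha, emp, atol=5e-3)
        # and they in turn track the generating profile
        np.testing.assert_allclose(emp, alpha_a_true, atol=2e-2)
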