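import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from shmindel.core import IndelModel, LengthDistribution, MuPrior, NucleotideSequence
from shmindel.inference import (
    OptimizerConfig,
    SequencePosterior,
    build_batch,
    compute_posterior,
    draw_mu_samples,
    em_update_prior,
    fit,
    initial_model_from_annotations,
    momentum_step,
    numerical_gradient,
    posterior_from_loglik,
    project_phi,
    project_simplex,
)
from shmindel.simulate import benchmark_model, generate_repertoire, random_templates
from .conftest import make_prior


def two_bin_prior(f=0.3, d=(0.8, 1.2)):
    dens = np.array(d, dtype=float)
    dens = dens / (dens.sum() * 0.5)
    return MuPrior(f=f, density=dens, bin_width=0.5)


class TestPosterior:
    def test_hand_computed_two_bin_case(self):
        """Bayes arithmetic on a two-bin prior, checked to 1e-12."""
        prior = two_bin_prior()
        lik = np.array([0.2, 0.05])  # L(s|mu) at the two bin centers
        lik0 = 0.5
        post = posterior_from_loglik(prior.centers, np.log(lik), np.log(lik0), prior)
        smooth = float((lik * prior.density).sum() * 0.5)
        marg = 0.3 * lik0 + 0.7 * smooth
        assert post.marginal_loglik == pytest.approx(np.log(marg), rel=1e-12)
        assert post.f_s == pytest.approx(0.3 * lik0 / marg, rel=1e-12)
        expected_density = lik * prior.density / smooth
        assert np.allclose(post.grid_density, expected_density, rtol=1e-12)

    def test_zero_prior_naive_weight(self):
        prior = two_bin_prior(f=0.0)
        post = posterior_from_loglik(
            prior.centers, np.log([0.2, 0.1]), 0.0, prior
        )
        assert post.f_s == 0.0

    def test_unmutated_read_raises_naive_posterior(self, seqs):
        """An exact-template read has f_s > f: S(s|0)=1 beats the marginal."""
        model = IndelModel(
            prior=make_prior(f=0.1, bin_width=0.01),
            beta_del=0.02,
            beta_ins=0.02,
            len_del=LengthDistribution([0.7, 0.3]),
            len_ins=LengthDistribution([0.7, 0.3]),
        )
        t = random_templates(1, 150, seed=3).templates[0]
        post = compute_posterior(t, t, model, exact_grid=True)
        assert post.f_s > model.prior.f

    def test_mutated_read_has_zero_naive_weight(self, seqs):
        model = IndelModel(
            prior=make_prior(f=0.5, bin_width=0.01),
            beta_del=0.02,
            beta_ins=0.02,
            len_del=LengthDistribution([1.0]),
            len_ins=LengthDistribution([1.0]),
        )
        t = random_templates(1, 60, seed=4).templates[0]
        s = NucleotideSequence("r", "A" + t.seq[1:] if t.seq[0] != "A" else "C" + t.seq[1:])
        post = compute_posterior(s, t, model, exact_grid=True)
        assert post.f_s == 0.0
        assert post.grid_density.sum() * 0.01 == pytest.approx(1.0, abs=1e-6)


class TestEMUpdate:
    def _post(self, f_s, dens, bin_width=0.25):
        dens = np.asarray(dens, dtype=float)
        return SequencePosterior(
            f_s=f_s,
            nodes=np.array([0.1]),
            values=np.array([1.0]),
            grid_density=dens,
            loglik_nodes=np.array([0.0]),
            marginal_loglik=0.0,
            map_mu=0.1,
            spread=0.1,
        )

    def test_mean_naive_weight(self):
        posts = [self._post(0.5, [1, 1, 1, 1]) for _ in range(4)]
        assert em_update_prior(posts).f == pytest.approx(0.5)

    def test_single_sequence_prior_equals_posterior(self):
        dens = np.array([2.0, 1.0, 0.5, 0.5])
        post = self._post(0.2, dens)
        new = em_update_prior([post])
        assert np.allclose(new.density * 0.25 / (dens * 0.25).sum() * dens.sum() * 0.25, dens * 0.25 / (dens.sum() * 0.25))
        assert np.allclose(new.density, dens / (dens.sum() * 0.25))

    def test_weighted_average_of_two(self):
        p1 = self._post(0.5, [4.0, 0.0, 0.0, 0.0])
        p2 = self._post(0.0, [0.0, 4.0, 0.0, 0.0])
        new = em_update_prior([p1, p2])
        assert new.f == pytest.approx(0.25)
        # weights 0.5 and 1.0 -> densities (0.5*4, 1*4)/1.5 per bin, renormalized
        expected = np.array([0.5 * 4, 4.0, 0, 0]) / 1.5
        expected /= expected.sum() * 0.25
        assert np.allclose(new.density, expected)

    def test_all_naive_keeps_previous_density(self):
        prev = make_prior(f=0.2, bin_width=0.25)
        posts = [self._post(1.0, [0, 0, 0, 0]) for _ in range(3)]
        with pytest.warns(UserWarning):
            new = em_update_prior(posts, previous=prev)
        assert new.f == 1.0
        assert np.allclose(new.density, prev.density)


class TestSampling:
    def test_degenerate_cases(self):
        all_naive = SequencePosterior(1.0, np.array([0.0]), np.array([0.0]),
                                      np.zeros(4), np.array([0.0]), 0.0, 0.0, 0.1)
        out = draw_mu_samples([all_naive], rng=0)
        assert out.shape == (1, 1) and out[0, 0] == 0.0
        point = SequencePosterior(0.0, np.array([0.0]), np.array([0.0]),
                                  np.array([0, 4.0, 0, 0]), np.array([0.0]), 0.0, 0.3, 0.1)
        out = draw_mu_samples([point], rng=1)
        assert 0.25 <= out[0, 0] < 0.5  # inside the only massive bin

    def test_samples_follow_posterior_cdf(self):
        dens = np.array([0.5, 2.0, 1.0, 0.5])
        dens = dens / (dens.sum() * 0.25)
        post = SequencePosterior(0.0, np.array([0.0]), np.array([0.0]),
                                 dens, np.array([0.0]), 0.0, 0.3, 0.1)
        cfg = OptimizerConfig(n_mc=1)
        rng = np.random.default_rng(42)
        samples = np.concatenate(
            [draw_mu_samples([post], cfg, rng)[0] for _ in range(20000)]
        )
        centers = (np.arange(4) + 0.5) * 0.25

        def cdf(x):
            edges = np.arange(5) * 0.25
            c = np.concatenate(([0.0], np.cumsum(dens * 0.25)))
            return np.interp(x, edges, c)

        stat, p = sps.kstest(samples, cdf)
        assert p > 0.01


class TestProjection:
    def test_valid_distribution_unchanged(self):
        v = np.array([0.2, 0.5, 0.3])
        assert np.allclose(project_simplex(v), v)

    def test_hand_projection(self):
        assert np.allclose(project_simplex(np.array([1.2, -0.2])), [1.0, 0.0])

    @given(hst.lists(hst.floats(-5, 5), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_idempotent_and_feasible(self, raw):
        v = np.array(raw)
        p = project_simplex(v)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(project_simplex(p), p, atol=1e-9)


class TestMomentumStep:
    def test_fixed_point(self):
        cfg = OptimizerConfig(T=100)
        phi = np.array([0.02, 0.03, 0.6, 0.4, 0.5, 0.5])
        out = momentum_step(phi, phi, np.zeros(6), 5, cfg, theta_max=2)
        assert np.allclose(out, phi, atol=1e-12)

    def test_schedule_values(self):
        cfg = OptimizerConfig(T=200, alpha0=0.05)
        assert cfg.learning_rate(200) == pytest.approx(0.05 * np.exp(-2))
        assert cfg.momentum(3) == pytest.approx(0.5)

    def test_converges_on_concave_toy_objective(self):
        """Projected momentum ascent finds the maximizer of a 1-D parabola."""
        cfg = OptimizerConfig(T=300, alpha0=0.5, scale_floor=0.05)
        target = 0.3
        phi = np.array([0.0, 0.0, 1.0, 1.0])  # only component 0 matters
        prev = phi.copy()
        for t in range(1, 301):
            grad = np.zeros(4)
            grad[0] = -2 * (phi[0] - target)
            new = momentum_step(phi, prev, grad, t, cfg, theta_max=1)
            prev, phi = phi, new
        assert abs(phi[0] - target) < 1e-3


def tiny_batch(seed=0, n=12, L=80):
    templates = random_templates(2, L, seed=seed)
    model = benchmark_model(theta_max=8, length_scale=4.0, bin_width=0.005)
    rep = generate_repertoire(templates, model, n, seed=seed + 1)
    ws, batch = build_batch(rep.reads, templates, model)
    return rep, templates, model, ws, batch


class TestNumericalGradient:
    def test_agrees_with_centered_difference(self):
        rep, templates, model, ws, batch = tiny_batch(seed=6)
        mus = np.full((1, len(rep.reads)), 0.06)
        phi = model.phi
        eps = 1e-4
        grad = numerical_gradient(phi, mus, batch, epsilon=eps)
        idx = np.arange(len(rep.reads))
        for comp in (0, 1, 2):
            e = np.zeros_like(phi)
            e[comp] = eps / 10
            up = batch.evaluate_phi(idx, mus[0], phi + e).sum()
            dn = batch.evaluate_phi(idx, mus[0], phi - e).sum()
            centered = (up - dn) / (2 * e[comp]) / len(rep.reads)
            assert grad[comp] == pytest.approx(centered, rel=0.05, abs=1e-3)

    def test_flat_component_has_zero_gradient(self):
        """With beta_ins = 0 the likelihood cannot depend on P_ins."""
        templates = random_templates(1, 60, seed=7)
        model = benchmark_model(theta_max=5, beta_ins=0.0, length_scale=3.0,
                                bin_width=0.005)
        rep = generate_repertoire(templates, model, 8, seed=8)
        ws, batch = build_batch(rep.reads, templates, model)
        mus = np.full((1, 8), 0.05)
        grad = numerical_gradient(model.phi, mus, batch, epsilon=1e-5)
        th = model.theta_max
        # P_ins(ell > 1) components: a length-1 insertion paired with a length-1
        # deletion is still reachable, so only strictly longer events are dead flat
        assert np.all(np.abs(grad[2 + th + 1 :]) < 1e-6)

    def test_insertion_surplus_pushes_beta_ins_up(self):
        """Reads with more insertions than the model expects raise d logL / d beta_ins."""
        templates = random_templates(1, 100, seed=9)
        gen = benchmark_model(theta_max=8, beta_ins=0.2, beta_del=0.01,
                              length_scale=4.0, bin_width=0.005)
        rep = generate_repertoire(templates, gen, 15, seed=10)
        low = benchmark_model(theta_max=8, beta_ins=0.005, beta_del=0.01,
                              length_scale=4.0, bin_width=0.005)
        ws, batch = build_batch(rep.reads, templates, low)
        mus = np.full((1, 15), 0.08)
        grad = numerical_gradient(low.phi, mus, batch, epsilon=1e-5)
        assert grad[1] > 0


class TestFit:
    def test_em_monotone_with_frozen_phi(self):
        """With phi frozen and exact-grid posteriors, EM never decreases the likelihood."""
        templates = random_templates(2, 80, seed=11)
        gen = benchmark_model(theta_max=6, length_scale=3.0, bin_width=0.01)
        rep = generate_repertoire(templates, gen, 40, seed=12)
        cfg = OptimizerConfig(T=6, posterior_mode="grid", seed=1)
        res = fit(rep.reads, templates, config=cfg, theta_max=6, bin_width=0.01,
                  freeze_phi=True)
        lls = res.trajectory["loglik"].to_numpy()
        assert np.all(np.diff(lls) >= -1e-9 * np.abs(lls[:-1]))

    def test_recovers_naive_fraction_without_indels(self):
        """Zero-indel data: fitted f ~ truth, fitted rates stay near zero."""
        templates = random_templates(2, 100, seed=13)
        gen = benchmark_model(theta_max=6, f=0.5, beta_del=0.0, beta_ins=0.0,
                              length_scale=3.0, bin_width=0.005)
        rep = generate_repertoire(templates, gen, 150, seed=14)
        emp_f = np.mean([sc.mu == 0 for sc in rep.truth])
        cfg = OptimizerConfig(T=15, seed=2)
        res = fit(rep.reads, templates, config=cfg, theta_max=6, bin_width=0.005)
        assert res.model.prior.f == pytest.approx(emp_f, abs=0.06)
        assert res.model.beta_del < 0.01
        assert res.model.beta_ins < 0.01

    def test_mask_refresh_midway(self):
        """Refreshing the pruning mask mid-fit changes nothing qualitative."""
        from shmindel.likelihood import PruningConfig

        templates = random_templates(2, 80, seed=21)
        gen = benchmark_model(theta_max=6, length_scale=3.0, bin_width=0.01)
        rep = generate_repertoire(templates, gen, 25, seed=22)
        cfg = OptimizerConfig(T=6, seed=4)
        res = fit(rep.reads, templates, config=cfg, theta_max=6, bin_width=0.01,
                  pruning=PruningConfig(refresh=True))
        assert np.all(np.isfinite(res.trajectory["loglik"]))

    def test_deterministic_under_seed(self):
        rep, templates, model, ws, batch = tiny_batch(seed=15, n=10)
        cfg = OptimizerConfig(T=4, seed=9)
        r1 = fit(rep.reads, templates, config=cfg, theta_max=8, bin_width=0.005)
        r2 = fit(rep.reads, templates, config=cfg, theta_max=8, bin_width=0.005)
        assert np.allclose(r1.trajectory["loglik"], r2.trajectory["loglik"])
        assert r1.model.beta_ins == r2.model.beta_ins


class TestInitialModel:
    def test_from_annotations_basics(self):
        from shmindel.annotate import annotate_repertoire

        templates = random_templates(2, 100, seed=16)
        gen = benchmark_model(theta_max=8, length_scale=4.0, bin_width=0.005)
        rep = generate_repertoire(templates, gen, 120, seed=17)
        anns = annotate_repertoire(rep.reads, templates)
        m = initial_model_from_annotations(anns, theta_max=8, bin_width=0.005)
        emp_f = np.mean([not a.events for a in anns])
        assert m.prior.f == pytest.approx(emp_f, abs=1e-9)
        assert m.beta_del > 0 and m.beta_ins > 0
        assert m.prior.density.sum() * 0.005 == pytest.approx(1.0, abs=1e-6)
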