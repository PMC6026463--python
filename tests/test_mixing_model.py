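"""Likelihood correctness and posterior behaviour of the mixing model."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from isodiet import (
    ConsumerSample,
    IsotopeTriplet,
    McmcConfig,
    MixingModelSpec,
    PosteriorDiet,
    SourceGroup,
    TEFSet,
    compare_prior_modes,
    log_likelihood,
    sample_posterior,
    summarize_posterior,
)

QUICK = McmcConfig(iterations=6000, burn_in=2000, thin=4, seed=0)


def _group(gid, means, sds):
    return SourceGroup(
        group_id=gid,
        mean=IsotopeTriplet(**dict(zip(("d13c", "d15n", "d34s"), means))),
        sd=IsotopeTriplet(**dict(zip(("d13c", "d15n", "d34s"), sds))),
        n={"d13c": 5, "d15n": 5, "d34s": 5},
    )


def _tefs(groups, means=(0.0, 0.0, 0.0), sds=(0.0, 0.0, 0.0)):
    return TEFSet(
        model_id="custom",
        values={
            g.group_id: {
                t: (means[j], sds[j]) for j, t in enumerate(("d13c", "d15n", "d34s"))
            }
            for g in groups
        },
    )


def _consumer(bid, *vals):
    full = list(vals) + [0.0] * (3 - len(vals))
    return ConsumerSample(
        bird_id=bid, triplet=IsotopeTriplet(d13c=full[0], d15n=full[1], d34s=full[2])
    )


def _oracle_loglik(p, sigma, x, mu, omega, lam, tau):
    """Independent per-term brute-force evaluation of the model density."""
    n, j = x.shape
    k = len(p)
    total = 0.0
    for i in range(n):
        for jj in range(j):
            mean = sum(p[kk] * (mu[jj, kk] + lam[jj, kk]) for kk in range(k))
            var = (
                sum(p[kk] ** 2 * (omega[jj, kk] ** 2 + tau[jj, kk] ** 2) for kk in range(k))
                + sigma[jj] ** 2
            )
            total += norm.logpdf(x[i, jj], loc=mean, scale=math.sqrt(var))
    return total


class TestLogLikelihood:
    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(10):
            k, j, n = 3, 2, 4
            mu = rng.normal(-20, 3, (3, k))
            omega = rng.uniform(0.1, 1.0, (3, k))
            lam = rng.normal(0, 1, (3, k))
            tau = rng.uniform(0.0, 0.5, (3, k))
            groups = [
                _group(f"g{kk}", mu[:, kk], omega[:, kk]) for kk in range(k)
            ]
            tefs = TEFSet(
                model_id="custom",
                values={
                    f"g{kk}": {
                        t: (lam[jj, kk], tau[jj, kk])
                        for jj, t in enumerate(("d13c", "d15n", "d34s"))
                    }
                    for kk in range(k)
                },
            )
            spec = MixingModelSpec(
                groups=tuple(groups), tefs=tefs, tracers=("d13c", "d15n")
            )
            p = rng.dirichlet(np.ones(k))
            sigma = rng.uniform(0.1, 1.0, j)
            x = rng.normal(-20, 2, (n, 3))
            consumers = [_consumer(f"c{i}", *x[i]) for i in range(n)]
            ours = log_likelihood(p, sigma, consumers, spec)
            oracle = _oracle_loglik(p, sigma, x[:, :2], mu[:2], omega[:2], lam[:2], tau[:2])
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_single_active_source_is_a_plain_normal(self):
        groups = [_group("a", (-20, 8, 15), (0.4, 0.3, 0.5)),
                  _group("b", (-25, 4, 10), (1.0, 1.0, 1.0))]
        tefs = _tefs(groups, means=(1.0, 2.0, 0.0), sds=(0.2, 0.1, 0.0))
        spec = MixingModelSpec(groups=tuple(groups), tefs=tefs)
        c = _consumer("c", -19.5, 9.0, 15.5)
        sigma = np.array([0.3, 0.3, 0.3])
        ours = log_likelihood([1.0, 0.0], sigma, [c], spec)
        expect = sum(
            norm.logpdf(
                x, loc=m + lam, scale=math.sqrt(w**2 + t**2 + s**2)
            )
            for x, m, lam, w, t, s in zip(
                (-19.5, 9.0, 15.5), (-20, 8, 15), (1.0, 2.0, 0.0),
                (0.4, 0.3, 0.5), (0.2, 0.1, 0.0), sigma,
            )
        )
        assert ours == pytest.approx(expect, abs=1e-12)

    def test_symmetry_peaks_at_even_split(self):
        groups = [_group("a", (-5, 0, 0), (1, 1, 1)),
                  _group("b", (5, 0, 0), (1, 1, 1))]
        spec = MixingModelSpec(
            groups=tuple(groups), tefs=_tefs(groups), tracers=("d13c",)
        )
        c = _consumer("c", 0.0)
        sigma = [0.5]
        center = log_likelihood([0.5, 0.5], sigma, [c], spec)
        for w in (0.2, 0.35, 0.65, 0.8):
            assert center > log_likelihood([w, 1 - w], sigma, [c], spec)

    def test_invalid_inputs_rejected(self):
        groups = [_group("a", (0, 0, 0), (1, 1, 1)), _group("b", (1, 1, 1), (1, 1, 1))]
        spec = MixingModelSpec(groups=tuple(groups), tefs=_tefs(groups))
        c = _consumer("c", 0, 0, 0)
        with pytest.raises(ValueError):
            log_likelihood([0.7, 0.7], [0.1] * 3, [c], spec)  # not a simplex
        with pytest.raises(ValueError):
            log_likelihood([0.5, 0.5], [-0.1, 0.1, 0.1], [c], spec)


class TestSamplePosterior:
    def test_no_data_posterior_matches_prior(self):
        groups = [_group(f"g{i}", (-20 + i, 5 + i, 10 + i), (0.5, 0.5, 0.5))
                  for i in range(3)]
        spec = MixingModelSpec(groups=tuple(groups), tefs=_tefs(groups))
        post = sample_posterior([], spec, QUICK)
        means = post.p.mean(axis=0)
        assert np.allclose(means, 1 / 3, atol=0.05)

    def test_two_source_geometry_recovered(self):
        # consumers at 7.0 between sources at 0 and 10 -> p2 around 0.70
        groups = [_group("low", (0, 0, 0), (0.1, 0.1, 0.1)),
                  _group("high", (10, 0, 0), (0.1, 0.1, 0.1))]
        spec = MixingModelSpec(
            groups=tuple(groups), tefs=_tefs(groups), tracers=("d13c",)
        )
        consumers = [_consumer(f"c{i}", 7.0) for i in range(20)]
        post = sample_posterior(
            consumers, spec,
            McmcConfig(iterations=20000, burn_in=5000, thin=5, seed=2),
        )
        assert post.p[:, 1].mean() == pytest.approx(0.70, abs=0.02)

    def test_draws_lie_on_the_simplex(self, study_groups, model0_tefs):
        spec = MixingModelSpec(groups=tuple(study_groups), tefs=model0_tefs)
        consumers = [_consumer("c", -21.4, 11.5, 16.3)]
        post = sample_posterior(consumers, spec, QUICK)
        assert np.abs(post.p.sum(axis=1) - 1).max() < 1e-10
        summ = summarize_posterior(post)
        assert summ["mean_pct"].sum() == pytest.approx(100.0, abs=0.5)

    def test_seeded_reproducibility(self, study_groups, model0_tefs):
        spec = MixingModelSpec(groups=tuple(study_groups), tefs=model0_tefs)
        consumers = [_consumer("c", -21.4, 11.5, 16.3)]
        a = sample_posterior(consumers, spec, QUICK)
        b = sample_posterior(consumers, spec, QUICK)
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.sigma, b.sigma)

    def test_label_permutation_equivariance(self):
        groups = [_group("a", (-20, 12, 15), (0.3, 0.3, 0.3)),
                  _group("b", (-22, 6, 17), (0.3, 0.3, 0.3)),
                  _group("c", (-18, 9, 11), (0.3, 0.3, 0.3))]
        consumers = [_consumer(f"c{i}", -20.5, 9.5, 14.5) for i in range(8)]
        fwd = MixingModelSpec(groups=tuple(groups), tefs=_tefs(groups))
        rev = MixingModelSpec(groups=tuple(reversed(groups)), tefs=_tefs(groups))
        pf = summarize_posterior(sample_posterior(consumers, fwd, QUICK))
        pr = summarize_posterior(sample_posterior(consumers, rev, QUICK))
        for gid in ("a", "b", "c"):
            assert pf.loc[gid, "mean_pct"] == pytest.approx(
                pr.loc[gid, "mean_pct"], abs=2.0
            )

    def test_posterior_contracts_relative_to_prior(self):
        groups = [_group("low", (0, 0, 0), (0.1, 0.1, 0.1)),
                  _group("high", (10, 0, 0), (0.1, 0.1, 0.1))]
        spec = MixingModelSpec(groups=tuple(groups), tefs=_tefs(groups),
                               tracers=("d13c",))
        consumers = [_consumer(f"c{i}", 7.0) for i in range(20)]
        post = sample_posterior(consumers, spec, QUICK)
        prior_sd = math.sqrt(1 * 1 / (2 * 2 * 3))  # Dirichlet(1,1) marginal SD
        assert post.p[:, 1].std() < prior_sd


class TestSummaries:
    def test_constant_draws(self):
        p = np.tile([0.2, 0.8], (50, 1))
        post = PosteriorDiet(
            p=p, sigma=np.zeros((50, 1)), source_ids=("a", "b"),
            tracers=("d13c",),
        )
        summ = summarize_posterior(post)
        assert summ.loc["a", "mean_pct"] == pytest.approx(20.0)
        assert summ.loc["b", "mean_pct"] == pytest.approx(80.0)
        assert (summ["sd_pct"] == 0).all()
        assert summ.loc["a", "ci2_5_pct"] == summ.loc["a", "ci97_5_pct"]

    def test_uniform_simplex_draws(self, rng):
        # Dirichlet(1,1,1) marginals are Beta(1,2)
        p = rng.dirichlet(np.ones(3), size=20000)
        post = PosteriorDiet(
            p=p, sigma=np.zeros((20000, 1)), source_ids=("a", "b", "c"),
            tracers=("d13c",),
        )
        summ = summarize_posterior(post)
        assert np.allclose(summ["mean_pct"], 100 / 3, atol=0.7)
        assert np.allclose(summ["ci2_5_pct"], 1.3, atol=0.4)
        assert np.allclose(summ["ci97_5_pct"], 84.2, atol=0.8)

    def test_empty_draws_rejected(self):
        post = PosteriorDiet(
            p=np.empty((0, 2)), sigma=np.empty((0, 1)),
            source_ids=("a", "b"), tracers=("d13c",),
        )
        with pytest.raises(ValueError):
            summarize_posterior(post)


class TestPriorModes:
    def test_informative_prior_pulls_in_symmetric_problem(self):
        groups = [_group("a", (-5, 0, 0), (1, 1, 1)),
                  _group("b", (5, 0, 0), (1, 1, 1))]
        spec = MixingModelSpec(groups=tuple(groups), tefs=_tefs(groups),
                               tracers=("d13c",))
        consumers = [_consumer(f"c{i}", 0.0) for i in range(5)]
        res = compare_prior_modes(
            consumers, spec,
            {"flat": None, "favour_a": np.array([4.0, 1.0])},
            QUICK,
        )
        flat = res[(res.prior_mode == "flat") & (res.source_id == "a")]["mean_pct"].iloc[0]
        fav = res[(res.prior_mode == "favour_a") & (res.source_id == "a")]["mean_pct"].iloc[0]
        assert fav > flat

    def test_identical_priors_give_identical_summaries(self, study_groups, model0_tefs):
        spec = MixingModelSpec(groups=tuple(study_groups), tefs=model0_tefs)
        consumers = [_consumer("c", -21.4, 11.5, 16.3)]
        res = compare_prior_modes(
            consumers, spec, {"m1": None, "m2": None}, QUICK
        )
        m1 = res[res.prior_mode == "m1"].drop(columns="prior_mode").reset_index(drop=True)
        m2 = res[res.prior_mode == "m2"].drop(columns="prior_mode").reset_index(drop=True)
        assert m1.equals(m2)
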