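"""Bayesian K-source, J-tracer stable-isotope mixing model.

The model is the classic Dirichlet-prior formulation used throughout the
diet-partitioning literature: consumer i's value on tracer j is

    X_ij ~ Normal( sum_k p_k (mu_jk + lam_jk),
                   sum_k p_k^2 (omega_jk^2 + tau_jk^2) + sigma_j^2 )

where p is the diet-proportion simplex, mu/omega are source means/SDs,
lam/tau are TEF means/SDs and sigma_j is a per-tracer residual SD.  The
prior is Dirichlet(alpha) on p (all-ones by default, gut-content-derived
otherwise) and half-Normal on each sigma_j.  Sampling is random-walk
Metropolis-within-Gibbs on an additive-log-ratio reparameterization of p
plus log-sigma updates — dependency-free and exactly reproducible under a
seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gut_contents import PriorSpec
from .isotope_prep import ConsumerSample, SourceGroup, TEFSet, TRACERS

logger = logging.getLogger("isodiet")

_SIMPLEX_TOL = 1e-8


@dataclass(frozen=True)
class MixingModelSpec:
    """Everything the likelihood needs: sources, TEFs, prior, tracers.

    ``prior`` may be a :class:`PriorSpec`, a raw alpha vector, or ``None``
    (flat Dirichlet(1,...,1)).  ``residual_scale`` is the half-Normal prior
    scale (‰) for the per-tracer residual SDs; 0 disables the residual term
    entirely (sigma pinned at 0).
    """

    groups: tuple[SourceGroup, ...]
    tefs: TEFSet
    prior: PriorSpec | np.ndarray | None = None
    tracers: tuple[str, ...] = TRACERS
    residual_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.groups) < 2:
            raise ValueError("mixing requires at least 2 sources")
        for t in self.tracers:
            if t not in TRACERS:
                raise ValueError(f"unknown tracer {t!r}")
        if self.residual_scale < 0:
            raise ValueError("residual_scale must be >= 0")

    @property
    def source_ids(self) -> tuple[str, ...]:
        return tuple(g.group_id for g in self.groups)

    def alpha(self) -> np.ndarray:
        k = len(self.groups)
        if self.prior is None:
            return np.ones(k)
        if isinstance(self.prior, PriorSpec):
            if self.prior.source_ids != self.source_ids:
                raise ValueError(
                    "prior source order does not match model sources: "
                    f"{self.prior.source_ids} vs {self.source_ids}"
                )
            return np.asarray(self.prior.alpha, dtype=float)
        a = np.asarray(self.prior, dtype=float)
        if a.shape != (k,) or not (a > 0).all():
            raise ValueError("alpha must be a positive vector of length K")
        return a


@dataclass(frozen=True)
class McmcConfig:
    """Random-walk MCMC settings."""

    iterations: int = 40_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int | None = None
    proposal_scale: float = 0.5

    def __post_init__(self) -> None:
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass(frozen=True)
class PosteriorDiet:
    """Posterior draws of the diet simplex and residual SDs."""

    p: np.ndarray  # (M, K), rows on the simplex
    sigma: np.ndarray  # (M, J)
    source_ids: tuple[str, ...]
    tracers: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p.ndim != 2 or self.p.shape[1] != len(self.source_ids):
            raise ValueError("p must be (draws, K)")
        if self.p.size and np.abs(self.p.sum(axis=1) - 1).max() > 1e-10:
            raise ValueError("posterior draws must lie on the simplex")
        if (self.sigma < 0).any():
            raise ValueError("sigma draws must be >= 0")


def _model_arrays(
    spec: MixingModelSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tracer/source TEF-shifted means M and composite variances V."""
    j, k = len(spec.tracers), len(spec.groups)
    m = np.empty((j, k))
    v = np.empty((j, k))
    for jj, t in enumerate(spec.tracers):
        for kk, g in enumerate(spec.groups):
            sd = g.sd_of(t)
            if math.isnan(g.mean_of(t)) or math.isnan(sd):
                raise ValueError(f"group {g.group_id}: missing {t} statistics")
            m[jj, kk] = g.mean_of(t) + spec.tefs.mean(g.group_id, t)
            v[jj, kk] = sd**2 + spec.tefs.sd(g.group_id, t) ** 2
    return m, v


def _consumer_matrix(
    consumers: Sequence[ConsumerSample], tracers: Sequence[str]
) -> np.ndarray:
    return np.array(
        [[c.triplet.get(t) for t in tracers] for c in consumers], dtype=float
    )


def log_likelihood(
    p: Sequence[float],
    sigma: Sequence[float],
    consumers: Sequence[ConsumerSample],
    spec: MixingModelSpec,
) -> float:
    """Model log-likelihood at diet proportions ``p`` and residual SDs
    ``sigma`` (one per tracer)."""
    p = np.asarray(p, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if p.shape != (len(spec.groups),) or (p < -_SIMPLEX_TOL).any() or abs(
        p.sum() - 1.0
    ) > _SIMPLEX_TOL:
        raise ValueError("p must be a K-vector on the simplex")
    if sigma.shape != (len(spec.tracers),) or (sigma < 0).any():
        raise ValueError("sigma must be a non-negative J-vector")
    m, v = _model_arrays(spec)
    x = _consumer_matrix(consumers, spec.tracers)
    mean = m @ p
    var = v @ (p**2) + sigma**2
    if (var <= 0).any():
        raise ValueError("zero model variance; supply positive SDs or sigma")
    resid2 = (x - mean[None, :]) ** 2
    return float(
        -0.5 * np.sum(np.log(2 * np.pi * var)[None, :] + resid2 / var[None, :])
    )


def _softmax_p(z: np.ndarray) -> np.ndarray:
    full = np.append(z, 0.0)
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def sample_posterior(
    consumers: Sequence[ConsumerSample],
    spec: MixingModelSpec,
    mcmc: McmcConfig | None = None,
) -> PosteriorDiet:
    """Draw from the posterior over (p, sigma) by Metropolis-within-Gibbs.

    The simplex is reparameterized by additive log-ratios (K−1 free
    coordinates, updated as one block) and each log sigma_j gets its own
    scalar update.  Proposal scales adapt toward standard acceptance-rate
    targets during burn-in only, so the retained chain is a fixed-kernel
    Markov chain.  Zero consumers is allowed: the result then samples the
    prior.
    """
    if mcmc is None:
        mcmc = McmcConfig()
    rng = np.random.default_rng(mcmc.seed)
    k = len(spec.groups)
    j = len(spec.tracers)
    alpha = spec.alpha()
    m, v = _model_arrays(spec)
    x = _consumer_matrix(consumers, spec.tracers)
    n = x.shape[0]
    s1 = x.sum(axis=0) if n else np.zeros(j)
    s2 = (x**2).sum(axis=0) if n else np.zeros(j)

    sample_sigma = spec.residual_scale > 0
    s0 = spec.residual_scale

    def log_post(z: np.ndarray, log_sig: np.ndarray) -> float:
        p = _softmax_p(z)
        if (p <= 0).any():  # underflow guard
            p = np.clip(p, 1e-300, None)
            p /= p.sum()
        sig2 = np.exp(2 * log_sig) if sample_sigma else np.zeros(j)
        var = v @ (p**2) + sig2
        if (var <= 0).any():
            return -np.inf
        mean = m @ p
        ll = -0.5 * np.sum(
            n * np.log(2 * np.pi * var) + (s2 - 2 * mean * s1 + n * mean**2) / var
        )
        lp = float(np.dot(alpha, np.log(p)))  # Dirichlet + ALR Jacobian
        if sample_sigma:
            # half-Normal(s0) on sigma, with log-sigma Jacobian
            lp += float(np.sum(-sig2 / (2 * s0**2) + log_sig))
        return ll + lp

    p0 = alpha / alpha.sum()
    z = np.log(p0[:-1] / p0[-1])
    log_sig = np.full(j, np.log(max(s0, 1e-6) / 2)) if sample_sigma else np.zeros(j)
    step_z = mcmc.proposal_scale
    step_s = np.full(j, 0.5)
    lp_cur = log_post(z, log_sig)

    n_keep = (mcmc.iterations - mcmc.burn_in) // mcmc.thin
    p_draws = np.empty((n_keep, k))
    s_draws = np.zeros((n_keep, j))
    acc_z = acc_z_win = 0
    acc_s = np.zeros(j)
    acc_s_win = np.zeros(j)
    kept = 0
    adapt_every = 100

    for it in range(mcmc.iterations):
        z_prop = z + step_z * rng.standard_normal(k - 1)
        lp_prop = log_post(z_prop, log_sig)
        if math.log(rng.random()) < lp_prop - lp_cur:
            z, lp_cur = z_prop, lp_prop
            acc_z += 1
            acc_z_win += 1
        if sample_sigma:
            for jj in range(j):
                ls_prop = log_sig.copy()
                ls_prop[jj] += step_s[jj] * rng.standard_normal()
                lp_prop = log_post(z, ls_prop)
                if math.log(rng.random()) < lp_prop - lp_cur:
                    log_sig, lp_cur = ls_prop, lp_prop
                    acc_s[jj] += 1
                    acc_s_win[jj] += 1
        if it < mcmc.burn_in and (it + 1) % adapt_every == 0:
            rate = acc_z_win / adapt_every
            step_z *= math.exp(np.clip(rate - 0.25, -0.5, 0.5))
            acc_z_win = 0
            rates = acc_s_win / adapt_every
            step_s *= np.exp(np.clip(rates - 0.44, -0.5, 0.5))
            acc_s_win[:] = 0
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0 and kept < n_keep:
            p = _softmax_p(z)
            p_draws[kept] = p / p.sum()
            if sample_sigma:
                s_draws[kept] = np.exp(log_sig)
            kept += 1

    diagnostics = {
        "accept_rate_p": acc_z / mcmc.iterations,
        "accept_rate_sigma": (acc_s / mcmc.iterations).tolist(),
        "n_draws": kept,
        "ess": _ess(p_draws[:kept]),
        "seed": mcmc.seed,
    }
    for sid, ess in zip(spec.source_ids, diagnostics["ess"]):
        if ess < 100:
            logger.warning(
                "low effective sample size for %s: %.0f (< 100)", sid, ess
            )
    return PosteriorDiet(
        p=p_draws[:kept],
        sigma=s_draws[:kept],
        source_ids=spec.source_ids,
        tracers=spec.tracers,
        diagnostics=diagnostics,
    )


def _ess(draws: np.ndarray) -> list[float]:
    """Per-component effective sample size of a single chain."""
    import arviz as az

    return [float(az.ess(draws[None, :, kk])) for kk in range(draws.shape[1])]


def summarize_posterior(
    post: PosteriorDiet, decimals: int | None = None
) -> pd.DataFrame:
    """Posterior mean, SD and empirical 95% credibility interval, in percent.

    ``decimals`` rounds for reporting (0 mimics the usual whole-percent
    diet tables); ``None`` keeps full precision.
    """
    if post.p.shape[0] < 1:
        raise ValueError("no posterior draws")
    pct = 100.0 * post.p
    out = pd.DataFrame(
        {
            "mean_pct": pct.mean(axis=0),
            "sd_pct": pct.std(axis=0, ddof=1) if pct.shape[0] > 1 else 0.0,
            "ci2_5_pct": np.percentile(pct, 2.5, axis=0),
            "ci97_5_pct": np.percentile(pct, 97.5, axis=0),
        },
        index=pd.Index(post.source_ids, name="source_id"),
    )
    ess = post.diagnostics.get("ess")
    if ess is not None:
        out["ess"] = ess
    if decimals is not None:
        num = ["mean_pct", "sd_pct", "ci2_5_pct", "ci97_5_pct"]
        out[num] = out[num].round(decimals)
    return out


def compare_prior_modes(
    consumers: Sequence[ConsumerSample],
    spec: MixingModelSpec,
    priors: Mapping[str, PriorSpec | np.ndarray | None],
    mcmc: McmcConfig | None = None,
) -> pd.DataFrame:
    """Run the model once per prior mode with identical seeds and stack the
    summaries into one table (columns include ``prior_mode``)."""
    frames = []
    for mode, prior in priors.items():
        post = sample_posterior(consumers, replace(spec, prior=prior), mcmc)
        summ = summarize_posterior(post).reset_index()
        summ.insert(0, "prior_mode", mode)
        frames.append(summ)
    return pd.concat(frames, ignore_index=True)
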