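"""Online MAP-EM estimation engine plus a batch-EM reference oracle.

The online E-step scores one read at a time and folds its posterior into
running per-transcript averages with step size ``1/(n+2)**sigma``
(forgetting factor ``0.5 < sigma <= 1``); the M-step maps those averages
back to mixing proportions and sampling profiles. The batch implementation
is written independently from the complete-posterior objective and is used
as a testing oracle (its log-posterior is asserted nondecreasing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import bias as bias_mod
from .model import (
    EffectiveLengths,
    ModelParams,
    SamplingProfile,
    TranscriptCatalog,
    log_posterior,
)

logger = logging.getLogger(__name__)

TAU_FLOOR = 1e-8
_SUM_TOL = 1e-9


@dataclass(frozen=True)
class EMConfig:
    forget_sigma: float = 0.85
    epochs: int = 2
    tol: float = 1e-6
    seed: int = 0
    minibatch: int = 1

    def __post_init__(self) -> None:
        if not (0.5 < self.forget_sigma <= 1.0):
            raise ValueError("forgetting factor must satisfy 0.5 < sigma <= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")


@dataclass
class SufficientStats:
    """Running conditional-probability averages per transcript."""

    q_p: np.ndarray
    q_ma: np.ndarray
    q_mb: np.ndarray

    def __post_init__(self) -> None:
        self.q_p = np.asarray(self.q_p, dtype=np.float64)
        self.q_ma = np.asarray(self.q_ma, dtype=np.float64)
        self.q_mb = np.asarray(self.q_mb, dtype=np.float64)
        if np.any(self.q_p < 0) or np.any(self.q_ma < 0) or np.any(self.q_mb < 0):
            raise ValueError("sufficient statistics must be nonnegative")
        if abs(float(self.q_p.sum()) - 1.0) > _SUM_TOL:
            raise ValueError("pure-sample averages must sum to 1")
        if abs(float(self.q_ma.sum() + self.q_mb.sum()) - 1.0) > _SUM_TOL:
            raise ValueError("mixed-sample averages must jointly sum to 1")


@dataclass
class LatentPosterior:
    """Posterior assignment weights of one read over its candidates.

    Pure reads carry ``q``; mixed reads carry the cell-type pair
    ``q_a``/``q_b`` (jointly normalized).
    """

    transcripts: np.ndarray
    q: np.ndarray | None = None
    q_a: np.ndarray | None = None
    q_b: np.ndarray | None = None

    @property
    def is_mixed(self) -> bool:
        return self.q is None


class ZeroLikelihoodRead(ValueError):
    """All candidate terms of a read vanished."""


def e_step_pure(group, params: ModelParams, l_eff: EffectiveLengths, weights=None) -> LatentPosterior:
    """Posterior over candidates of a pure-sample read."""
    t = group.transcripts
    num = params.alpha_a.alpha[t] / l_eff.l_eff[t]
    if weights is not None:
        num = num * weights
    z = float(num.sum())
    if z <= 0.0:
        raise ZeroLikelihoodRead(group.read_id)
    return LatentPosterior(transcripts=t, q=num / z)


def e_step_mixed(group, params: ModelParams, l_eff: EffectiveLengths, weights=None) -> LatentPosterior:
    """Joint posterior over (candidate, cell type) of a mixed-sample read."""
    t = group.transcripts
    le = l_eff.l_eff[t]
    na = params.tau_a * params.alpha_a.alpha[t] / le
    nb = params.tau_b * params.alpha_b.alpha[t] / le
    if weights is not None:
        na = na * weights
        nb = nb * weights
    z = float(na.sum() + nb.sum())
    if z <= 0.0:
        raise ZeroLikelihoodRead(group.read_id)
    return LatentPosterior(transcripts=t, q_a=na / z, q_b=nb / z)


def step_size(n: int, forget_sigma: float) -> float:
    return float((n + 2.0) ** (-forget_sigma))


def interpolate_stats(
    stats: SufficientStats, posterior: LatentPosterior, n: int, forget_sigma: float
) -> SufficientStats:
    """Fold one read's posterior into the running averages (step index n)."""
    gamma = step_size(n, forget_sigma)
    if posterior.is_mixed:
        q_ma = (1.0 - gamma) * stats.q_ma
        q_mb = (1.0 - gamma) * stats.q_mb
        np.add.at(q_ma, posterior.transcripts, gamma * posterior.q_a)
        np.add.at(q_mb, posterior.transcripts, gamma * posterior.q_b)
        return SufficientStats(q_p=stats.q_p.copy(), q_ma=q_ma, q_mb=q_mb)
    q_p = (1.0 - gamma) * stats.q_p
    np.add.at(q_p, posterior.transcripts, gamma * posterior.q)
    return SufficientStats(q_p=q_p, q_ma=stats.q_ma.copy(), q_mb=stats.q_mb.copy())


def m_step(
    stats: SufficientStats,
    beta_a: float,
    beta_b: float,
    n_mixed: int,
    prev_alpha_b: np.ndarray | None = None,
) -> ModelParams:
    """Map sufficient statistics to model parameters.

    The mixing proportion uses the MAP update; the sampling profiles are
    renormalized after the update so that each sums to exactly 1 (the raw
    update only normalizes at the maximum-likelihood fixed point).
    """
    if n_mixed < 1:
        raise ValueError("n_mixed must be >= 1")
    s_ma = float(stats.q_ma.sum())
    tau_a = (s_ma + (beta_a - 1.0) / n_mixed) / (1.0 + (beta_a + beta_b - 2.0) / n_mixed)
    tau_a = min(max(tau_a, 0.0), 1.0)
    tau_b = 1.0 - tau_a

    raw_a = (stats.q_p + stats.q_ma) / (1.0 + tau_a)
    alpha_a = SamplingProfile(raw_a / raw_a.sum())

    s_mb = float(stats.q_mb.sum())
    if tau_b < TAU_FLOOR or s_mb <= 0.0:
        logger.warning("m_step: tau_b below floor; holding alpha_b fixed")
        if prev_alpha_b is None:
            prev_alpha_b = np.full(len(stats.q_p), 1.0 / len(stats.q_p))
        alpha_b = SamplingProfile(np.asarray(prev_alpha_b, dtype=np.float64))
    else:
        raw_b = stats.q_mb / tau_b
        alpha_b = SamplingProfile(raw_b / raw_b.sum())

    return ModelParams(
        alpha_a=alpha_a,
        alpha_b=alpha_b,
        tau_a=tau_a,
        tau_b=tau_b,
        beta_a=max(1.0, beta_a),
        beta_b=max(1.0, beta_b),
    )


@dataclass
class EMResult:
    params: ModelParams
    stats: SufficientStats
    trace: list[float]
    n_pure: int
    n_mixed: int
    skipped_reads: int = 0
    bias_models: tuple | None = None


@dataclass
class SingleFitResult:
    """Result of the naive single-sample (no deconvolution) fit."""

    alpha: SamplingProfile
    q: np.ndarray
    trace: list[float]
    n_reads: int
    skipped_reads: int = 0
    bias_models: tuple | None = None


def _pooled_alpha(q_p, q_ma, q_mb, n_pure, n_mixed):
    """Sampling profile of the pooled pure+mixed read stream (bias training)."""
    pooled = n_pure * q_p + n_mixed * (q_ma + q_mb)
    return SamplingProfile(pooled / pooled.sum())


def run_online_em(
    pure_groups,
    mixed_groups,
    catalog: TranscriptCatalog,
    l_eff: EffectiveLengths,
    prior: tuple[float, float, float],
    config: EMConfig,
    bias_config: bias_mod.BiasConfig | None = None,
) -> EMResult:
    """Fit the two-sample mixture by online MAP-EM.

    ``prior`` is (prior proportion of type a, of type b, beta scale); the
    Beta pseudo-counts are ``beta = proportion * beta_scale * n_mixed``,
    floored at 1. Reads are processed in a seeded shuffled interleave of
    both streams, each read updating its own sample's running averages with
    a per-stream step counter that continues across epochs. When the bias
    module is enabled, one bias-free warm-up pass precedes training of the
    (then frozen) bias models.
    """
    pure_groups = list(pure_groups)
    mixed_groups = list(mixed_groups)
    if not pure_groups or not mixed_groups:
        raise ValueError("both read streams must be non-empty")

    T = catalog.size
    n_pure, n_mixed = len(pure_groups), len(mixed_groups)
    p_a, p_b, beta_scale = prior
    if not (0.0 <= p_b <= 1.0 and abs(p_a + p_b - 1.0) <= 1e-9):
        raise ValueError("prior proportions must be in [0,1] and sum to 1")
    beta_a = max(1.0, p_a * beta_scale * n_mixed)
    beta_b = max(1.0, p_b * beta_scale * n_mixed)

    le = l_eff.l_eff
    sigma = config.forget_sigma
    rng = np.random.default_rng(config.seed)

    # scaled running averages: actual q = scale * array
    tau_a, tau_b = p_a, p_b  # prior mean (exact Beta mean up to the beta>=1 floor)
    Qp = np.full(T, 1.0 / T)
    sp = 1.0
    Qma = np.full(T, tau_a / T)
    Qmb = np.full(T, tau_b / T)
    sm = 1.0
    s_ma, s_mb = tau_a, tau_b
    np_ctr = 0  # pure-stream step counter
    nm_ctr = 0  # mixed-stream step counter
    uniform = 1.0 / T
    skipped = 0
    steps_since_m = 0
    tau_den = 1.0 + (beta_a + beta_b - 2.0) / n_mixed
    beta_off = (beta_a - 1.0) / n_mixed

    weights_pure: list[np.ndarray] | None = None
    weights_mixed: list[np.ndarray] | None = None
    bias_models = None
    bias_on = bias_config is not None and bias_config.enabled
    total_epochs = config.epochs + (1 if bias_on else 0)

    merged = np.arange(n_pure + n_mixed)
    trace: list[float] = []

    for epoch in range(total_epochs):
        order = rng.permutation(merged)
        for j in order:
            if j < n_pure:
                g = pure_groups[j]
                c = g.transcripts
                w = weights_pure[j] if weights_pure is not None else None
                qp_c = sp * Qp[c]
                qma_c = sm * Qma[c]
                num = (qp_c + qma_c) / ((1.0 + s_ma) * le[c])
                if w is not None:
                    num = num * w
                z = num.sum()
                if z <= 0.0:
                    skipped += 1
                    continue
                q = num / z
                gamma = (np_ctr + 2.0) ** (-sigma)
                sp *= 1.0 - gamma
                Qp[c] += (gamma / sp) * q
                np_ctr += 1
                if sp < 1e-200:
                    Qp *= sp
                    sp = 1.0
            else:
                g = mixed_groups[j - n_pure]
                c = g.transcripts
                w = weights_mixed[j - n_pure] if weights_mixed is not None else None
                qp_c = sp * Qp[c]
                qma_c = sm * Qma[c]
                qmb_c = sm * Qmb[c]
                aa = (qp_c + qma_c) / (1.0 + s_ma)
                if s_mb > TAU_FLOOR:
                    ab = qmb_c / s_mb
                else:
                    ab = uniform
                na = tau_a * aa / le[c]
                nb = tau_b * ab / le[c]
                if w is not None:
                    na = na * w
                    nb = nb * w
                z = na.sum() + nb.sum()
                if z <= 0.0:
                    skipped += 1
                    continue
                qa = na / z
                qb = nb / z
                gamma = (nm_ctr + 2.0) ** (-sigma)
                keep = 1.0 - gamma
                sm *= keep
                Qma[c] += (gamma / sm) * qa
                Qmb[c] += (gamma / sm) * qb
                s_ma = keep * s_ma + gamma * qa.sum()
                s_mb = keep * s_mb + gamma * qb.sum()
                nm_ctr += 1
                if sm < 1e-200:
                    Qma *= sm
                    Qmb *= sm
                    sm = 1.0
            steps_since_m += 1
            if steps_since_m >= config.minibatch:
                steps_since_m = 0
                tau_a = min(max((s_ma + beta_off) / tau_den, 0.0), 1.0)
                tau_b = 1.0 - tau_a

        if bias_on and epoch == 0:
            stats = SufficientStats(q_p=sp * Qp, q_ma=sm * Qma, q_mb=sm * Qmb)
            pooled = _pooled_alpha(stats.q_p, stats.q_ma, stats.q_mb, n_pure, n_mixed)
            bias_models = bias_mod.train_bias(
                pure_groups + mixed_groups, catalog, l_eff, pooled, bias_config
            )
            weights_pure = bias_mod.weight_groups(pure_groups, bias_models, catalog, l_eff)
            weights_mixed = bias_mod.weight_groups(mixed_groups, bias_models, catalog, l_eff)
            continue  # warm-up pass does not count toward convergence

        stats = SufficientStats(q_p=sp * Qp, q_ma=sm * Qma, q_mb=sm * Qmb)
        params = m_step(stats, beta_a, beta_b, n_mixed)
        lp = log_posterior(params, pure_groups, mixed_groups, l_eff, weights_pure, weights_mixed)
        if not np.isfinite(lp) or not np.isfinite(params.tau_a):
            raise RuntimeError(f"online EM diverged (epoch {epoch}); trace: {trace + [lp]}")
        trace.append(lp)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(lp - prev) <= config.tol * (abs(prev) + 1e-12):
                break

    stats = SufficientStats(q_p=sp * Qp, q_ma=sm * Qma, q_mb=sm * Qmb)
    params = m_step(stats, beta_a, beta_b, n_mixed)
    if skipped:
        logger.warning("online EM: %d reads skipped with zero likelihood", skipped)
    return EMResult(
        params=params,
        stats=stats,
        trace=trace,
        n_pure=n_pure,
        n_mixed=n_mixed,
        skipped_reads=skipped,
        bias_models=bias_models,
    )


def run_single_em(
    groups,
    catalog: TranscriptCatalog,
    l_eff: EffectiveLengths,
    config: EMConfig,
    bias_config: bias_mod.BiasConfig | None = None,
) -> SingleFitResult:
    """Naive mode: online EM on one read set treated as a pure sample."""
    groups = list(groups)
    if not groups:
        raise ValueError("read stream must be non-empty")
    T = catalog.size
    le = l_eff.l_eff
    sigma = config.forget_sigma
    rng = np.random.default_rng(config.seed)

    Qp = np.full(T, 1.0 / T)
    sp = 1.0
    n_ctr = 0
    skipped = 0
    weights: list[np.ndarray] | None = None
    bias_models = None
    bias_on = bias_config is not None and bias_config.enabled
    total_epochs = config.epochs + (1 if bias_on else 0)
    trace: list[float] = []
    uniform_b = SamplingProfile(np.full(T, 1.0 / T))

    for epoch in range(total_epochs):
        order = rng.permutation(len(groups))
        for j in order:
            g = groups[j]
            c = g.transcripts
            w = weights[j] if weights is not None else None
            num = sp * Qp[c] / le[c]
            if w is not None:
                num = num * w
            z = num.sum()
            if z <= 0.0:
                skipped += 1
                continue
            q = num / z
            gamma = (n_ctr + 2.0) ** (-sigma)
            sp *= 1.0 - gamma
            Qp[c] += (gamma / sp) * q
            n_ctr += 1
            if sp < 1e-200:
                Qp *= sp
                sp = 1.0

        if bias_on and epoch == 0:
            alpha = SamplingProfile(sp * Qp / (sp * Qp).sum())
            bias_models = bias_mod.train_bias(groups, catalog, l_eff, alpha, bias_config)
            weights = bias_mod.weight_groups(groups, bias_models, catalog, l_eff)
            continue

        q_p = sp * Qp
        alpha = SamplingProfile(q_p / q_p.sum())
        params = ModelParams(alpha_a=alpha, alpha_b=uniform_b, tau_a=1.0, tau_b=0.0)
        lp = log_posterior(params, groups, [], l_eff, weights, None)
        if not np.isfinite(lp):
            raise RuntimeError(f"single-sample EM diverged; trace: {trace + [lp]}")
        trace.append(lp)
        if len(trace) >= 2 and abs(lp - trace[-2]) <= config.tol * (abs(trace[-2]) + 1e-12):
            break

    q_p = sp * Qp
    alpha = SamplingProfile(q_p / q_p.sum())
    if skipped:
        logger.warning("single-sample EM: %d reads skipped", skipped)
    return SingleFitResult(
        alpha=alpha,
        q=q_p,
        trace=trace,
        n_reads=len(groups),
        skipped_reads=skipped,
        bias_models=bias_models,
    )


@dataclass
class BatchEMResult:
    params: ModelParams
    trace: list[float]
    stats: SufficientStats


def batch_em_oracle(
    pure_groups,
    mixed_groups,
    catalog: TranscriptCatalog,
    l_eff: EffectiveLengths,
    priors: tuple[float, float],
    n_iter: int = 100,
    weights_pure=None,
    weights_mixed=None,
) -> BatchEMResult:
    """Classic in-memory EM on the full posterior, written independently of
    the online path; the log-posterior is asserted nondecreasing.

    ``priors`` are the Beta pseudo-counts (beta_a, beta_b) directly.
    """
    pure_groups = list(pure_groups)
    mixed_groups = list(mixed_groups)
    T = catalog.size
    le = l_eff.l_eff
    beta_a, beta_b = priors
    n_mixed = len(mixed_groups)

    alpha_a = np.full(T, 1.0 / T)
    alpha_b = np.full(T, 1.0 / T)
    tau_a = beta_a / (beta_a + beta_b)
    tau_b = 1.0 - tau_a
    trace: list[float] = []
    n_p = n_ma = n_mb = None

    for it in range(n_iter):
        n_p = np.zeros(T)
        n_ma = np.zeros(T)
        n_mb = np.zeros(T)
        for j, g in enumerate(pure_groups):
            c = g.transcripts
            num = alpha_a[c] / le[c]
            if weights_pure is not None:
                num = num * weights_pure[j]
            z = num.sum()
            if z <= 0.0:
                continue
            np.add.at(n_p, c, num / z)
        for j, g in enumerate(mixed_groups):
            c = g.transcripts
            na = tau_a * alpha_a[c] / le[c]
            nb = tau_b * alpha_b[c] / le[c]
            if weights_mixed is not None:
                na = na * weights_mixed[j]
                nb = nb * weights_mixed[j]
            z = na.sum() + nb.sum()
            if z <= 0.0:
                continue
            np.add.at(n_ma, c, na / z)
            np.add.at(n_mb, c, nb / z)

        n_assigned = float(n_ma.sum() + n_mb.sum())
        tau_a = (n_ma.sum() + beta_a - 1.0) / (n_assigned + beta_a + beta_b - 2.0)
        tau_a = min(max(float(tau_a), 0.0), 1.0)
        tau_b = 1.0 - tau_a
        tot_a = float(n_p.sum() + n_ma.sum())
        alpha_a = (n_p + n_ma) / tot_a
        if n_mb.sum() > 0.0:
            alpha_b = n_mb / n_mb.sum()

        params = ModelParams(
            alpha_a=SamplingProfile(alpha_a),
            alpha_b=SamplingProfile(alpha_b),
            tau_a=tau_a,
            tau_b=tau_b,
            beta_a=max(1.0, beta_a),
            beta_b=max(1.0, beta_b),
        )
        lp = log_posterior(params, pure_groups, mixed_groups, l_eff, weights_pure, weights_mixed)
        if trace and lp < trace[-1] - 1e-9 * abs(trace[-1]):
            raise AssertionError(
                f"batch EM log-posterior decreased at iteration {it}: {trace[-1]} -> {lp}"
            )
        trace.append(lp)

    n_pure_used = max(1.0, float(n_p.sum()))
    stats = SufficientStats(
        q_p=n_p / n_pure_used,
        q_ma=n_ma / max(1.0, n_assigned),
        q_mb=n_mb / max(1.0, n_assigned),
    )
    return BatchEMResult(params=params, trace=trace, stats=stats)
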