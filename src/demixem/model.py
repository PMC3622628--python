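"""Core domain types and probability transforms.

Holds the transcript catalog, fragment-length model, abundance/sampling
profiles, effective-length computation, the conversions between relative
abundance (``rho``) and read sampling probability (``alpha``), the mixing
diagnostics, and the unnormalized log-posterior used for convergence
monitoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: tolerance for "sums to one" checks on probability profiles
PROFILE_TOL = 1e-9


class DegenerateProfileError(ValueError):
    """Raised when a profile conversion has an all-zero numerator."""


@dataclass(frozen=True)
class TranscriptCatalog:
    """The reference transcript set: ids, lengths and optional sequences."""

    ids: tuple[str, ...]
    lengths: np.ndarray
    sequences: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        lengths = np.asarray(self.lengths, dtype=np.int64)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "lengths", lengths)
        if len(ids) < 1:
            raise ValueError("catalog must contain at least one transcript")
        if len(set(ids)) != len(ids):
            raise ValueError("transcript ids must be unique")
        if lengths.shape != (len(ids),):
            raise ValueError("lengths must align with ids")
        if np.any(lengths < 1):
            raise ValueError("all transcript lengths must be >= 1")
        if self.sequences is not None:
            seqs = tuple(self.sequences)
            object.__setattr__(self, "sequences", seqs)
            if len(seqs) != len(ids):
                raise ValueError("sequences must align with ids")
            for s, l in zip(seqs, lengths):
                if len(s) != l:
                    raise ValueError("sequence length must equal declared length")

    @property
    def size(self) -> int:
        return len(self.ids)

    def index_map(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.ids)}


@dataclass(frozen=True)
class FragmentModel:
    """Normal fragment-length distribution (mean, standard deviation)."""

    mu: float = 200.0
    sigma: float = 80.0

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("fragment mean must be positive")
        if self.sigma < 0:
            raise ValueError("fragment sigma must be nonnegative")


def _check_profile(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.size < 1:
        raise ValueError(f"{name} must be a nonempty 1-d vector")
    if np.any(values < 0):
        raise ValueError(f"{name} entries must be nonnegative")
    if abs(float(values.sum()) - 1.0) > PROFILE_TOL:
        raise ValueError(f"{name} must sum to 1 within {PROFILE_TOL}")
    return values


@dataclass(frozen=True)
class AbundanceProfile:
    """Per-transcript relative abundance; sums to one."""

    rho: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rho", _check_profile(self.rho, "rho"))


@dataclass(frozen=True)
class SamplingProfile:
    """Per-transcript read sampling probability; sums to one."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", _check_profile(self.alpha, "alpha"))


@dataclass(frozen=True)
class EffectiveLengths:
    """Per-transcript effective length, each within [1, l_t]."""

    l_eff: np.ndarray

    def __post_init__(self) -> None:
        l_eff = np.asarray(self.l_eff, dtype=np.float64)
        object.__setattr__(self, "l_eff", l_eff)
        if np.any(l_eff < 1.0):
            raise ValueError("effective lengths must be >= 1")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: two sampling profiles, mixing proportions, prior."""

    alpha_a: SamplingProfile
    alpha_b: SamplingProfile
    tau_a: float
    tau_b: float
    beta_a: float = 1.0
    beta_b: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.tau_a + self.tau_b - 1.0) > PROFILE_TOL:
            raise ValueError("tau_a + tau_b must equal 1")
        if not (0.0 <= self.tau_a <= 1.0 and 0.0 <= self.tau_b <= 1.0):
            raise ValueError("mixing proportions must lie in [0, 1]")
        if self.beta_a < 1.0 or self.beta_b < 1.0:
            raise ValueError("Beta prior pseudo-counts must be >= 1")


# ---------------------------------------------------------------------------
# effective length


def _fallback_eff_length(l_t: float, mu: float) -> float:
    return float(min(max(1.0, l_t - mu + 1.0), l_t))


def effective_length(l_t: int, frag: FragmentModel) -> float:
    """Expected number of read start positions in a transcript of length ``l_t``.

    The fragment length is normal(mu, sigma^2) renormalized over the
    discrete support {1, ..., l_t}; the effective length is the expectation
    of ``l_t - x + 1`` under that distribution, clamped to [1, l_t].
    ``sigma == 0`` is a point mass at ``round(mu)``.
    """
    if l_t < 1:
        raise ValueError("transcript length must be >= 1")
    if frag.sigma == 0:
        x0 = int(round(frag.mu))
        if x0 <= l_t:
            return float(max(1.0, l_t - x0 + 1.0))
        return _fallback_eff_length(l_t, frag.mu)
    x = np.arange(1, l_t + 1, dtype=np.float64)
    pdf = norm.pdf(x, loc=frag.mu, scale=frag.sigma)
    total = float(pdf.sum())
    if not np.isfinite(total) or total <= 0.0:
        return _fallback_eff_length(l_t, frag.mu)
    value = float(np.sum(pdf * (l_t - x + 1.0)) / total)
    return float(min(max(1.0, value), l_t))


def effective_lengths(catalog: TranscriptCatalog, frag: FragmentModel) -> EffectiveLengths:
    """Vectorized :func:`effective_length` over a catalog.

    Uses cumulative sums of the fragment pdf over a shared grid so the cost
    is O(max length + T) rather than O(sum of lengths).
    """
    lengths = catalog.lengths
    if frag.sigma == 0:
        out = np.array([effective_length(int(l), frag) for l in lengths])
        return EffectiveLengths(out)
    max_l = int(lengths.max())
    x = np.arange(1, max_l + 1, dtype=np.float64)
    pdf = norm.pdf(x, loc=frag.mu, scale=frag.sigma)
    c0 = np.cumsum(pdf)
    c1 = np.cumsum(x * pdf)
    idx = lengths - 1
    total = c0[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = ((lengths + 1.0) * c0[idx] - c1[idx]) / total
    bad = ~np.isfinite(vals) | (total <= 0.0)
    if np.any(bad):
        vals = vals.copy()
        vals[bad] = [_fallback_eff_length(float(l), frag.mu) for l in lengths[bad]]
    out = np.minimum(np.maximum(vals, 1.0), lengths.astype(np.float64))
    return EffectiveLengths(out)


# ---------------------------------------------------------------------------
# profile conversions


def rho_to_alpha(rho: AbundanceProfile, l_eff: EffectiveLengths) -> SamplingProfile:
    """Read sampling probability: abundance weighted by effective length."""
    w = rho.rho * l_eff.l_eff
    total = float(w.sum())
    if total <= 0.0:
        raise DegenerateProfileError("all rho * effective-length products are zero")
    return SamplingProfile(w / total)


def alpha_to_rho(alpha: SamplingProfile, l_eff: EffectiveLengths) -> AbundanceProfile:
    """Inverse of :func:`rho_to_alpha`."""
    w = alpha.alpha / l_eff.l_eff
    total = float(w.sum())
    if total <= 0.0:
        raise DegenerateProfileError("all alpha / effective-length ratios are zero")
    return AbundanceProfile(w / total)


def mixed_alpha_linear(
    alpha_a: SamplingProfile,
    alpha_b: SamplingProfile,
    tau_a: float,
    tau_b: float,
) -> SamplingProfile:
    """Linear approximation of the mixed-sample sampling profile."""
    if abs(tau_a + tau_b - 1.0) > PROFILE_TOL:
        raise ValueError("tau_a + tau_b must equal 1")
    return SamplingProfile(tau_a * alpha_a.alpha + tau_b * alpha_b.alpha)


def mixing_factors(
    rho_a: AbundanceProfile,
    rho_b: AbundanceProfile,
    tau_a: float,
    tau_b: float,
    l_eff: EffectiveLengths,
) -> tuple[float, float]:
    """Diagnostic nonlinearity factors of the exact mixed-sample profile.

    Both equal 1 when the two abundance profiles (or all effective lengths)
    coincide; values near 1 justify the linear mixing approximation. These
    are never applied during estimation.
    """
    if abs(tau_a + tau_b - 1.0) > PROFILE_TOL:
        raise ValueError("tau_a + tau_b must equal 1")
    num_a = float(np.sum(rho_a.rho * l_eff.l_eff))
    num_b = float(np.sum(rho_b.rho * l_eff.l_eff))
    rho_m = tau_a * rho_a.rho + tau_b * rho_b.rho
    den = float(np.sum(rho_m * l_eff.l_eff))
    return num_a / den, num_b / den


# ---------------------------------------------------------------------------
# log posterior


def log_posterior(
    params: ModelParams,
    pure_groups,
    mixed_groups,
    l_eff: EffectiveLengths,
    weights_pure=None,
    weights_mixed=None,
) -> float:
    """Unnormalized log-posterior of the model given both read sets.

    ``weights_*`` are optional per-group candidate bias-weight vectors
    (parallel to the group lists); ``None`` means all weights are 1.
    Reads whose candidate terms all vanish are excluded with a warning.
    """
    le = l_eff.l_eff
    a_a = params.alpha_a.alpha
    a_b = params.alpha_b.alpha
    mix = params.tau_a * a_a + params.tau_b * a_b
    total = 0.0
    n_skipped = 0

    for groups, rates, weights in (
        (pure_groups, a_a, weights_pure),
        (mixed_groups, mix, weights_mixed),
    ):
        for j, g in enumerate(groups):
            t = g.transcripts
            terms = rates[t] / le[t]
            if weights is not None:
                terms = terms * weights[j]
            s = float(terms.sum())
            if s <= 0.0:
                n_skipped += 1
                continue
            total += np.log(s)

    if n_skipped:
        logger.warning("log_posterior: %d reads had zero total weight", n_skipped)
    # Beta prior terms; exponent 0 contributes nothing even at tau == 0.
    if params.beta_a > 1.0:
        total += (params.beta_a - 1.0) * np.log(params.tau_a)
    if params.beta_b > 1.0:
        total += (params.beta_b - 1.0) * np.log(params.tau_b)
    return float(total)
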