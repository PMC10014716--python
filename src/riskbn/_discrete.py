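"""Bounded discrete distributions matched to target moments.

Psychometric sum scores (PHQ-8, GAD-7, loneliness, ...) live on a bounded
integer support and are summarised in the literature by mean and SD alone.
To reproduce such a marginal we fit a discrete exponential family with
linear and quadratic sufficient statistics,

    p(k)  ∝  exp(a·t + b·t²+ c·1[k ≥ k0]),   t = (k − lo)/(hi − lo),

which for b < 0 is exactly a discretized truncated normal and for b ≥ 0
extends continuously to flatter / endpoint-heavy shapes (some published
scale SDs exceed the discretized-normal maximum at the given mean, e.g. a
mean of 8.38 with SD 6.99 on 0..24).  The optional step term at ``k0``
(``c``, the *tilt*) moves tail mass P(K ≥ k0) while the (a, b) re-solve
keeps mean and SD pinned; the survey generator uses it to calibrate the
depression-flag rate without disturbing the printed PHQ-8 moments.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

__all__ = ["DiscreteScaleDistribution", "fit_scale_pmf"]


class ScaleFitError(ValueError):
    """Raised when no distribution on the support attains the target moments."""


def _pmf(a: float, b: float, t: np.ndarray, step: np.ndarray) -> np.ndarray:
    logit = a * t + b * t * t + step
    logit -= logit.max()
    p = np.exp(logit)
    return p / p.sum()


def fit_scale_pmf(
    mean: float,
    sd: float,
    lo: int,
    hi: int,
    tilt_at: int | None = None,
    tilt: float = 0.0,
) -> np.ndarray:
    """Return the pmf over ``lo..hi`` with the requested mean and SD.

    Raises :class:`ScaleFitError` when the pair (mean, sd) is not attainable
    on the support (the mean must lie in [lo, hi] and the variance below the
    two-point bound (mean-lo)(hi-mean)).
    """
    if not lo <= mean <= hi:
        raise ScaleFitError(f"target mean {mean} outside support [{lo}, {hi}]")
    if sd <= 0:
        raise ScaleFitError("target sd must be positive")
    if sd**2 >= (mean - lo) * (hi - mean):
        raise ScaleFitError(
            f"target sd {sd} unattainable on [{lo}, {hi}] at mean {mean}"
        )
    ks = np.arange(lo, hi + 1, dtype=float)
    t = (ks - lo) / (hi - lo)
    step = (ks >= tilt_at).astype(float) * tilt if tilt_at is not None else np.zeros_like(t)

    def resid(x):
        p = _pmf(x[0], x[1], t, step)
        m = float(ks @ p)
        v = float(p @ (ks - m) ** 2)
        return [m - mean, np.sqrt(max(v, 1e-300)) - sd]

    # start from the normal-kernel parameterisation of the targets
    b0 = -0.5 * ((hi - lo) / sd) ** 2
    a0 = -2.0 * b0 * (mean - lo) / (hi - lo)
    x, info, ier, msg = optimize.fsolve(resid, [a0, b0], full_output=True)
    if ier != 1 or max(abs(r) for r in resid(x)) > 1e-6:
        # retry from a flat start; the moment map is smooth and monotone
        x, info, ier, msg = optimize.fsolve(resid, [0.0, 0.0], full_output=True)
        if ier != 1 or max(abs(r) for r in resid(x)) > 1e-6:
            raise ScaleFitError(
                f"moment matching failed on [{lo},{hi}] for mean={mean}, sd={sd}: {msg}"
            )
    return _pmf(x[0], x[1], t, step)


class DiscreteScaleDistribution:
    """Moment-matched distribution on an integer support with quantile mapping."""

    def __init__(self, mean, sd, lo, hi, tilt_at=None, tilt=0.0):
        self.lo, self.hi = int(lo), int(hi)
        self.mean_target, self.sd_target = float(mean), float(sd)
        self.tilt_at, self.tilt = tilt_at, float(tilt)
        self.pmf = fit_scale_pmf(mean, sd, lo, hi, tilt_at=tilt_at, tilt=tilt)
        self.values = np.arange(self.lo, self.hi + 1)
        self.cdf = np.cumsum(self.pmf)
        self.cdf[-1] = 1.0

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Generalised inverse CDF: smallest k with F(k) >= u."""
        idx = np.searchsorted(self.cdf, u, side="left")
        return self.values[np.clip(idx, 0, len(self.values) - 1)]

    def from_latent(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal latents through the Gaussian copula onto the scale."""
        from scipy.stats import norm

        return self.ppf(norm.cdf(z))

    def tail_prob(self, k0: int) -> float:
        return float(self.pmf[self.values >= k0].sum())

    @property
    def moments(self) -> tuple[float, float]:
        m = float(self.values @ self.pmf)
        v = float(self.pmf @ (self.values - m) ** 2)
        return m, np.sqrt(v)
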