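"""Second-generation p-values, their power function, and empirical-Bayes PPV.

A second-generation p-value (p_delta) compares an uncertainty interval
I = [lo, hi] for the log odds ratio with a pre-specified interval null
N = [null_lo, null_hi] — the "indifference zone" of effect sizes too small to
matter clinically:

    p_delta = (|I ∩ N| / |I|) * max(|I| / (2|N|), 1)

The small-sample correction factor caps the contribution of very wide
intervals (|I| > 2|N|) and never changes which findings get p_delta = 0.
p_delta = 0 means the data support only clinically meaningful effect sizes
(interval fully outside the indifference zone); p_delta = 1 confirms a null.

For a point estimate theta_hat ~ N(theta, se^2) with a level-gamma Wald
interval, the probability of declaring a finding is

    P(p_delta = 0 | theta) = Phi((null_lo - theta)/se - z)
                           + Phi((theta - null_hi)/se - z)

with z the two-sided gamma quantile.  Averaging this power function under a
uniform prior over the null interval (alpha) and under a uniform distribution
over the observed interval (1 - beta) gives the empirical-Bayes positive
predictive value

    PPV = 1 - [1 + ((1-beta)/alpha) * ((1-pi0)/pi0)]^(-1)

where pi0 is the prior probability of the null (0.5 by default, the
non-informative choice).  All interval arithmetic happens on the log-odds
scale; configuration accepts odds-ratio-scale nulls and log-transforms them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateIntervalError
from .screen import IntervalEstimate

__all__ = [
    "NullInterval",
    "sgpv",
    "classify",
    "sgpv_power",
    "ppv",
    "SgpvRanker",
]

_GL_ORDER = 64  # Gauss-Legendre nodes per integral; integrands are smooth


@dataclass(frozen=True)
class NullInterval:
    """Interval null hypothesis on the log-odds scale."""

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ConfigError(
                f"null interval requires lo < hi, got [{self.lo}, {self.hi}]"
            )
        if not (self.lo <= 0.0 <= self.hi):
            warnings.warn(
                "null interval does not contain OR=1 (log-odds 0); "
                "is this indifference zone intended?",
                stacklevel=2,
            )

    @classmethod
    def from_or(cls, lo: float, hi: float) -> "NullInterval":
        """Build from odds-ratio-scale bounds, e.g. (0.3, 1.5)."""
        if lo <= 0 or hi <= 0:
            raise ConfigError("odds-ratio null bounds must be positive")
        return cls(math.log(lo), math.log(hi))

    @property
    def width(self) -> float:
        return self.hi - self.lo


def _interval_bounds(interval) -> tuple[float, float]:
    if isinstance(interval, IntervalEstimate):
        return interval.lo, interval.hi
    lo, hi = interval
    return float(lo), float(hi)


def sgpv(interval, null: NullInterval) -> float:
    """Second-generation p-value of ``interval`` against ``null``.

    ``interval`` is an IntervalEstimate or a (lo, hi) pair, both on the
    log-odds scale.  Returns a value in [0, 1]; exactly 0 iff the intervals
    are disjoint, exactly 1 iff the estimate lies inside the null and is no
    wider than twice the null.
    """
    lo, hi = _interval_bounds(interval)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise DegenerateIntervalError("interval estimate must be finite")
    if not lo < hi:
        raise DegenerateIntervalError(
            f"zero-width interval estimate [{lo}, {hi}]"
        )
    overlap = max(0.0, min(hi, null.hi) - max(lo, null.lo))
    width = hi - lo
    p = (overlap / width) * max(width / (2.0 * null.width), 1.0)
    return min(1.0, p)


def classify(p_delta: float) -> str:
    """Map p_delta to {significant, inconclusive, confirmed_null}."""
    if p_delta == 0.0:
        return "significant"
    if p_delta == 1.0:
        return "confirmed_null"
    return "inconclusive"


def sgpv_power(theta, se: float, null: NullInterval, level: float = 0.95):
    """P(p_delta = 0 | theta) under the normal approximation.

    Vectorized over ``theta``.  This is the probability that the level-gamma
    Wald interval around theta_hat ~ N(theta, se^2) clears the null interval
    entirely on one side or the other.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    theta = np.asarray(theta, dtype=float)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    below = stats.norm.cdf((null.lo - theta) / se - z)
    above = stats.norm.cdf((theta - null.hi) / se - z)
    out = below + above
    return float(out) if out.ndim == 0 else out


def _uniform_average_power(
    a: float, b: float, se: float, null: NullInterval, level: float
) -> float:
    """Mean of the power function under Uniform[a, b], by Gauss-Legendre."""
    nodes, weights = np.polynomial.legendre.leggauss(_GL_ORDER)
    theta = 0.5 * (b - a) * nodes + 0.5 * (a + b)
    vals = sgpv_power(theta, se, null, level)
    # leggauss weights sum to 2; (1/(b-a)) * (b-a)/2 * sum(w v) = mean
    return float(np.sum(weights * vals) / 2.0)


def ppv(
    interval,
    null: NullInterval,
    pi0: float = 0.5,
    level: float = 0.95,
    se: float | None = None,
) -> float:
    """Empirical-Bayes positive predictive value of a p_delta = 0 finding.

    alpha  = average power under f0 ~ Uniform[null.lo, null.hi]
    1-beta = average power under f1 ~ Uniform[interval lo, hi] (the observed
             uncertainty interval; data-dependent by design)
    PPV    = 1 - [1 + ((1-beta)/alpha) * ((1-pi0)/pi0)]^(-1)

    ``se`` defaults to the interval's own standard error (recovered from the
    Wald width when a bare (lo, hi) pair is passed).  Integrals use
    fixed-order Gauss-Legendre quadrature, so the value is deterministic.
    """
    if not 0.0 <= pi0 <= 1.0:
        raise ConfigError("pi0 must be in [0, 1]")
    lo, hi = _interval_bounds(interval)
    if not lo < hi:
        raise DegenerateIntervalError(f"zero-width interval [{lo}, {hi}]")
    if se is None:
        if isinstance(interval, IntervalEstimate):
            se = interval.se
        else:
            z = stats.norm.ppf(1 - (1 - level) / 2)
            se = (hi - lo) / (2 * z)
    if pi0 == 0.0:
        return 1.0
    if pi0 == 1.0:
        return 0.0

    alpha = _uniform_average_power(null.lo, null.hi, se, null, level)
    power_alt = _uniform_average_power(lo, hi, se, null, level)
    if alpha <= 0.0:
        # the null can essentially never produce p_delta = 0: certainty
        return 1.0
    bayes_factor = (power_alt / alpha) * ((1 - pi0) / pi0)
    return 1.0 - 1.0 / (1.0 + bayes_factor)


class SgpvRanker:
    """Attach SGPV, classification and PPV columns to a screen results table.

    sklearn-style transformer (stateless fit).  Expects the DataFrame emitted
    by :class:`phedas.screen.PhecodeScreen`: columns ``theta``, ``se``,
    ``ci_lo``, ``ci_hi`` (log-odds scale), ``converged``, ``separation``.

    Parameters
    ----------
    null_or : (float, float)
        Null interval on the odds-ratio scale, e.g. ``(0.3, 1.5)``.
    pi0 : float, default 0.5
        Prior probability of the null.
    level : float, default 0.95
        Confidence level used for the Wald intervals and the power function.

    Separated or non-converged fits get NaN sgpv/ppv and classification
    ``not_evaluated``; findings whose interval lies entirely *below* the null
    are flagged ``negative_direction`` (less clinical interest, but the
    p_delta itself is unchanged).
    """

    def __init__(self, null_or=(0.3, 1.5), pi0: float = 0.5, level: float = 0.95):
        self.null_or = tuple(null_or)
        self.pi0 = pi0
        self.level = level

    def get_params(self, deep=True):
        return {"null_or": self.null_or, "pi0": self.pi0, "level": self.level}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @property
    def null_(self) -> NullInterval:
        return NullInterval.from_or(*self.null_or)

    def fit(self, X=None, y=None):
        return self

    def transform(self, results: "pd.DataFrame") -> "pd.DataFrame":
        import pandas as pd  # local: keep module import light

        null = self.null_
        out = results.copy()
        sg, pv, cls, neg = [], [], [], []
        for _, row in out.iterrows():
            if not row["converged"] or row.get("separation", False):
                sg.append(np.nan)
                pv.append(np.nan)
                cls.append("not_evaluated")
                neg.append(False)
                continue
            p_delta = sgpv((row["ci_lo"], row["ci_hi"]), null)
            sg.append(p_delta)
            cls.append(classify(p_delta))
            neg.append(bool(row["ci_hi"] < null.lo))
            if p_delta == 0.0:
                pv.append(
                    ppv((row["ci_lo"], row["ci_hi"]), null,
                        pi0=self.pi0, level=self.level, se=row["se"])
                )
            else:
                pv.append(np.nan)  # PPV defined only for p_delta = 0 findings
        out["sgpv"] = sg
        out["ppv"] = pv
        out["classification"] = cls
        out["negative_direction"] = neg
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
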