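"""Latent generative mechanics for family-planning trajectories.

The annual latent state of a country/marital group is a four-way composition
(modern use, traditional use, unmet need, no need).  It is driven by three
modelled quantities: prevalence of any-method use (a logistic transition in
time), the modern share among users (a second logistic transition), and the
unmet-need fraction among non-users (a monotone function of prevalence, not of
time).  Autocorrelated deviations on the log-odds scale perturb the two
transition curves around their systematic paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import invlogit, logit

__all__ = [
    "TransitionParams",
    "Composition",
    "YEAR_GRID",
    "logistic_transition",
    "unmet_link",
    "compose_shares",
    "ar1_deviations",
    "latent_trajectory",
]

#: Annual estimation/projection grid.
YEAR_GRID = np.arange(1970, 2031)


@dataclass
class TransitionParams:
    """Country-level parameters of the latent process for one marital group.

    ``asymptote_*`` are long-run maximum levels in (0, 1]; ``rate_*`` are
    per-year logistic growth rates (> 0); ``midpoint_*`` are the calendar years
    at which the curve reaches half its asymptote.  ``unmet_intercept`` and the
    world-level ``unmet_slope`` parameterise the prevalence-to-unmet link on
    the log-odds scale.  ``ar_rho``/``ar_sd`` are the AR(1) parameters of the
    deviation processes for (any-use, modern-share).
    """

    asymptote_any: float
    rate_any: float
    midpoint_any: float
    asymptote_ratio: float
    rate_ratio: float
    midpoint_ratio: float
    unmet_intercept: float
    unmet_slope: float
    ar_rho: tuple[float, float] = (0.85, 0.85)
    ar_sd: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("asymptote_any", "asymptote_ratio"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("rate_any", "rate_ratio"):
            v = getattr(self, name)
            if v <= 0.0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for i, rho in enumerate(self.ar_rho):
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"ar_rho[{i}] must be in [0, 1), got {rho}")
        for i, sd in enumerate(self.ar_sd):
            if sd < 0.0:
                raise ValueError(f"ar_sd[{i}] must be >= 0, got {sd}")


@dataclass
class Composition:
    """Four-way partition of a population; shares sum to one."""

    modern: float
    traditional: float
    unmet: float
    no_need: float

    _TOL = 1e-9

    def __post_init__(self) -> None:
        total = self.modern + self.traditional + self.unmet + self.no_need
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"composition shares sum to {total}, not 1")
        for name in ("modern", "traditional", "unmet", "no_need"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def use_any(self) -> float:
        return self.modern + self.traditional

    @property
    def need(self) -> float:
        return self.use_any + self.unmet

    def as_array(self) -> np.ndarray:
        return np.array([self.modern, self.traditional, self.unmet, self.no_need])


def logistic_transition(t, asymptote: float, rate: float, midpoint: float):
    """Evaluate the S-shaped transition curve at time(s) ``t``.

    Returns ``asymptote / (1 + exp(-rate * (t - midpoint)))``: strictly
    increasing in ``t``, bounded above by ``asymptote``, and equal to half the
    asymptote at the midpoint.
    """
    if not (0.0 < asymptote <= 1.0):
        raise ValueError(f"asymptote must be in (0, 1], got {asymptote}")
    if rate <= 0.0:
        raise ValueError(f"rate must be > 0, got {rate}")
    t = np.asarray(t, dtype=float)
    out = asymptote * invlogit(rate * (t - midpoint))
    if np.ndim(out) == 0:
        return float(out)
    return out


def unmet_link(p_any, intercept: float, slope: float):
    """Unmet-need fraction among non-users as a function of prevalence.

    ``inverse-logit(intercept + slope * p_any)``; increasing in prevalence for
    positive slope.  The overall unmet share ``(1 - p) * unmet_link(p)`` then
    rises with prevalence before declining to zero as use saturates.
    """
    p_any = np.asarray(p_any, dtype=float)
    if np.any(p_any < -1e-12) or np.any(p_any > 1.0 + 1e-12):
        raise ValueError("p_any must lie in [0, 1]")
    out = invlogit(intercept + slope * p_any)
    if np.ndim(out) == 0:
        return float(out)
    return out


def compose_shares(p_any: float, r_modern: float, u_nonusers: float) -> Composition:
    """Assemble the four-way composition from the three modelled quantities."""
    for name, v in (("p_any", p_any), ("r_modern", r_modern), ("u_nonusers", u_nonusers)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return Composition(
        modern=p_any * r_modern,
        traditional=p_any * (1.0 - r_modern),
        unmet=(1.0 - p_any) * u_nonusers,
        no_need=(1.0 - p_any) * (1.0 - u_nonusers),
    )


def ar1_deviations(n_years: int, rho: float, sd: float, seed) -> np.ndarray:
    """Draw one stationary AR(1) path of length ``n_years``.

    The first value is drawn from the stationary law N(0, sd^2 / (1 - rho^2));
    subsequent values follow the recursion ``x_t = rho x_{t-1} + e_t`` with
    innovation sd ``sd``.  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if sd < 0.0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sd == 0.0:
        # still consume the same number of variates so seeds line up
        rng.standard_normal(n_years)
        return np.zeros(n_years)
    z = rng.standard_normal(n_years)
    x = np.empty(n_years)
    x[0] = z[0] * sd / np.sqrt(1.0 - rho**2)
    for t in range(1, n_years):
        x[t] = rho * x[t - 1] + sd * z[t]
    return x


def systematic_logits(params: TransitionParams, years) -> tuple[np.ndarray, np.ndarray]:
    """Log-odds of the systematic any-use and modern-share curves."""
    years = np.asarray(years, dtype=float)
    p_any = logistic_transition(years, params.asymptote_any, params.rate_any, params.midpoint_any)
    r_mod = logistic_transition(
        years, params.asymptote_ratio, params.rate_ratio, params.midpoint_ratio
    )
    return logit(p_any), logit(r_mod)


def latent_trajectory(
    params: TransitionParams,
    years,
    deviations_any=None,
    deviations_ratio=None,
) -> list[Composition]:
    """Latent annual compositions given parameters and aligned deviation series.

    Deviations perturb the systematic curves on the log-odds scale; the unmet
    link is applied to the deviated prevalence.  Passing ``None`` for a
    deviation series is equivalent to all zeros.
    """
    years = np.asarray(years, dtype=float)
    n = years.size
    d_any = np.zeros(n) if deviations_any is None else np.asarray(deviations_any, dtype=float)
    d_rat = np.zeros(n) if deviations_ratio is None else np.asarray(deviations_ratio, dtype=float)
    if d_any.size != n or d_rat.size != n:
        raise ValueError("deviation series must align with the year grid")
    l_any, l_rat = systematic_logits(params, years)
    p_any = invlogit(l_any + d_any)
    r_mod = invlogit(l_rat + d_rat)
    u = unmet_link(p_any, params.unmet_intercept, params.unmet_slope)
    return [
        compose_shares(float(p_any[i]), float(r_mod[i]), float(u[i])) for i in range(n)
    ]
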