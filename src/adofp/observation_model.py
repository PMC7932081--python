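"""Likelihood of survey observations given the latent composition.

Surveys that sampled non-baseline populations (e.g. age-18+ only) receive
additive shifts on the log-odds scale for prevalence and for the unmet-need
fraction; surveys known to misreport method type reallocate a share of mass
between the modern and traditional categories while leaving any-method use
untouched.  Observation errors are independent normals on the log-odds scale
with variance = delta-method sampling variance + source-specific
non-sampling variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import BASELINE_FLAGS, MISCLASS_FLAGS, SOURCE_TYPES, SurveyObservation
from .process_model import Composition
from .util import invlogit, logit, norm_logpdf

__all__ = [
    "BiasParams",
    "expected_observation",
    "observation_loglik",
    "sampling_variance_logit",
    "continuity_correct",
]

DEFAULT_EFFECTIVE_N = 1000


def _default_nonsampling_sd() -> dict:
    return {s: 0.1 for s in SOURCE_TYPES}


def _default_sampling_var() -> dict:
    # fallback logit-scale sampling variance when no SE is reported
    return {s: 0.04 for s in SOURCE_TYPES}


@dataclass
class BiasParams:
    """Bias and misclassification adjustment parameters.

    ``shift_any``/``shift_unmet`` are additive log-odds shifts per baseline
    (non-baseline-sample) flag.  ``misclass_realloc`` gives, per flag, the
    share of the smaller category moved: ``modern_inflated`` and
    ``methods_combined`` move that share of traditional use into modern;
    ``traditional_inflated`` moves that share of modern use into traditional.
    ``nonsampling_sd`` is the extra log-odds-scale error sd by source type.
    """

    shift_any: dict = field(default_factory=lambda: {f: 0.0 for f in BASELINE_FLAGS})
    shift_unmet: dict = field(default_factory=lambda: {f: 0.0 for f in BASELINE_FLAGS})
    misclass_realloc: dict = field(default_factory=lambda: {f: 0.0 for f in MISCLASS_FLAGS})
    nonsampling_sd: dict = field(default_factory=_default_nonsampling_sd)
    default_sampling_var: dict = field(default_factory=_default_sampling_var)

    def __post_init__(self) -> None:
        for s, v in self.nonsampling_sd.items():
            if v < 0:
                raise ValueError(f"nonsampling_sd[{s}] must be >= 0")


def continuity_correct(p: float, n: int = DEFAULT_EFFECTIVE_N) -> float:
    """Replace boundary proportions by 1/(2n) and 1 - 1/(2n)."""
    lo = 1.0 / (2 * n)
    return min(max(p, lo), 1.0 - lo)


def sampling_variance_logit(p: float, se: float, n: int = DEFAULT_EFFECTIVE_N) -> float:
    """Delta-method transform of a proportion-scale SE to the log-odds scale."""
    if se < 0:
        raise ValueError("se must be >= 0")
    p = continuity_correct(p, n)
    return (se / (p * (1.0 - p))) ** 2


def expected_observation(latent: Composition, flags, bias: BiasParams) -> dict:
    """Expected observed summaries on the log-odds scale for a flagged survey.

    Returns a dict with keys ``logit_any``, ``logit_modern``,
    ``logit_traditional`` and ``logit_unmet``.  With no flags this is the
    identity transform of the latent composition.
    """
    flags = frozenset(flags)
    unknown = flags - set(BASELINE_FLAGS) - set(MISCLASS_FLAGS)
    if unknown:
        raise ValueError(f"unknown flags: {sorted(unknown)}")

    p_any = latent.use_any
    modern, trad = latent.modern, latent.traditional
    for f in flags & set(MISCLASS_FLAGS):
        k = bias.misclass_realloc.get(f, 0.0)
        if f in ("modern_inflated", "methods_combined"):
            moved = k * trad
            modern, trad = modern + moved, trad - moved
        else:  # traditional_inflated
            moved = k * modern
            modern, trad = modern - moved, trad + moved

    shift_a = sum(bias.shift_any.get(f, 0.0) for f in flags & set(BASELINE_FLAGS))
    shift_u = sum(bias.shift_unmet.get(f, 0.0) for f in flags & set(BASELINE_FLAGS))

    nonuse = 1.0 - p_any
    u = latent.unmet / nonuse if nonuse > 0 else 0.0
    p_any_adj = invlogit(logit(p_any) + shift_a)
    u_adj = invlogit(logit(u) + shift_u)
    return {
        "logit_any": float(logit(p_any) + shift_a),
        "logit_modern": float(logit(modern) + shift_a),
        "logit_traditional": float(logit(trad) + shift_a),
        "logit_unmet": float(logit((1.0 - p_any_adj) * u_adj)),
    }


def _total_variance(p_obs, se, source_type: str, bias: BiasParams) -> float:
    if se is not None and se > 0:
        v_samp = sampling_variance_logit(p_obs, se)
    else:
        v_samp = bias.default_sampling_var.get(source_type, 0.04)
    return v_samp + bias.nonsampling_sd.get(source_type, 0.0) ** 2


def observation_loglik(
    obs: SurveyObservation,
    latent: Composition,
    bias: BiasParams,
    effective_n: int = DEFAULT_EFFECTIVE_N,
) -> float:
    """Log-density of one observation's present indicators given the latent state.

    Independent normal terms on the log-odds scale for any-method use, modern
    use and unmet need (traditional use is redundant given any + modern and is
    not scored).  Boundary proportions are continuity-corrected.
    """
    expected = expected_observation(latent, obs.baseline_flags | obs.misclass_flags, bias)
    terms = []
    for p_obs, se, key in (
        (obs.p_any, obs.se_any, "logit_any"),
        (obs.p_modern, obs.se_modern, "logit_modern"),
        (obs.p_unmet, obs.se_unmet, "logit_unmet"),
    ):
        if p_obs is None:
            continue
        v = _total_variance(p_obs, se, obs.source_type, bias)
        if v <= 0:
            raise ValueError("total observation variance must be positive")
        y = logit(continuity_correct(p_obs, effective_n))
        terms.append(float(norm_logpdf(y, expected[key], v)))
    if not terms:
        raise ValueError("observation carries no indicator values")
    return float(sum(terms))
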