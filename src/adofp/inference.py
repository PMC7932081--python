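"""Posterior estimation by adaptive Metropolis-within-Gibbs, and projection.

The sampler alternates through blocks: country-level transition parameters
(random-walk updates, vectorised across countries, one coordinate at a time),
AR(1) deviation fields (chequerboard updates proposing from the process
conditional prior so the acceptance ratio is the observation-likelihood ratio
alone), hierarchical node means (conjugate Gibbs), level standard deviations,
the world unmet-need slope, AR parameters, and bias/misclassification
parameters.  Proposal scales adapt during warmup only, so the post-warmup
chain is a valid time-homogeneous Markov chain.

Trajectories beyond the last observation year are produced by
:func:`project`, which continues each draw's deviation process forward from
its final sampled value using that draw's AR parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import BASELINE_FLAGS, MISCLASS_FLAGS, SOURCE_TYPES
from .hierarchy import N_PARAMS, PARAM_NAMES, HierarchyTree, build_hierarchy
from .observation_model import DEFAULT_EFFECTIVE_N, continuity_correct, sampling_variance_logit
from .util import invlogit, logit, norm_logpdf

GRID_START, GRID_END = 1970, 2030

__all__ = [
    "ModelConfig",
    "McmcConfig",
    "PosteriorSamples",
    "fit",
    "project",
    "diagnostics",
    "split_rhat",
    "effective_sample_size",
]


def _default_world_mean() -> np.ndarray:
    # logit asym_any, log rate_any, mid_any, logit asym_ratio, log rate_ratio,
    # mid_ratio, unmet intercept
    return np.array([0.0, -2.0, 2000.0, 1.5, -2.0, 1995.0, -1.0])


def _default_world_sd() -> np.ndarray:
    return np.array([1.0, 0.5, 15.0, 1.0, 0.5, 15.0, 1.0])


def _default_sd_scale() -> np.ndarray:
    # half-normal hyperprior scales for the level sds, per parameter
    return np.array([0.5, 0.3, 5.0, 0.5, 0.3, 5.0, 0.5])


@dataclass
class ModelConfig:
    """Priors and structural switches of the estimation model."""

    world_mean: np.ndarray = field(default_factory=_default_world_mean)
    world_prior_sd: np.ndarray = field(default_factory=_default_world_sd)
    sd_scale: np.ndarray = field(default_factory=_default_sd_scale)
    sd_init_frac: float = 0.5  # level sds start at sd_scale * this
    unmet_slope_prior: tuple = (1.0, 2.0)  # normal (mean, sd)
    ar_rho_logit_prior: tuple = (1.5, 1.0)  # normal on logit(rho)
    ar_sd_scale: float = 0.15  # half-normal scale
    bias_shift_prior_sd: float = 0.5
    misclass_logit_prior: tuple = (0.0, 1.5)
    nonsampling_sd: dict = field(default_factory=lambda: {s: 0.1 for s in SOURCE_TYPES})
    default_sampling_var: dict = field(default_factory=lambda: {s: 0.04 for s in SOURCE_TYPES})
    effective_n: int = DEFAULT_EFFECTIVE_N
    # structural switches (used by toy/oracle configurations)
    sample_deviations: bool = True
    sample_hyper: bool = True
    sample_sds: bool = True
    sample_slope: bool = True
    sample_ar: bool = True
    sample_bias: bool = True
    free_mask: np.ndarray = field(default_factory=lambda: np.ones(N_PARAMS, dtype=bool))
    init_theta: np.ndarray | None = None
    fixed_slope: float = 1.0
    fixed_ar_rho: tuple = (0.8, 0.8)
    fixed_ar_sd: tuple = (0.1, 0.1)
    fit_end_year: int | None = None

    def fingerprint(self) -> str:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in vars(self).items()
            if not isinstance(v, dict)
        }
        payload["nonsampling_sd"] = sorted(self.nonsampling_sd.items())
        payload["default_sampling_var"] = sorted(self.default_sampling_var.items())
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class McmcConfig:
    n_chains: int = 4
    n_iterations: int = 10_000
    n_warmup: int = 5_000
    thinning: int = 5
    seed: int = 0
    adapt_target_scalar: float = 0.44
    adapt_target_joint: float = 0.234
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if not (self.n_iterations > self.n_warmup >= 0):
            raise ValueError("need n_iterations > n_warmup >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorSamples:
    """Retained posterior draws for one marital group.

    Trajectory arrays are (draws, countries, years) on the probability scale;
    parameter arrays are per draw.  ``dev_last`` holds the final sampled AR(1)
    deviation per component, the anchor for forward projection.
    """

    marital_group: str
    countries: list
    years: np.ndarray
    fit_end_year: int
    p_any: np.ndarray
    r_modern: np.ndarray
    u_nonusers: np.ndarray
    theta: np.ndarray  # (D, C, 7) unconstrained country params
    slope: np.ndarray  # (D,)
    ar_rho: np.ndarray  # (D, 2)
    ar_sd: np.ndarray  # (D, 2)
    dev_last: np.ndarray  # (D, C, 2)
    world_mean_draws: np.ndarray  # (D, 7)
    level_sd_draws: np.ndarray  # (D, 3, 7) country/mid/top
    bias_draws: np.ndarray  # (D, 9) shifts_any(3), shifts_unmet(3), realloc_logit(3)
    chain_id: np.ndarray  # (D,)
    seed: int
    config_fingerprint: str

    @property
    def n_draws(self) -> int:
        return self.p_any.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.chain_id.size else 0

    def composition(self) -> np.ndarray:
        """Four-way composition per (draw, country, year); sums to one."""
        pa = self.p_any.astype(np.float64)
        r = self.r_modern.astype(np.float64)
        u = self.u_nonusers.astype(np.float64)
        return np.stack(
            [pa * r, pa * (1 - r), (1 - pa) * u, (1 - pa) * (1 - u)], axis=-1
        )

    def year_index(self, year: int) -> int:
        i = int(year) - int(self.years[0])
        if not (0 <= i < self.years.size):
            raise KeyError(f"year {year} outside sample grid")
        return i


# ---------------------------------------------------------------------------
# data preparation


class _ObsData:
    """Observation table flattened into aligned numpy arrays."""

    def __init__(self, observations, countries, years_fit, config: ModelConfig):
        cindex = {c: i for i, c in enumerate(countries)}
        T = years_fit.size
        rows = [o for o in observations if o.country_code in cindex]
        N = len(rows)
        self.n_obs = N
        self.c_idx = np.zeros(N, dtype=int)
        self.t_idx = np.zeros(N, dtype=int)
        self.t_dec = np.zeros(N)
        self.y = np.full((N, 3), np.nan)  # any, modern, unmet on logit scale
        self.var = np.full((N, 3), np.nan)
        self.Fb = np.zeros((N, len(BASELINE_FLAGS)))
        self.Fm = np.zeros((N, len(MISCLASS_FLAGS)))
        en = config.effective_n
        for i, o in enumerate(rows):
            self.c_idx[i] = cindex[o.country_code]
            self.t_dec[i] = o.ref_year
            self.t_idx[i] = int(np.clip(round(o.ref_year - years_fit[0]), 0, T - 1))
            for j, (p, se) in enumerate(
                ((o.p_any, o.se_any), (o.p_modern, o.se_modern), (o.p_unmet, o.se_unmet))
            ):
                if p is None:
                    continue
                self.y[i, j] = logit(continuity_correct(p, en))
                if se is not None and se > 0:
                    v = sampling_variance_logit(p, se, en)
                else:
                    v = config.default_sampling_var.get(o.source_type, 0.04)
                v += config.nonsampling_sd.get(o.source_type, 0.0) ** 2
                self.var[i, j] = v
            for j, f in enumerate(BASELINE_FLAGS):
                self.Fb[i, j] = float(f in o.baseline_flags)
            for j, f in enumerate(MISCLASS_FLAGS):
                self.Fm[i, j] = float(f in o.misclass_flags)
        self.present = ~np.isnan(self.y)
        self.y0 = np.where(self.present, self.y, 0.0)
        self.v0 = np.where(self.present, self.var, 1.0)
        self.any_flagged = bool(N) and bool(self.Fb.any() or self.Fm.any())
        # residual weights and the constant normalisation term of the normal
        # log-density, so the likelihood loop only computes weighted squares
        self.w = np.where(self.present, 0.5 / self.v0, 0.0)
        self.ll_const = np.where(self.present, -0.5 * np.log(2.0 * np.pi * self.v0), 0.0).sum(axis=1)


def _sys_any(data: _ObsData, theta):
    """Systematic any-use log-odds at observation times (N,)."""
    c, td = data.c_idx, data.t_dec
    return logit(invlogit(theta[c, 0]) * invlogit(np.exp(theta[c, 1]) * (td - theta[c, 2])))


def _sys_rat(data: _ObsData, theta):
    """Systematic modern-share log-odds at observation times (N,)."""
    c, td = data.c_idx, data.t_dec
    return logit(invlogit(theta[c, 3]) * invlogit(np.exp(theta[c, 4]) * (td - theta[c, 5])))


def _ll_from(data: _ObsData, la_sys, lr_sys, u0, dev_any_obs, dev_rat_obs, slope, bias_vec):
    """Per-observation log-likelihood (N,) from cached systematic pieces.

    ``la_sys``/``lr_sys`` are systematic log-odds per observation, ``u0`` the
    unmet intercept per observation, ``dev_*_obs`` the deviation values gathered
    at each observation's country-year site.
    """
    la = la_sys + dev_any_obs
    lr = lr_sys + dev_rat_obs
    pa = invlogit(la)
    modern = pa * invlogit(lr)

    if data.any_flagged:
        trad = pa - modern
        # modern_inflated and methods_combined move traditional into modern;
        # traditional_inflated moves modern out
        realloc = invlogit(bias_vec[6:9])
        gain = (data.Fm[:, 0] * realloc[0] + data.Fm[:, 2] * realloc[2]) * trad
        loss = data.Fm[:, 1] * realloc[1] * modern
        mod_exp = np.minimum(np.maximum(modern + gain - loss, 1e-12), 1.0 - 1e-12)
        shift_a = data.Fb @ bias_vec[0:3]
        shift_u = data.Fb @ bias_vec[3:6]
        mean_any = la + shift_a
        mean_mod = logit(mod_exp) + shift_a
        pa_adj = invlogit(mean_any)
        # logit(unmet_link) is linear in its argument, so the shift adds directly
        u_adj = invlogit(u0 + slope * pa + shift_u)
        mean_unmet = logit((1.0 - pa_adj) * u_adj)
    else:
        mean_any = la
        mean_mod = logit(modern)
        u = invlogit(u0 + slope * pa)
        mean_unmet = logit((1.0 - pa) * u)

    w = data.w
    return (
        data.ll_const
        - w[:, 0] * (data.y0[:, 0] - mean_any) ** 2
        - w[:, 1] * (data.y0[:, 1] - mean_mod) ** 2
        - w[:, 2] * (data.y0[:, 2] - mean_unmet) ** 2
    )


def _obs_loglik(data: _ObsData, theta, dev_any, dev_rat, slope, bias_vec):
    """Per-observation log-likelihood (N,); reference entry point."""
    if data.n_obs == 0:
        return np.zeros(0)
    c, t = data.c_idx, data.t_idx
    return _ll_from(
        data, _sys_any(data, theta), _sys_rat(data, theta), theta[c, 6],
        dev_any[c, t], dev_rat[c, t], slope, bias_vec,
    )


def _ar_logpdf(dev, rho, sd):
    """Stationary AR(1) log-density of deviation rows (C, T)."""
    if sd <= 0:
        return 0.0 if np.allclose(dev, 0.0) else -np.inf
    C, T = dev.shape
    v0 = sd**2 / (1.0 - rho**2)
    ll = -0.5 * (C * np.log(2 * np.pi * v0) + float(dev[:, 0] @ dev[:, 0]) / v0)
    if T > 1:
        resid = dev[:, 1:] - rho * dev[:, :-1]
        ll += -0.5 * (C * (T - 1) * np.log(2 * np.pi * sd**2) + float(np.sum(resid * resid)) / sd**2)
    return float(ll)


def _halfnormal_logpdf(x, scale):
    if np.any(np.asarray(x) < 0):
        return -np.inf
    return float(np.sum(-np.log(scale) - 0.5 * (np.asarray(x) / scale) ** 2))


# ---------------------------------------------------------------------------
# sampler


class _ChainState:
    def __init__(self, tree: HierarchyTree, config: ModelConfig):
        C = tree.n_countries
        M = len(tree.mid_nodes)
        Tn = len(tree.top_nodes)
        wm = np.asarray(config.world_mean, dtype=float)
        self.theta = (
            np.array(config.init_theta, dtype=float)
            if config.init_theta is not None
            else np.tile(wm, (C, 1))
        )
        self.mid_means = np.tile(wm, (M, 1))
        self.top_means = np.tile(wm, (Tn, 1))
        self.world_mean = wm.copy()
        init_sd = np.asarray(config.sd_scale, dtype=float) * config.sd_init_frac
        self.sd_country = init_sd.copy()
        self.sd_mid = init_sd.copy()
        self.sd_top = init_sd.copy()
        self.slope = float(config.fixed_slope if not config.sample_slope else config.unmet_slope_prior[0])
        self.ar_rho = np.array(config.fixed_ar_rho, dtype=float)
        self.ar_sd = np.array(config.fixed_ar_sd, dtype=float)
        self.bias = np.zeros(9)
        self.dev = None  # set once fit window known: (2, C, Tfit)


def _run_chain(data: _ObsData, tree, config: ModelConfig, mcmc: McmcConfig, rng, Tfit, n_keep, keep_every, start_keep):
    C = tree.n_countries
    st = _ChainState(tree, config)
    st.dev = np.zeros((2, C, Tfit))
    wm_prior_sd = np.asarray(config.world_prior_sd, dtype=float)
    free = np.asarray(config.free_mask, dtype=bool)
    parity_sites = [np.arange(0, Tfit, 2), np.arange(1, Tfit, 2)]

    # adaptive proposal scales
    step_theta = np.full((C, N_PARAMS), 0.2)
    step_theta[:, [2, 5]] = 4.0  # midpoints live on the year scale
    step_sd = 0.3
    step_slope = 0.3
    step_ar = 0.2
    step_bias = 0.15

    # cached per-observation pieces, kept in sync with the state
    oc, ot = data.c_idx, data.t_idx
    la_sys = _sys_any(data, st.theta) if data.n_obs else np.zeros(0)
    lr_sys = _sys_rat(data, st.theta) if data.n_obs else np.zeros(0)
    u0 = st.theta[oc, 6] if data.n_obs else np.zeros(0)

    def loglik_all():
        if data.n_obs == 0:
            return np.zeros(0)
        return _ll_from(data, la_sys, lr_sys, u0, st.dev[0][oc, ot], st.dev[1][oc, ot], st.slope, st.bias)

    ll_obs = loglik_all()
    if not np.all(np.isfinite(ll_obs)):
        bad = np.where(~np.isfinite(ll_obs))[0]
        raise FloatingPointError(
            f"non-finite log-likelihood at initialization for observation(s) {bad[:5].tolist()}"
        )

    # storage
    out = {
        "theta": np.empty((n_keep, C, N_PARAMS), dtype=np.float64),
        "slope": np.empty(n_keep),
        "ar_rho": np.empty((n_keep, 2)),
        "ar_sd": np.empty((n_keep, 2)),
        "dev": np.empty((n_keep, 2, C, Tfit), dtype=np.float32),
        "world_mean": np.empty((n_keep, N_PARAMS)),
        "level_sd": np.empty((n_keep, 3, N_PARAMS)),
        "bias": np.empty((n_keep, 9)),
    }
    kept = 0

    mid_of = tree.country_parent
    top_of = tree.mid_parent
    n_child_mid = np.bincount(mid_of, minlength=len(tree.mid_nodes)).astype(float)
    n_child_top = np.bincount(top_of, minlength=len(tree.top_nodes)).astype(float)

    for it in range(mcmc.n_iterations):
        adapting = it < mcmc.n_warmup
        eta = 1.0 / (1.0 + 0.1 * it) if adapting else 0.0

        # --- country parameter coordinates -------------------------------
        ll_c = np.bincount(oc, weights=ll_obs, minlength=C) if data.n_obs else np.zeros(C)
        dev_a_obs = st.dev[0][oc, ot] if data.n_obs else np.zeros(0)
        dev_r_obs = st.dev[1][oc, ot] if data.n_obs else np.zeros(0)
        for j in range(N_PARAMS):
            if not free[j]:
                continue
            prop = st.theta.copy()
            prop[:, j] = st.theta[:, j] + step_theta[:, j] * rng.standard_normal(C)
            if data.n_obs:
                la_p, lr_p, u0_p = la_sys, lr_sys, u0
                if j < 3:
                    la_p = _sys_any(data, prop)
                elif j < 6:
                    lr_p = _sys_rat(data, prop)
                else:
                    u0_p = prop[oc, 6]
                ll_obs_p = _ll_from(data, la_p, lr_p, u0_p, dev_a_obs, dev_r_obs, st.slope, st.bias)
                ll_c_p = np.bincount(oc, weights=ll_obs_p, minlength=C)
            else:
                ll_c_p = np.zeros(C)
            mu = st.mid_means[mid_of, j]
            sdj = st.sd_country[j]
            dprior = norm_logpdf(prop[:, j], mu, sdj**2) - norm_logpdf(st.theta[:, j], mu, sdj**2)
            logacc = ll_c_p - ll_c + dprior
            acc = np.log(rng.random(C)) < logacc
            st.theta[acc, j] = prop[acc, j]
            if data.n_obs and acc.any():
                replaced = acc[oc]
                ll_obs = np.where(replaced, ll_obs_p, ll_obs)
                ll_c = np.where(acc, ll_c_p, ll_c)
                if j < 3:
                    la_sys = np.where(replaced, la_p, la_sys)
                elif j < 6:
                    lr_sys = np.where(replaced, lr_p, lr_sys)
                else:
                    u0 = np.where(replaced, u0_p, u0)
            if adapting:
                step_theta[:, j] *= np.exp(
                    eta * (np.where(acc, 1.0, 0.0) - mcmc.adapt_target_scalar)
                )
                np.clip(step_theta[:, j], 1e-4, 50.0, out=step_theta[:, j])

        # --- deviation fields --------------------------------------------
        if config.sample_deviations:
            for comp in range(2):
                rho, sd = st.ar_rho[comp], st.ar_sd[comp]
                if sd <= 0:
                    continue
                for sites in parity_sites:
                    dev = st.dev[comp]
                    mean = np.empty((C, sites.size))
                    var = np.empty((C, sites.size))
                    interior = (sites > 0) & (sites < Tfit - 1)
                    si = sites[interior]
                    mean[:, interior] = rho * (dev[:, si - 1] + dev[:, si + 1]) / (1 + rho**2)
                    var[:, interior] = sd**2 / (1 + rho**2)
                    if sites[0] == 0:
                        mean[:, 0] = rho * dev[:, 1] if Tfit > 1 else 0.0
                        var[:, 0] = sd**2 if Tfit > 1 else sd**2 / (1 - rho**2)
                    if sites[-1] == Tfit - 1 and Tfit > 1:
                        mean[:, -1] = rho * dev[:, Tfit - 2]
                        var[:, -1] = sd**2
                    prop_vals = mean + np.sqrt(var) * rng.standard_normal((C, sites.size))
                    if data.n_obs:
                        dev_prop = dev.copy()
                        dev_prop[:, sites] = prop_vals
                        d0 = dev_prop if comp == 0 else st.dev[0]
                        d1 = dev_prop if comp == 1 else st.dev[1]
                        ll_obs_p = _ll_from(
                            data, la_sys, lr_sys, u0, d0[oc, ot], d1[oc, ot], st.slope, st.bias
                        )
                        key = oc * Tfit + ot
                        site_cur = np.bincount(key, weights=ll_obs, minlength=C * Tfit).reshape(C, Tfit)
                        site_prop = np.bincount(key, weights=ll_obs_p, minlength=C * Tfit).reshape(C, Tfit)
                        dll = (site_prop - site_cur)[:, sites]
                    else:
                        dll = np.zeros((C, sites.size))
                    acc = np.log(rng.random((C, sites.size))) < dll
                    new = dev[:, sites].copy()
                    new[acc] = prop_vals[acc]
                    st.dev[comp][:, sites] = new
                    if data.n_obs:
                        # each observation depends on exactly one site per
                        # component, so its proposed loglik is valid iff that
                        # site was accepted
                        acc_full = np.zeros((C, Tfit), dtype=bool)
                        acc_full[:, sites] = acc
                        replaced = acc_full[oc, ot]
                        ll_obs = np.where(replaced, ll_obs_p, ll_obs)

        # --- hierarchical means (conjugate Gibbs) ------------------------
        if config.sample_hyper:
            sums_mid = np.zeros((len(tree.mid_nodes), N_PARAMS))
            np.add.at(sums_mid, mid_of, st.theta)
            prec = n_child_mid[:, None] / st.sd_country**2 + 1.0 / st.sd_mid**2
            mu = (sums_mid / st.sd_country**2 + st.top_means[top_of] / st.sd_mid**2) / prec
            st.mid_means = mu + rng.standard_normal(mu.shape) / np.sqrt(prec)

            sums_top = np.zeros((len(tree.top_nodes), N_PARAMS))
            np.add.at(sums_top, top_of, st.mid_means)
            prec = n_child_top[:, None] / st.sd_mid**2 + 1.0 / st.sd_top**2
            mu = (sums_top / st.sd_mid**2 + st.world_mean[None, :] / st.sd_top**2) / prec
            st.top_means = mu + rng.standard_normal(mu.shape) / np.sqrt(prec)

            k = len(tree.top_nodes)
            prec = k / st.sd_top**2 + 1.0 / wm_prior_sd**2
            mu = (st.top_means.sum(axis=0) / st.sd_top**2 + np.asarray(config.world_mean) / wm_prior_sd**2) / prec
            st.world_mean = mu + rng.standard_normal(N_PARAMS) / np.sqrt(prec)

        # --- level sds ----------------------------------------------------
        if config.sample_hyper and config.sample_sds:
            for sd_vec, child, parent_vals, n_res in (
                (st.sd_country, st.theta, st.mid_means[mid_of], C),
                (st.sd_mid, st.mid_means, st.top_means[top_of], len(tree.mid_nodes)),
                (st.sd_top, st.top_means, np.tile(st.world_mean, (len(tree.top_nodes), 1)), len(tree.top_nodes)),
            ):
                rss = ((child - parent_vals) ** 2).sum(axis=0)
                prop = sd_vec * np.exp(step_sd * rng.standard_normal(N_PARAMS))
                scale = np.asarray(config.sd_scale, dtype=float)

                def sd_logpost(s):
                    return (
                        -n_res * np.log(s)
                        - rss / (2 * s**2)
                        - 0.5 * (s / scale) ** 2
                        + np.log(s)  # log-scale Jacobian
                    )

                logacc = sd_logpost(prop) - sd_logpost(sd_vec)
                acc = np.log(rng.random(N_PARAMS)) < logacc
                sd_vec[acc] = prop[acc]

        # --- unmet slope --------------------------------------------------
        if config.sample_slope:
            prop = st.slope + step_slope * rng.standard_normal()
            ll_obs_p = (
                _ll_from(data, la_sys, lr_sys, u0, st.dev[0][oc, ot], st.dev[1][oc, ot], prop, st.bias)
                if data.n_obs
                else np.zeros(0)
            )
            m0, s0 = config.unmet_slope_prior
            dl = ll_obs_p.sum() - ll_obs.sum() + float(
                norm_logpdf(prop, m0, s0**2) - norm_logpdf(st.slope, m0, s0**2)
            )
            if np.log(rng.random()) < dl:
                st.slope = prop
                ll_obs = ll_obs_p
                a = 1.0
            else:
                a = 0.0
            if adapting:
                step_slope = float(np.clip(step_slope * np.exp(eta * (a - mcmc.adapt_target_scalar)), 1e-3, 5.0))

        # --- AR parameters ------------------------------------------------
        if config.sample_ar and config.sample_deviations:
            for comp in range(2):
                lrho = logit(st.ar_rho[comp])
                lsd = np.log(max(st.ar_sd[comp], 1e-8))
                prop_lrho = lrho + step_ar * rng.standard_normal()
                prop_lsd = lsd + step_ar * rng.standard_normal()
                rho_p, sd_p = float(invlogit(prop_lrho)), float(np.exp(prop_lsd))
                m0, s0 = config.ar_rho_logit_prior

                def ar_post(lr, ls, rho, sd):
                    return (
                        _ar_logpdf(st.dev[comp], rho, sd)
                        + float(norm_logpdf(lr, m0, s0**2))
                        + _halfnormal_logpdf(sd, config.ar_sd_scale)
                        + ls  # Jacobian of log(sd)
                        + float(np.log(rho) + np.log1p(-rho))  # Jacobian of logit(rho)
                    )

                dl = ar_post(prop_lrho, prop_lsd, rho_p, sd_p) - ar_post(
                    lrho, lsd, st.ar_rho[comp], st.ar_sd[comp]
                )
                if np.log(rng.random()) < dl:
                    st.ar_rho[comp], st.ar_sd[comp] = rho_p, sd_p

        # --- bias parameters ---------------------------------------------
        if config.sample_bias and data.any_flagged:
            prop = st.bias + step_bias * rng.standard_normal(9)
            ll_obs_p = _ll_from(
                data, la_sys, lr_sys, u0, st.dev[0][oc, ot], st.dev[1][oc, ot], st.slope, prop
            )
            bs = config.bias_shift_prior_sd
            mm, ms = config.misclass_logit_prior

            def bias_prior(b):
                return float(
                    np.sum(norm_logpdf(b[0:6], 0.0, bs**2))
                    + np.sum(norm_logpdf(b[6:9], mm, ms**2))
                )

            dl = ll_obs_p.sum() - ll_obs.sum() + bias_prior(prop) - bias_prior(st.bias)
            if np.log(rng.random()) < dl:
                st.bias = prop
                ll_obs = ll_obs_p
                a = 1.0
            else:
                a = 0.0
            if adapting:
                step_bias = float(np.clip(step_bias * np.exp(eta * (a - mcmc.adapt_target_joint)), 1e-3, 2.0))

        # --- retain -------------------------------------------------------
        if it >= start_keep and (it - start_keep) % keep_every == 0 and kept < n_keep:
            out["theta"][kept] = st.theta
            out["slope"][kept] = st.slope
            out["ar_rho"][kept] = st.ar_rho
            out["ar_sd"][kept] = st.ar_sd
            out["dev"][kept] = st.dev
            out["world_mean"][kept] = st.world_mean
            out["level_sd"][kept, 0] = st.sd_country
            out["level_sd"][kept, 1] = st.sd_mid
            out["level_sd"][kept, 2] = st.sd_top
            out["bias"][kept] = st.bias
            kept += 1
    return out, kept


def _trajectories(theta, dev, slope, years):
    """Probability-scale trajectories from draw arrays.

    theta (D, C, 7); dev (D, 2, C, T); slope (D,) -> p_any, r, u each (D, C, T).
    """
    t = np.asarray(years, dtype=float)[None, None, :]
    asym_a = invlogit(theta[:, :, 0])[:, :, None]
    rate_a = np.exp(theta[:, :, 1])[:, :, None]
    mid_a = theta[:, :, 2][:, :, None]
    asym_r = invlogit(theta[:, :, 3])[:, :, None]
    rate_r = np.exp(theta[:, :, 4])[:, :, None]
    mid_r = theta[:, :, 5][:, :, None]
    la = logit(asym_a * invlogit(rate_a * (t - mid_a))) + dev[:, 0]
    lr = logit(asym_r * invlogit(rate_r * (t - mid_r))) + dev[:, 1]
    pa = invlogit(la)
    r = invlogit(lr)
    u = invlogit(theta[:, :, 6][:, :, None] + slope[:, None, None] * pa)
    return pa, r, u


def fit(
    observations,
    demography,
    meta,
    model_config: ModelConfig | None = None,
    mcmc_config: McmcConfig | None = None,
    marital_group: str = "married",
) -> PosteriorSamples:
    """Draw from the joint posterior for one marital group.

    Observations for the other marital group are ignored; countries come from
    the metadata table, so countries with no data are still estimated (their
    posterior is the hierarchy-induced prior).  The returned samples cover the
    full 1970-2030 grid; years beyond the last observation are filled by
    :func:`project`.
    """
    config = model_config or ModelConfig()
    mcmc = mcmc_config or McmcConfig()
    tree = build_hierarchy(meta, marital_group)
    obs = [o for o in observations if o.marital_group == marital_group]

    if config.fit_end_year is not None:
        fit_end = int(config.fit_end_year)
    elif obs:
        fit_end = int(min(GRID_END, int(np.ceil(max(o.ref_year for o in obs)))))
    else:
        fit_end = GRID_START + 10  # prior-only: minimal window, rest projected
    fit_end = max(fit_end, GRID_START + 1)
    years_fit = np.arange(GRID_START, fit_end + 1)
    Tfit = years_fit.size

    data = _ObsData(obs, tree.countries, years_fit, config)

    per_chain = (mcmc.n_iterations - mcmc.n_warmup) // mcmc.thinning
    if per_chain < 1:
        raise ValueError("no draws retained; increase n_iterations")
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chunks = []
    chain_ids = []
    for ch in range(mcmc.n_chains):
        rng = np.random.default_rng(seeds[ch])
        outc, kept = _run_chain(
            data, tree, config, mcmc, rng, Tfit,
            n_keep=per_chain, keep_every=mcmc.thinning, start_keep=mcmc.n_warmup,
        )
        chunks.append({k: v[:kept] for k, v in outc.items()})
        chain_ids.append(np.full(kept, ch))

    def cat(key):
        return np.concatenate([c[key] for c in chunks], axis=0)

    theta = cat("theta")
    dev = cat("dev").astype(np.float64)
    slope = cat("slope")
    pa, r, u = _trajectories(theta, dev, slope, years_fit)

    samples = PosteriorSamples(
        marital_group=marital_group,
        countries=tree.countries,
        years=years_fit,
        fit_end_year=fit_end,
        p_any=pa.astype(np.float32),
        r_modern=r.astype(np.float32),
        u_nonusers=u.astype(np.float32),
        theta=theta,
        slope=slope,
        ar_rho=cat("ar_rho"),
        ar_sd=cat("ar_sd"),
        dev_last=np.stack([dev[:, 0, :, -1], dev[:, 1, :, -1]], axis=-1),
        world_mean_draws=cat("world_mean"),
        level_sd_draws=cat("level_sd"),
        bias_draws=cat("bias"),
        chain_id=np.concatenate(chain_ids),
        seed=mcmc.seed,
        config_fingerprint=config.fingerprint(),
    )
    if fit_end < GRID_END:
        samples = project(samples, GRID_END)
    return samples


def project(samples: PosteriorSamples, horizon_end: int, seed: int | None = None) -> PosteriorSamples:
    """Extend trajectories beyond the data period by continuing the AR process.

    For each draw, the deviation processes are sampled forward from their last
    value using that draw's (rho, sd); the systematic curves are evaluated
    from their time-invariant parameters.
    """
    if horizon_end <= samples.fit_end_year:
        raise ValueError(
            f"projection horizon {horizon_end} not beyond last data year {samples.fit_end_year}"
        )
    if horizon_end > GRID_END:
        raise ValueError(f"horizon beyond grid end {GRID_END}")
    rng = np.random.default_rng((samples.seed + 986_527) if seed is None else seed)
    D = samples.n_draws
    C = len(samples.countries)
    new_years = np.arange(samples.fit_end_year + 1, horizon_end + 1)
    K = new_years.size

    dev = np.empty((D, 2, C, K))
    last = np.transpose(samples.dev_last, (0, 2, 1)).copy()  # (D, 2, C)
    for k in range(K):
        last = samples.ar_rho[:, :, None] * last + samples.ar_sd[:, :, None] * rng.standard_normal((D, 2, C))
        dev[:, :, :, k] = last

    pa, r, u = _trajectories(samples.theta, dev, samples.slope, new_years)
    keep_fit = samples.years <= samples.fit_end_year
    return replace(
        samples,
        years=np.concatenate([samples.years[keep_fit], new_years]),
        p_any=np.concatenate([samples.p_any[:, :, keep_fit], pa.astype(np.float32)], axis=2),
        r_modern=np.concatenate([samples.r_modern[:, :, keep_fit], r.astype(np.float32)], axis=2),
        u_nonusers=np.concatenate([samples.u_nonusers[:, :, keep_fit], u.astype(np.float32)], axis=2),
    )


# ---------------------------------------------------------------------------
# diagnostics


def split_rhat(chains: np.ndarray) -> float:
    """Split R-hat of a (n_chains, n_iter) array, floored at 1."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains")
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 1e-300:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(max(1.0, np.sqrt(var_hat / W)))


def effective_sample_size(chains: np.ndarray) -> float:
    """ESS via initial-positive-sequence autocorrelation (Geyer)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[None, :]
    m, n = chains.shape
    centred = chains - chains.mean(axis=1, keepdims=True)
    var = centred.var(axis=1).mean()
    if var <= 1e-300:
        return float(m * n)
    # mean autocorrelation over chains
    acov = np.zeros(n)
    for c in centred:
        f = np.fft.rfft(c, 2 * n)
        acf = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += acf
    acov /= m
    rho = acov / acov[0]
    # Geyer initial positive sequence on pair sums
    tau = 1.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k] if 2 * k < n else 0.0
        if pair < 0:
            break
        tau += 2 * pair
    return float(m * n / max(tau, 1e-12))


def diagnostics(samples: PosteriorSamples, threshold: float = 1.1) -> dict:
    """Split R-hat and ESS for monitored scalar summaries; flags R-hat > threshold."""
    if samples.n_chains < 2:
        raise ValueError("diagnostics require at least two chains")
    per_chain = [np.where(samples.chain_id == c)[0] for c in range(samples.n_chains)]
    nmin = min(len(ix) for ix in per_chain)

    def stack(x):
        return np.stack([x[ix[:nmin]] for ix in per_chain], axis=0)

    monitored = {"unmet_slope": samples.slope}
    for j, name in enumerate(PARAM_NAMES):
        monitored[f"world_mean[{name}]"] = samples.world_mean_draws[:, j]
    for i, c in enumerate(samples.countries):
        monitored[f"theta[{c},logit_asymptote_any]"] = samples.theta[:, i, 0]

    report = {"scalars": {}, "flagged": []}
    for name, x in monitored.items():
        ch = stack(x)
        r = split_rhat(ch)
        e = effective_sample_size(ch)
        report["scalars"][name] = {"rhat": r, "ess": e}
        if r > threshold:
            report["flagged"].append(name)
    return report
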