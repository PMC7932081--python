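"""Synthetic input generator: truth, surveys, demography, metadata.

Produces complete input bundles with the statistical structure the estimation
model assumes — hierarchically drawn country transition parameters, latent
trajectories with AR(1) deviations, declining marriage proportions, sparse and
uneven survey availability (zero-inflated counts), mixed source types with
different error scales, non-baseline-sample bias flags and modern/traditional
misclassification — so the whole pipeline can be exercised end-to-end with no
external data.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .core_io import (
    BASELINE_FLAGS,
    MISCLASS_FLAGS,
    CountryDemography,
    CountryMeta,
    SurveyObservation,
    write_demography,
    write_meta,
    write_observations,
)
from .hierarchy import N_PARAMS
from .observation_model import BiasParams, expected_observation
from .process_model import TransitionParams, ar1_deviations, latent_trajectory
from .util import invlogit, logit

__all__ = ["SimulationConfig", "TruthBundle", "simulate_truth", "simulate_surveys", "make_fixture"]

_SOURCE_DEFAULT_MIX = {"DHS": 0.42, "MICS": 0.18, "RHS": 0.06, "WFS": 0.04, "PMA": 0.05, "national": 0.1, "other": 0.15}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; every probability lives in [0, 1]."""

    n_regions: int = 2
    n_subregions_per_region: int = 2
    n_countries_per_subregion: int = 3
    year_start: int = 1970
    year_end: int = 2030
    # survey availability: zero-inflated Poisson per country (some countries get
    # none, some many, mirroring the observed sparsity pattern)
    surveys_mean: float = 4.0
    zero_inflation: float = 0.15
    survey_year_range: tuple = (1975, 2018)
    source_mix: dict = field(default_factory=lambda: dict(_SOURCE_DEFAULT_MIX))
    # scalar applies to every flag; a dict gives per-flag probabilities
    baseline_flag_prob: float | dict = 0.05
    misclass_flag_prob: float | dict = 0.05
    # hierarchical prior hyperparameters (unconstrained scales; see PARAM_NAMES)
    world_mean: tuple = (0.0, -2.0, 2000.0, 1.5, -2.0, 1995.0, -1.0)
    sd_region: tuple = (0.3, 0.15, 5.0, 0.3, 0.15, 5.0, 0.3)
    sd_subregion: tuple = (0.25, 0.1, 4.0, 0.25, 0.1, 4.0, 0.25)
    sd_country: tuple = (0.3, 0.15, 5.0, 0.3, 0.15, 5.0, 0.3)
    unmet_slope: float = 1.0
    ar_rho: tuple = (0.8, 0.8)
    ar_sd: tuple = (0.05, 0.05)
    # unmarried-specific structure
    frac_group0_subregions: float = 0.25
    group0_asymptote_shift: float = -2.5
    unmarried_asymptote_shift: float = -1.5
    # observation error (logit-scale sd) by source type
    obs_error_sd: dict = field(
        default_factory=lambda: {"DHS": 0.12, "MICS": 0.15, "RHS": 0.2, "WFS": 0.2, "PMA": 0.18, "national": 0.25, "other": 0.3}
    )
    # true bias/misclassification effects applied to flagged records
    bias_shift_any: float = -0.3
    bias_shift_unmet: float = -0.2
    misclass_realloc: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_regions * self.n_subregions_per_region * self.n_countries_per_subregion < 2:
            raise ValueError("need at least 2 countries")
        for name in ("zero_inflation", "baseline_flag_prob", "misclass_flag_prob", "frac_group0_subregions"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(not (0.0 <= x <= 1.0) for x in vals):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("world_mean", "sd_region", "sd_subregion", "sd_country", "ar_rho", "ar_sd", "survey_year_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def true_bias_params(self) -> BiasParams:
        return BiasParams(
            shift_any={f: self.bias_shift_any for f in BASELINE_FLAGS},
            shift_unmet={f: self.bias_shift_unmet for f in BASELINE_FLAGS},
            misclass_realloc={f: self.misclass_realloc for f in MISCLASS_FLAGS},
        )


@dataclass
class TruthBundle:
    config: SimulationConfig
    meta: dict  # country_code -> CountryMeta
    demography: dict  # country_code -> CountryDemography
    params: dict  # (country_code, marital_group) -> TransitionParams
    trajectories: dict  # (country_code, marital_group) -> list[Composition]
    years: np.ndarray


def _country_codes(n: int) -> list:
    letters = string.ascii_uppercase
    codes = []
    i = 0
    while len(codes) < n:
        a, rem = divmod(i, 26 * 26)
        b, c = divmod(rem, 26)
        codes.append("X" + letters[b] + letters[c] if a == 0 else letters[a - 1] + letters[b] + letters[c])
        i += 1
    return codes


def simulate_truth(config: SimulationConfig, seed: int | None = None) -> TruthBundle:
    """Draw a synthetic world from the model's own generative assumptions."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    years = np.arange(config.year_start, config.year_end + 1)

    n_countries = config.n_regions * config.n_subregions_per_region * config.n_countries_per_subregion
    codes = _country_codes(n_countries)
    meta: dict = {}
    k = 0
    subregion_group0: dict = {}
    for r in range(config.n_regions):
        for s in range(config.n_subregions_per_region):
            sub = f"subregion_{r}_{s}"
            subregion_group0[sub] = rng.random() < config.frac_group0_subregions
            for _ in range(config.n_countries_per_subregion):
                meta[codes[k]] = CountryMeta(
                    country_code=codes[k],
                    name=f"Country {codes[k]}",
                    subregion=sub,
                    region=f"region_{r}",
                    income_group=("low", "middle", "high")[k % 3],
                    development_group=("less", "more")[k % 2],
                    activity_group=0 if subregion_group0[sub] else 1,
                )
                k += 1

    # demography: growing cohort sizes, declining marriage proportions
    demography: dict = {}
    t_rel = years - years[0]
    for code in codes:
        base = float(np.exp(rng.normal(np.log(5e5), 0.8)))
        growth = rng.normal(0.012, 0.006)
        pop = base * np.exp(growth * t_rel)
        a0 = rng.normal(-1.0, 0.5)
        decline = rng.uniform(0.01, 0.05)
        prop_married = invlogit(a0 - decline * t_rel)
        demography[code] = CountryDemography(
            country_code=code,
            years=years,
            pop_15_19=pop,
            prop_married=prop_married,
            pop_15_49=pop * rng.uniform(5.0, 7.0),
        )

    wm = np.asarray(config.world_mean, dtype=float)
    sd_r = np.asarray(config.sd_region, dtype=float)
    sd_s = np.asarray(config.sd_subregion, dtype=float)
    sd_c = np.asarray(config.sd_country, dtype=float)

    params: dict = {}
    trajectories: dict = {}
    for group in ("married", "unmarried"):
        base = wm.copy()
        if group == "unmarried":
            base[0] += config.unmarried_asymptote_shift
        region_eff = {f"region_{r}": base + sd_r * rng.standard_normal(N_PARAMS) for r in range(config.n_regions)}
        sub_eff = {}
        for sub, g0 in subregion_group0.items():
            parent = region_eff[f"region_{int(sub.split('_')[1])}"]
            eff = parent + sd_s * rng.standard_normal(N_PARAMS)
            if group == "unmarried" and g0:
                eff = eff.copy()
                eff[0] += config.group0_asymptote_shift
            sub_eff[sub] = eff
        for code in codes:
            vec = sub_eff[meta[code].subregion] + sd_c * rng.standard_normal(N_PARAMS)
            p = TransitionParams(
                asymptote_any=float(invlogit(vec[0])),
                rate_any=float(np.exp(vec[1])),
                midpoint_any=float(vec[2]),
                asymptote_ratio=float(invlogit(vec[3])),
                rate_ratio=float(np.exp(vec[4])),
                midpoint_ratio=float(vec[5]),
                unmet_intercept=float(vec[6]),
                unmet_slope=config.unmet_slope,
                ar_rho=tuple(config.ar_rho),
                ar_sd=tuple(config.ar_sd),
            )
            params[(code, group)] = p
            d_any = ar1_deviations(years.size, p.ar_rho[0], p.ar_sd[0], rng)
            d_rat = ar1_deviations(years.size, p.ar_rho[1], p.ar_sd[1], rng)
            trajectories[(code, group)] = latent_trajectory(p, years, d_any, d_rat)

    return TruthBundle(
        config=config, meta=meta, demography=demography, params=params,
        trajectories=trajectories, years=years,
    )


def simulate_surveys(truth: TruthBundle, config: SimulationConfig | None = None, seed: int | None = None):
    """Draw survey observations around the latent truth.

    Counts per country are zero-inflated Poisson; observation noise is applied
    on the log-odds scale with source-type-specific sd; flagged records are
    biased/misclassified through the same expectation operator the likelihood
    uses, so generator and model agree.
    """
    config = config or truth.config
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    bias = config.true_bias_params()
    sources = sorted(config.source_mix)
    source_p = np.array([config.source_mix[s] for s in sources], dtype=float)
    source_p = source_p / source_p.sum()
    y_lo, y_hi = config.survey_year_range
    y_lo = max(y_lo, int(truth.years[0]))
    y_hi = min(y_hi, int(truth.years[-1]))

    observations = []
    for code in sorted(truth.meta):
        for group in ("married", "unmarried"):
            n = 0 if rng.random() < config.zero_inflation else int(rng.poisson(config.surveys_mean))
            if n == 0:
                continue
            yrs = np.sort(rng.integers(y_lo, y_hi + 1, size=n))
            for y in yrs:
                comp = truth.trajectories[(code, group)][int(y) - int(truth.years[0])]
                source = sources[int(rng.choice(len(sources), p=source_p))]

                def _fp(spec, f):
                    return spec.get(f, 0.0) if isinstance(spec, dict) else spec

                bflags = frozenset(
                    f for f in BASELINE_FLAGS if rng.random() < _fp(config.baseline_flag_prob, f)
                )
                mflags = frozenset(
                    f for f in MISCLASS_FLAGS if rng.random() < _fp(config.misclass_flag_prob, f)
                )
                exp = expected_observation(comp, bflags | mflags, bias)
                sd = config.obs_error_sd.get(source, 0.2)
                z = rng.standard_normal(3)
                p_any = float(invlogit(exp["logit_any"] + sd * z[0]))
                p_mod = float(invlogit(exp["logit_modern"] + sd * z[1]))
                p_unm = float(invlogit(exp["logit_unmet"] + sd * z[2]))
                p_mod = min(p_mod, p_any)
                p_trad = p_any - p_mod
                se = {
                    name: float(max(sd * p * (1.0 - p), 1e-6))
                    for name, p in (("se_any", p_any), ("se_modern", p_mod), ("se_unmet", p_unm))
                }
                observations.append(
                    SurveyObservation(
                        country_code=code,
                        marital_group=group,
                        # stamped at the grid instant so the recorded latent
                        # state and the reference time coincide exactly
                        ref_year=float(y),
                        p_any=p_any,
                        p_modern=p_mod,
                        p_traditional=p_trad,
                        p_unmet=p_unm,
                        source_type=source,
                        baseline_flags=bflags,
                        misclass_flags=mflags,
                        **se,
                    )
                )
    return observations


def make_fixture(config: SimulationConfig, seed: int, outdir) -> dict:
    """Write a loadable file bundle (observations/demography/meta + truth).

    Returns the paths written.  Same config and seed give byte-identical files.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config, seed)
    obs = simulate_surveys(truth, config, seed + 1)

    paths = {
        "observations": outdir / "observations.csv",
        "demography": outdir / "demography.csv",
        "meta": outdir / "meta.csv",
        "truth_trajectories": outdir / "truth_trajectories.csv",
        "truth_params": outdir / "truth_params.csv",
    }
    write_observations(obs, paths["observations"])
    write_demography(truth.demography, paths["demography"])
    write_meta(truth.meta, paths["meta"])

    rows = []
    for (code, group), comps in sorted(truth.trajectories.items()):
        for y, c in zip(truth.years, comps):
            rows.append(
                {
                    "country_code": code, "marital_group": group, "year": int(y),
                    "modern": repr(c.modern), "traditional": repr(c.traditional),
                    "unmet": repr(c.unmet), "no_need": repr(c.no_need),
                }
            )
    pd.DataFrame(rows).to_csv(paths["truth_trajectories"], index=False)

    prows = []
    for (code, group), p in sorted(truth.params.items()):
        d = {"country_code": code, "marital_group": group}
        d.update({k: repr(v) for k, v in asdict(p).items() if not isinstance(v, tuple)})
        d["ar_rho_any"], d["ar_rho_ratio"] = p.ar_rho
        d["ar_sd_any"], d["ar_sd_ratio"] = p.ar_sd
        prows.append(d)
    pd.DataFrame(prows).to_csv(paths["truth_params"], index=False)
    return paths
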