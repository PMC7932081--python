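"""Out-of-sample validation: holdout splits and predictive calibration."""

from __future__ import annotations

import numpy as np

from .inference import ModelConfig, PosteriorSamples, _ObsData
from .util import invlogit

__all__ = ["holdout_split", "coverage_report", "predictive_intervals"]


def holdout_split(observations, rule: str = "last_observation_per_country", year: float | None = None):
    """Deterministic train/test partition of the observation list.

    ``last_observation_per_country`` holds out each country-group's most recent
    observation, unless it is the only one (a country is never left dataless).
    ``observations_after_year`` holds out everything strictly after ``year``.
    """
    if rule == "last_observation_per_country":
        by_key: dict = {}
        for o in observations:
            by_key.setdefault((o.country_code, o.marital_group), []).append(o)
        train, test = [], []
        for key, obs in by_key.items():
            obs = sorted(obs, key=lambda o: o.ref_year)
            if len(obs) < 2:
                train.extend(obs)
            else:
                train.extend(obs[:-1])
                test.append(obs[-1])
        return train, test
    if rule == "observations_after_year":
        if year is None:
            raise ValueError("observations_after_year requires a year")
        train = [o for o in observations if o.ref_year <= year]
        test = [o for o in observations if o.ref_year > year]
        return train, test
    raise ValueError(f"unknown holdout rule {rule!r}")


def predictive_intervals(
    samples: PosteriorSamples,
    test_observations,
    model_config: ModelConfig | None = None,
    level: float = 0.95,
    seed: int = 0,
):
    """Posterior-predictive intervals for new observations.

    The predictive distribution includes observation error: for each retained
    draw the expected observed value and total variance are computed, a
    predictive value is simulated, and empirical quantiles are taken.  Returns
    a list of dicts per (observation, indicator present) with the realised
    value and interval on the proportion scale.
    """
    config = model_config or ModelConfig()
    years_fit = samples.years
    data = _ObsData(
        [o for o in test_observations if o.marital_group == samples.marital_group],
        samples.countries,
        years_fit,
        config,
    )
    if data.n_obs == 0:
        raise ValueError("empty test set")
    rng = np.random.default_rng(seed)
    D = samples.n_draws
    lo_q, hi_q = 50 * (1 - level), 100 - 50 * (1 - level)

    from .inference import _obs_loglik  # noqa: F401  (shared mean machinery below)
    from .util import logit

    results = []
    c, t = data.c_idx, data.t_idx
    pa = samples.p_any[:, c, t].astype(float)  # (D, N)
    r = samples.r_modern[:, c, t].astype(float)
    u = samples.u_nonusers[:, c, t].astype(float)
    bias = samples.bias_draws  # (D, 9)
    shifts_any = data.Fb @ bias[:, 0:3].T  # (N, D)
    shifts_unmet = data.Fb @ bias[:, 3:6].T
    realloc = invlogit(bias[:, 6:9])  # (D, 3)
    modern = pa * r
    trad = pa * (1 - r)
    gain = (np.outer(realloc[:, 0], data.Fm[:, 0]) + np.outer(realloc[:, 2], data.Fm[:, 2])) * trad
    loss = np.outer(realloc[:, 1], data.Fm[:, 1]) * modern
    mod_exp = np.clip(modern + gain - loss, 1e-12, 1 - 1e-12)
    mean = {
        0: logit(pa) + shifts_any.T,
        1: logit(mod_exp) + shifts_any.T,
    }
    pa_adj = invlogit(mean[0])
    u_adj = invlogit(logit(u) + shifts_unmet.T)
    mean[2] = logit(np.clip((1 - pa_adj) * u_adj, 1e-12, 1 - 1e-12))

    names = ("p_any", "p_modern", "p_unmet")
    for i in range(data.n_obs):
        for j in range(3):
            if not data.present[i, j]:
                continue
            draws = mean[j][:, i] + np.sqrt(data.var[i, j]) * rng.standard_normal(D)
            p_draws = invlogit(draws)
            results.append(
                {
                    "obs_index": i,
                    "country": samples.countries[c[i]],
                    "indicator": names[j],
                    "observed": float(invlogit(data.y[i, j])),
                    "lo": float(np.percentile(p_draws, lo_q)),
                    "hi": float(np.percentile(p_draws, hi_q)),
                    "median": float(np.median(p_draws)),
                }
            )
    return results


def coverage_report(test_observations, samples: PosteriorSamples, model_config=None, seed: int = 0):
    """Empirical 95% predictive coverage, median error and median absolute error.

    One entry per indicator plus an ``overall`` pool; errors are observed minus
    predictive median, on the proportion scale.
    """
    intervals = predictive_intervals(samples, test_observations, model_config, seed=seed)
    if not intervals:
        raise ValueError("empty test set")
    by_ind: dict = {}
    for rec in intervals:
        by_ind.setdefault(rec["indicator"], []).append(rec)
    report = {}
    pooled = []
    for ind, recs in by_ind.items():
        inside = [rec["lo"] <= rec["observed"] <= rec["hi"] for rec in recs]
        errors = [rec["observed"] - rec["median"] for rec in recs]
        pooled.extend(zip(inside, errors))
        report[ind] = {
            "n": len(recs),
            "coverage": float(np.mean(inside)),
            "median_error": float(np.median(errors)),
            "median_abs_error": float(np.median(np.abs(errors))),
        }
    inside, errors = zip(*pooled)
    report["overall"] = {
        "n": len(inside),
        "coverage": float(np.mean(inside)),
        "median_error": float(np.median(errors)),
        "median_abs_error": float(np.median(np.abs(errors))),
    }
    return report
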