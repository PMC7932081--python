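"""Transform posterior trajectories into reported indicators.

All combination and aggregation happens at the level of the MCMC draws:
all-women values are marital-weighted sums per draw, aggregate counts are
draw-wise sums over member countries, and aggregate proportions are ratios of
summed counts per draw.  Summaries are empirical medians and 2.5/97.5
percentiles, with a proportional rescaling of the modern/traditional medians
(only) so the reported method split sums to the reported any-method median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import EstimateRecord
from .inference import PosteriorSamples

__all__ = [
    "AggregateSpec",
    "IndicatorSamples",
    "as_indicator_samples",
    "combine_marital",
    "counts_from_proportions",
    "aggregate",
    "need_satisfied_modern",
    "summarize",
    "suppression_filter",
    "adolescent_share",
]

BASE_INDICATORS = ("use_any", "use_modern", "use_traditional", "unmet", "need", "no_need")
MIN_DRAWS = 100


@dataclass
class AggregateSpec:
    """Membership map for one grouping plus suppression thresholds."""

    grouping: str
    members: dict  # aggregate name -> list of country codes
    min_obs_for_reporting: int = 2
    min_need_for_ratio: float = 100_000.0

    def __post_init__(self) -> None:
        seen: dict = {}
        for name, codes in self.members.items():
            for c in codes:
                if c in seen:
                    raise ValueError(
                        f"country {c} appears in both {seen[c]!r} and {name!r} for grouping {self.grouping!r}"
                    )
                seen[c] = name


@dataclass
class IndicatorSamples:
    """Draw-level indicator arrays, (draws, countries, years)."""

    marital_group: str
    countries: list
    years: np.ndarray
    scale: str  # proportion | count
    data: dict = field(default_factory=dict)  # indicator -> array
    population: np.ndarray | None = None  # (C, T) group population for counts

    @property
    def n_draws(self) -> int:
        return next(iter(self.data.values())).shape[0]


def as_indicator_samples(samples: PosteriorSamples) -> IndicatorSamples:
    """Expand posterior trajectories into the reported indicator set."""
    comp = samples.composition()  # (D, C, T, 4): modern, traditional, unmet, no_need
    modern, trad, unmet, no_need = (comp[..., i] for i in range(4))
    any_use = modern + trad
    return IndicatorSamples(
        marital_group=samples.marital_group,
        countries=list(samples.countries),
        years=np.asarray(samples.years),
        scale="proportion",
        data={
            "use_any": any_use,
            "use_modern": modern,
            "use_traditional": trad,
            "unmet": unmet,
            "need": any_use + unmet,
            "no_need": no_need,
        },
    )


def _marriage_weights(countries, years, demography) -> np.ndarray:
    w = np.empty((len(countries), len(years)))
    for i, c in enumerate(countries):
        d = demography[c]
        for j, y in enumerate(years):
            _, w[i, j] = d.at(int(y))
    return w


def _populations(countries, years, demography) -> np.ndarray:
    pop = np.empty((len(countries), len(years)))
    for i, c in enumerate(countries):
        d = demography[c]
        for j, y in enumerate(years):
            pop[i, j], _ = d.at(int(y))
    return pop


def combine_marital(
    married: IndicatorSamples | PosteriorSamples,
    unmarried: IndicatorSamples | PosteriorSamples,
    demography,
) -> IndicatorSamples:
    """All-women indicator draws: ``w * married + (1 - w) * unmarried``.

    ``w`` is the country-year proportion married; summation happens per draw.
    """
    if isinstance(married, PosteriorSamples):
        married = as_indicator_samples(married)
    if isinstance(unmarried, PosteriorSamples):
        unmarried = as_indicator_samples(unmarried)
    if married.countries != unmarried.countries or not np.array_equal(married.years, unmarried.years):
        raise ValueError("married and unmarried samples are not on the same grid")
    shapes = {k: v.shape for k, v in married.data.items()}
    for k, v in unmarried.data.items():
        if shapes.get(k) != v.shape:
            raise ValueError(f"draw dimensions mismatch for indicator {k!r}")
    w = _marriage_weights(married.countries, married.years, demography)[None, :, :]
    data = {
        k: w * married.data[k] + (1.0 - w) * unmarried.data[k] for k in married.data
    }
    return IndicatorSamples(
        marital_group="all",
        countries=married.countries,
        years=married.years,
        scale=married.scale,
        data=data,
    )


def counts_from_proportions(samples: IndicatorSamples | PosteriorSamples, demography) -> IndicatorSamples:
    """Convert proportion draws to person counts using group populations.

    Married counts use ``w * pop_15_19``, unmarried ``(1 - w) * pop_15_19``,
    all women the full ``pop_15_19``.
    """
    if isinstance(samples, PosteriorSamples):
        samples = as_indicator_samples(samples)
    if samples.scale != "proportion":
        raise ValueError("input must be on the proportion scale")
    pop = _populations(samples.countries, samples.years, demography)
    w = _marriage_weights(samples.countries, samples.years, demography)
    if samples.marital_group == "married":
        group_pop = pop * w
    elif samples.marital_group == "unmarried":
        group_pop = pop * (1.0 - w)
    else:
        group_pop = pop
    data = {k: v * group_pop[None, :, :] for k, v in samples.data.items()}
    return IndicatorSamples(
        marital_group=samples.marital_group,
        countries=samples.countries,
        years=samples.years,
        scale="count",
        data=data,
        population=group_pop,
    )


def aggregate(count_samples: IndicatorSamples, spec: AggregateSpec) -> dict:
    """Draw-wise sums of member-country counts per aggregate.

    Returns ``{aggregate name: IndicatorSamples}`` where each output has a
    single pseudo-country.  Aggregate proportions, when wanted, are ratios of
    summed counts: use the carried population.
    """
    if count_samples.scale != "count":
        raise ValueError("aggregation is defined on count samples")
    index = {c: i for i, c in enumerate(count_samples.countries)}
    out = {}
    for name, codes in spec.members.items():
        missing = [c for c in codes if c not in index]
        if missing:
            raise ValueError(f"aggregate {name!r} references unknown countries {missing}")
        sel = [index[c] for c in codes]
        data = {k: v[:, sel, :].sum(axis=1, keepdims=True) for k, v in count_samples.data.items()}
        pop = (
            count_samples.population[sel, :].sum(axis=0, keepdims=True)
            if count_samples.population is not None
            else None
        )
        out[name] = IndicatorSamples(
            marital_group=count_samples.marital_group,
            countries=[name],
            years=count_samples.years,
            scale="count",
            data=data,
            population=pop,
        )
    return out


def proportions_from_counts(count_samples: IndicatorSamples) -> IndicatorSamples:
    """Count-weighted proportions: summed numerators over the group population."""
    if count_samples.population is None:
        raise ValueError("population not available on count samples")
    pop = count_samples.population[None, :, :]
    data = {k: np.where(pop > 0, v / np.where(pop > 0, pop, 1.0), 0.0) for k, v in count_samples.data.items()}
    return IndicatorSamples(
        marital_group=count_samples.marital_group,
        countries=count_samples.countries,
        years=count_samples.years,
        scale="proportion",
        data=data,
    )


def need_satisfied_modern(samples: IndicatorSamples) -> np.ndarray:
    """Per-draw SDG 3.7.1 ratio: modern use over total need.

    Draws with zero need yield NaN; a fully-NaN output signals suppression
    rather than raising.
    """
    modern = samples.data["use_modern"]
    need = samples.data["use_any"] + samples.data["unmet"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(need > 0, modern / np.where(need > 0, need, 1.0), np.nan)
    return ratio


def _percentiles(x, axis=0):
    med = np.nanmedian(x, axis=axis)
    lo = np.nanpercentile(x, 2.5, axis=axis)
    hi = np.nanpercentile(x, 97.5, axis=axis)
    return med, lo, hi


def summarize(samples: IndicatorSamples, years=None) -> list[EstimateRecord]:
    """Summarise indicator draws into EstimateRecords.

    Empirical medians and 95% intervals per location/indicator/year, the SDG
    ratio included; the modern/traditional medians are proportionally rescaled
    to sum to the any-method median (intervals are never adjusted).
    """
    if samples.n_draws < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} retained draws, got {samples.n_draws}")
    years = samples.years if years is None else np.asarray(years)
    year_ix = [int(np.where(samples.years == y)[0][0]) for y in years]

    stats = {k: _percentiles(v[:, :, year_ix]) for k, v in samples.data.items()}
    ratio = need_satisfied_modern(samples)[:, :, year_ix]
    with np.errstate(all="ignore"):
        stats["need_satisfied_modern"] = _percentiles(ratio)

    med_any = stats["use_any"][0]
    med_mod = stats["use_modern"][0].copy()
    med_trad = stats["use_traditional"][0].copy()
    denom = med_mod + med_trad
    scale = np.where(denom > 0, med_any / np.where(denom > 0, denom, 1.0), 1.0)
    med_mod *= scale
    med_trad *= scale

    records = []
    for i, loc in enumerate(samples.countries):
        for k, (med, lo, hi) in stats.items():
            for j, y in enumerate(years):
                m = med[i, j]
                if k == "use_modern":
                    m = med_mod[i, j]
                elif k == "use_traditional":
                    m = med_trad[i, j]
                if np.isnan(m):
                    continue  # suppressed ratio cell (all-NaN draws)
                # the identity adjustment must not break interval ordering
                m = float(np.clip(m, lo[i, j], hi[i, j]))
                records.append(
                    EstimateRecord(
                        location=loc,
                        marital_group=samples.marital_group,
                        indicator=k,
                        scale=samples.scale if k != "need_satisfied_modern" else "proportion",
                        year=int(y),
                        median=m,
                        ui_low=float(lo[i, j]),
                        ui_high=float(hi[i, j]),
                    )
                )
    return records


def suppression_filter(
    records,
    married_any_obs_counts: dict,
    spec: AggregateSpec,
    need_medians: dict | None = None,
) -> list[EstimateRecord]:
    """Apply the reporting suppression rules, returning new records.

    Country-level records are flagged when the country has fewer than
    ``spec.min_obs_for_reporting`` married any-method observations.  SDG-ratio
    records are flagged when the group's median count of women in need (from
    ``need_medians``: location -> persons) falls below ``spec.min_need_for_ratio``.
    Suppressed countries still contribute to aggregates upstream.
    """
    out = []
    for r in records:
        suppressed = r.suppressed
        if r.location in married_any_obs_counts:
            if married_any_obs_counts[r.location] < spec.min_obs_for_reporting:
                suppressed = True
        if (
            r.indicator == "need_satisfied_modern"
            and need_medians is not None
            and r.location in need_medians
            and need_medians[r.location] < spec.min_need_for_ratio
        ):
            suppressed = True
        out.append(
            EstimateRecord(
                location=r.location,
                marital_group=r.marital_group,
                indicator=r.indicator,
                scale=r.scale,
                year=r.year,
                median=r.median,
                ui_low=r.ui_low,
                ui_high=r.ui_high,
                suppressed=suppressed,
            )
        )
    return out


def adolescent_share(adolescent_counts: dict, all_age_counts: dict) -> dict:
    """Share (percent) of each indicator category accounted for by adolescents.

    Both arguments map indicator -> median count of women.  Cells with a zero
    or missing all-age denominator are returned as None (suppressed).
    """
    if not all_age_counts:
        raise ValueError(
            "all-age (15-49) category counts were not supplied; the adolescent "
            "share cannot be computed without them"
        )
    out = {}
    for k, num in adolescent_counts.items():
        denom = all_age_counts.get(k)
        out[k] = None if not denom else 100.0 * num / denom
    return out
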