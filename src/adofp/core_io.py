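"""Domain types, dataset validation and CSV readers/writers.

All proportions are stored internally on the [0, 1] scale.  Input files may
carry proportions in percent, signalled by a ``units=percent`` marker column or
by ``_pct`` column-name suffixes; see :func:`read_observations`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SurveyObservation",
    "CountryDemography",
    "CountryMeta",
    "EstimateRecord",
    "ValidationReport",
    "read_observations",
    "write_observations",
    "read_demography",
    "write_demography",
    "read_meta",
    "write_meta",
    "read_estimates",
    "write_estimates",
    "validate_dataset",
]

MARITAL_GROUPS = ("married", "unmarried")
SOURCE_TYPES = ("DHS", "MICS", "RHS", "WFS", "PMA", "national", "other")
BASELINE_FLAGS = ("age_truncated", "geographic_subset", "other_nonbaseline")
MISCLASS_FLAGS = ("modern_inflated", "traditional_inflated", "methods_combined")
INDICATORS = (
    "use_any",
    "use_modern",
    "use_traditional",
    "unmet",
    "need",
    "need_satisfied_modern",
    "no_need",
)

#: tolerance on the any = modern + traditional identity (published rounding)
METHOD_SUM_TOL = 5e-3

YEAR_MIN, YEAR_MAX = 1960.0, 2030.0
GRID_START, GRID_END = 1970, 2030


class ObservationError(ValueError):
    """Record-level validation failure while reading survey observations."""


@dataclass
class SurveyObservation:
    """One survey-based measurement for a country-year-marital group."""

    country_code: str
    marital_group: str
    ref_year: float
    p_any: float | None = None
    p_modern: float | None = None
    p_traditional: float | None = None
    p_unmet: float | None = None
    source_type: str = "other"
    se_any: float | None = None
    se_modern: float | None = None
    se_unmet: float | None = None
    baseline_flags: frozenset = frozenset()
    misclass_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.marital_group not in MARITAL_GROUPS:
            raise ObservationError(f"unknown marital_group {self.marital_group!r}")
        if self.source_type not in SOURCE_TYPES:
            raise ObservationError(f"unknown source_type {self.source_type!r}")
        if not (YEAR_MIN <= self.ref_year <= YEAR_MAX):
            raise ObservationError(f"ref_year {self.ref_year} outside [{YEAR_MIN}, {YEAR_MAX}]")
        self.baseline_flags = frozenset(self.baseline_flags)
        self.misclass_flags = frozenset(self.misclass_flags)
        if not self.baseline_flags <= set(BASELINE_FLAGS):
            raise ObservationError(f"unknown baseline flags {self.baseline_flags - set(BASELINE_FLAGS)}")
        if not self.misclass_flags <= set(MISCLASS_FLAGS):
            raise ObservationError(f"unknown misclass flags {self.misclass_flags - set(MISCLASS_FLAGS)}")
        for name in ("p_any", "p_modern", "p_traditional", "p_unmet"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ObservationError(f"{name}={v} outside [0, 1]")
        if (
            self.p_any is not None
            and self.p_modern is not None
            and self.p_traditional is not None
            and abs(self.p_modern + self.p_traditional - self.p_any) > METHOD_SUM_TOL
        ):
            raise ObservationError(
                f"method-sum identity violated: {self.p_modern} + {self.p_traditional} "
                f"!= {self.p_any} (tol {METHOD_SUM_TOL})"
            )


@dataclass
class CountryDemography:
    """Annual counts of women 15-19 and proportion married on the 1970-2030 grid."""

    country_code: str
    years: np.ndarray
    pop_15_19: np.ndarray
    prop_married: np.ndarray
    pop_15_49: np.ndarray | None = None
    interpolated: bool = False

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.pop_15_19 = np.asarray(self.pop_15_19, dtype=float)
        self.prop_married = np.asarray(self.prop_married, dtype=float)
        if not (self.years.size == self.pop_15_19.size == self.prop_married.size):
            raise ValueError("demography series lengths differ")
        if np.any(np.diff(self.years) != 1):
            raise ValueError(f"{self.country_code}: year grid not contiguous")
        if np.any((self.prop_married < 0) | (self.prop_married > 1)):
            raise ValueError(f"{self.country_code}: prop_married outside [0, 1]")
        if np.any(self.pop_15_19 < 0):
            raise ValueError(f"{self.country_code}: negative population")

    def at(self, year: int) -> tuple[float, float]:
        i = int(year) - int(self.years[0])
        if not (0 <= i < self.years.size):
            raise KeyError(f"{self.country_code}: year {year} outside demography grid")
        return float(self.pop_15_19[i]), float(self.prop_married[i])


@dataclass(frozen=True)
class CountryMeta:
    country_code: str
    name: str
    subregion: str
    region: str
    income_group: str = "unknown"
    development_group: str = "unknown"
    activity_group: int | str = "unknown"  # {0, 1, "unknown"}


@dataclass
class EstimateRecord:
    """One summarised posterior quantity (median + 95% interval)."""

    location: str
    marital_group: str  # married | unmarried | all
    indicator: str
    scale: str  # proportion | count
    year: int
    median: float
    ui_low: float
    ui_high: float
    suppressed: bool = False

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.scale not in ("proportion", "count"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not (self.ui_low <= self.median + 1e-12 and self.median <= self.ui_high + 1e-12):
            raise ValueError(
                f"interval ordering violated: {self.ui_low} <= {self.median} <= {self.ui_high}"
            )
        if self.scale == "proportion":
            for v in (self.median, self.ui_low, self.ui_high):
                if not (-1e-12 <= v <= 1.0 + 1e-12):
                    raise ValueError(f"proportion-scale value {v} outside [0, 1]")


@dataclass
class ValidationReport:
    orphan_countries: list = field(default_factory=list)
    out_of_grid_observations: list = field(default_factory=list)
    obs_counts: dict = field(default_factory=dict)  # (country, marital_group) -> int

    @property
    def issues(self) -> list:
        return list(self.orphan_countries) + list(self.out_of_grid_observations)

    def to_json(self) -> str:
        return json.dumps(
            {
                "orphan_countries": self.orphan_countries,
                "out_of_grid_observations": self.out_of_grid_observations,
                "obs_counts": {f"{c}|{g}": n for (c, g), n in sorted(self.obs_counts.items())},
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# observations


_OBS_MANDATORY = ("country_code", "marital_group", "ref_year")
_OBS_PROPORTIONS = ("p_any", "p_modern", "p_traditional", "p_unmet")
_OBS_KNOWN = set(_OBS_MANDATORY) | set(_OBS_PROPORTIONS) | {
    "source_type",
    "se_any",
    "se_modern",
    "se_unmet",
    "baseline_flags",
    "misclass_flags",
    "units",
}


def _units_factor(df: pd.DataFrame) -> float:
    """1.0 for files on the [0,1] scale, 0.01 when declared percent."""
    if "units" in df.columns and len(df) > 0:
        units = set(str(u).strip().lower() for u in df["units"].dropna().unique())
        if units <= {"percent", "pct", "%"} and units:
            return 0.01
        if units <= {"proportion", "prop"} and units:
            return 1.0
        if units:
            raise ValueError(f"unrecognised units declaration {units}")
    return 1.0


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or (isinstance(v, str) and not v.strip()):
        return None
    return float(v)


def _parse_flags(v) -> frozenset:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return frozenset()
    s = str(v).strip()
    if not s:
        return frozenset()
    return frozenset(part.strip() for part in s.replace(";", "|").split("|") if part.strip())


def read_observations(path) -> list[SurveyObservation]:
    """Read the survey-observation table from a CSV file.

    Mandatory columns: ``country_code``, ``marital_group``, ``ref_year``.
    Proportions are taken from ``p_any``/``p_modern``/``p_traditional``/
    ``p_unmet`` and interpreted on the percent scale when a ``units`` column
    declares ``percent``.  Unknown columns are ignored with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in _OBS_MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in _OBS_KNOWN]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {', '.join(unknown)}", stacklevel=2)
    factor = _units_factor(df)

    records = []
    for i, row in df.iterrows():
        props = {}
        for name in _OBS_PROPORTIONS:
            raw = _opt_float(row.get(name))
            if raw is not None and factor == 0.01 and not (0.0 <= raw <= 100.0):
                raise ObservationError(f"row {i}: {name}={raw} outside [0, 100] percent")
            props[name] = None if raw is None else raw * factor
        ses = {
            name: (None if (v := _opt_float(row.get(name))) is None else v * factor)
            for name in ("se_any", "se_modern", "se_unmet")
        }
        try:
            records.append(
                SurveyObservation(
                    country_code=str(row["country_code"]).strip(),
                    marital_group=str(row["marital_group"]).strip(),
                    ref_year=float(row["ref_year"]),
                    source_type=str(row.get("source_type", "other") or "other").strip(),
                    baseline_flags=_parse_flags(row.get("baseline_flags")),
                    misclass_flags=_parse_flags(row.get("misclass_flags")),
                    **props,
                    **ses,
                )
            )
        except ObservationError as exc:
            raise ObservationError(f"row {i}: {exc}") from exc
    return records


def write_observations(records, path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "country_code": r.country_code,
                "marital_group": r.marital_group,
                "ref_year": r.ref_year,
                "p_any": r.p_any,
                "p_modern": r.p_modern,
                "p_traditional": r.p_traditional,
                "p_unmet": r.p_unmet,
                "source_type": r.source_type,
                "se_any": r.se_any,
                "se_modern": r.se_modern,
                "se_unmet": r.se_unmet,
                "baseline_flags": "|".join(sorted(r.baseline_flags)),
                "misclass_flags": "|".join(sorted(r.misclass_flags)),
                "units": "proportion",
            }
        )
    columns = [
        "country_code", "marital_group", "ref_year", "p_any", "p_modern",
        "p_traditional", "p_unmet", "source_type", "se_any", "se_modern",
        "se_unmet", "baseline_flags", "misclass_flags", "units",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# demography


def read_demography(path, interpolate: bool = True) -> dict[str, CountryDemography]:
    """Read the long-format demography table (country, year, pop_15_19, prop_married).

    Gaps in a country's year series are filled by linear interpolation when
    ``interpolate`` is true (the result is flagged); otherwise gaps raise.
    Single-year series are extended as constants over their own span (trivially
    contiguous).  Series are kept on their native span, clipped to 1970-2030.
    """
    df = pd.read_csv(path)
    for c in ("country_code", "year", "pop_15_19", "prop_married"):
        if c not in df.columns:
            raise ValueError(f"missing mandatory column(s): {c}")
    out: dict[str, CountryDemography] = {}
    for code, grp in df.groupby("country_code", sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if np.any((grp["prop_married"] < 0) | (grp["prop_married"] > 1)):
            raise ValueError(f"{code}: prop_married outside [0, 1]")
        if years.size == 1:
            # degenerate single-year series: constant extension over the grid
            full = np.arange(GRID_START, GRID_END + 1)
            flagged = True
        else:
            full = np.arange(years[0], years[-1] + 1)
            flagged = False
            if years.size != full.size:
                if not interpolate:
                    raise ValueError(f"{code}: non-contiguous years and interpolation disabled")
                flagged = True
        pop = np.interp(full, years, grp["pop_15_19"].to_numpy(dtype=float))
        pm = np.interp(full, years, grp["prop_married"].to_numpy(dtype=float))
        p49 = None
        if "pop_15_49" in grp.columns and grp["pop_15_49"].notna().all():
            p49 = np.interp(full, years, grp["pop_15_49"].to_numpy(dtype=float))
        out[str(code)] = CountryDemography(
            country_code=str(code),
            years=full,
            pop_15_19=pop,
            prop_married=pm,
            pop_15_49=p49,
            interpolated=flagged,
        )
    return out


def write_demography(demog: dict[str, CountryDemography], path) -> None:
    frames = []
    for code in sorted(demog):
        d = demog[code]
        frame = {
            "country_code": code,
            "year": d.years,
            "pop_15_19": d.pop_15_19,
            "prop_married": d.prop_married,
        }
        if d.pop_15_49 is not None:
            frame["pop_15_49"] = d.pop_15_49
        frames.append(pd.DataFrame(frame))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# metadata


def read_meta(path) -> dict[str, CountryMeta]:
    df = pd.read_csv(path)
    for c in ("country_code", "subregion", "region"):
        if c not in df.columns:
            raise ValueError(f"missing mandatory column(s): {c}")
    out: dict[str, CountryMeta] = {}
    for _, row in df.iterrows():
        code = str(row["country_code"]).strip()
        if code in out:
            raise ValueError(f"country {code} listed more than once in metadata")
        ag = row.get("activity_group", "unknown")
        try:
            ag = int(ag)
        except (TypeError, ValueError):
            ag = "unknown"
        out[code] = CountryMeta(
            country_code=code,
            name=str(row.get("name", code)),
            subregion=str(row["subregion"]),
            region=str(row["region"]),
            income_group=str(row.get("income_group", "unknown")),
            development_group=str(row.get("development_group", "unknown")),
            activity_group=ag,
        )
    return out


def write_meta(meta: dict[str, CountryMeta], path) -> None:
    rows = [
        {
            "country_code": m.country_code,
            "name": m.name,
            "subregion": m.subregion,
            "region": m.region,
            "income_group": m.income_group,
            "development_group": m.development_group,
            "activity_group": m.activity_group,
        }
        for m in (meta[c] for c in sorted(meta))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# estimates


def write_estimates(records, path) -> None:
    rows = [
        {
            "location": r.location,
            "marital_group": r.marital_group,
            "indicator": r.indicator,
            "scale": r.scale,
            "year": r.year,
            "median": repr(r.median),
            "ui_low": repr(r.ui_low),
            "ui_high": repr(r.ui_high),
            "suppressed": r.suppressed,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_estimates(path) -> list[EstimateRecord]:
    df = pd.read_csv(path)
    return [
        EstimateRecord(
            location=str(row["location"]),
            marital_group=str(row["marital_group"]),
            indicator=str(row["indicator"]),
            scale=str(row["scale"]),
            year=int(row["year"]),
            median=float(row["median"]),
            ui_low=float(row["ui_low"]),
            ui_high=float(row["ui_high"]),
            suppressed=bool(row["suppressed"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# cross-dataset validation


def validate_dataset(observations, demography, meta) -> ValidationReport:
    """Report-only consistency check across the three input tables.

    Lists observation/demography country codes absent from the metadata,
    observations falling outside the demography year grid, and per-country
    observation counts by marital group (consumed by the suppression filter).
    """
    report = ValidationReport()
    known = set(meta)
    seen_orphans = set()
    for obs in observations:
        key = (obs.country_code, obs.marital_group)
        report.obs_counts[key] = report.obs_counts.get(key, 0) + 1
        if obs.country_code not in known and obs.country_code not in seen_orphans:
            seen_orphans.add(obs.country_code)
            report.orphan_countries.append(obs.country_code)
        d = demography.get(obs.country_code)
        if d is not None and not (d.years[0] <= obs.ref_year <= d.years[-1] + 1):
            report.out_of_grid_observations.append(
                f"{obs.country_code}/{obs.marital_group}@{obs.ref_year}"
            )
    for code in demography:
        if code not in known and code not in seen_orphans:
            seen_orphans.add(code)
            report.orphan_countries.append(code)
    return report
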