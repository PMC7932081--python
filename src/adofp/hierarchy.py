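"""Hierarchical prior structure for borrowing of strength across countries.

Married women: world -> region -> subregion -> country.
Unmarried women: world -> sexual-activity group -> subregion -> country
(subregions keep their geographic identity inside the two activity groups).

All shrinkage is normal on unconstrained scales: log-odds for asymptotes,
log for rates, identity for midpoints and the unmet-need intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import norm_logpdf

__all__ = [
    "PARAM_NAMES",
    "HierarchyTree",
    "build_hierarchy",
    "assign_activity_group",
    "prior_logdensity",
]

#: unconstrained-scale country parameter vector layout
PARAM_NAMES = (
    "logit_asymptote_any",
    "log_rate_any",
    "midpoint_any",
    "logit_asymptote_ratio",
    "log_rate_ratio",
    "midpoint_ratio",
    "unmet_intercept",
)
N_PARAMS = len(PARAM_NAMES)

ACTIVITY_THRESHOLD_PCT = 2.0  # group 0 iff sexual activity in past 28 days <= 2%


@dataclass
class HierarchyTree:
    """Parent maps from countries up to the root.

    ``countries`` is the ordered leaf list; ``country_parent`` maps country ->
    level-2 node index; ``mid_parent`` maps level-2 node -> level-1 node index;
    level-1 nodes hang off the world root.  For married women level 2 is the
    subregion and level 1 the region; for unmarried women level 2 is the
    subregion and level 1 the activity group.
    """

    marital_group: str
    countries: list
    mid_nodes: list
    top_nodes: list
    country_parent: np.ndarray  # (C,) index into mid_nodes
    mid_parent: np.ndarray  # (M,) index into top_nodes
    # per-level prior sds for each parameter (filled from model config)
    sd_country: np.ndarray = field(default_factory=lambda: np.ones(N_PARAMS))
    sd_mid: np.ndarray = field(default_factory=lambda: np.ones(N_PARAMS))
    sd_top: np.ndarray = field(default_factory=lambda: np.ones(N_PARAMS))
    world_mean: np.ndarray = field(default_factory=lambda: np.zeros(N_PARAMS))

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    @property
    def depth(self) -> int:
        return 4  # world, top, mid, country

    def parent_chain(self, country_code: str) -> list:
        i = self.countries.index(country_code)
        m = int(self.country_parent[i])
        t = int(self.mid_parent[m])
        return [self.mid_nodes[m], self.top_nodes[t], "world"]


def assign_activity_group(pct_active_28d, threshold: float = ACTIVITY_THRESHOLD_PCT, meta_value=None):
    """Classify a country into sexual-activity group 0 (low) or 1.

    Group 0 when the share of unmarried women reporting sexual activity in the
    past 28 days is not more than ``threshold`` percent (boundary inclusive).
    A missing measurement falls back to the externally resolved metadata value;
    missing both is an error — the group is never guessed.
    """
    if pct_active_28d is None or (isinstance(pct_active_28d, float) and np.isnan(pct_active_28d)):
        if meta_value in (0, 1):
            return int(meta_value)
        raise ValueError("activity group unresolved: no measurement and no metadata value")
    if not (0.0 <= pct_active_28d <= 100.0):
        raise ValueError(f"pct_active_28d={pct_active_28d} outside [0, 100]")
    return 0 if pct_active_28d <= threshold else 1


def build_hierarchy(meta: dict, marital_group: str) -> HierarchyTree:
    """Construct the shrinkage tree for one marital group from country metadata."""
    if marital_group not in ("married", "unmarried"):
        raise ValueError(f"unknown marital group {marital_group!r}")
    countries = sorted(meta)
    if len(set(countries)) != len(countries):
        raise ValueError("duplicate country codes in metadata")

    subregions = sorted({meta[c].subregion for c in countries})
    for c in countries:
        if not meta[c].subregion or meta[c].subregion == "unknown":
            raise ValueError(f"country {c} has unknown subregion")

    if marital_group == "married":
        top_nodes = sorted({meta[c].region for c in countries})
        sub_top = {}
        for c in countries:
            m = meta[c]
            if m.subregion in sub_top and sub_top[m.subregion] != m.region:
                raise ValueError(f"subregion {m.subregion} maps to multiple regions")
            sub_top[m.subregion] = m.region
    else:
        # subregions cluster into the two activity groups; a subregion's group is
        # the group of its member countries (must agree)
        top_nodes = ["activity_group_0", "activity_group_1"]
        sub_top = {}
        for c in countries:
            m = meta[c]
            g = m.activity_group
            if g not in (0, 1):
                raise ValueError(f"country {c} has unresolved activity group {g!r}")
            node = f"activity_group_{g}"
            if m.subregion in sub_top and sub_top[m.subregion] != node:
                raise ValueError(f"subregion {m.subregion} spans both activity groups")
            sub_top[m.subregion] = node

    mid_index = {s: i for i, s in enumerate(subregions)}
    top_index = {t: i for i, t in enumerate(top_nodes)}
    country_parent = np.array([mid_index[meta[c].subregion] for c in countries], dtype=int)
    mid_parent = np.array([top_index[sub_top[s]] for s in subregions], dtype=int)
    return HierarchyTree(
        marital_group=marital_group,
        countries=countries,
        mid_nodes=subregions,
        top_nodes=top_nodes,
        country_parent=country_parent,
        mid_parent=mid_parent,
    )


def _halfnormal_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        return -np.inf
    return float(np.sum(0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2))


def prior_logdensity(
    country_params: np.ndarray,
    tree: HierarchyTree,
    mid_means: np.ndarray | None = None,
    top_means: np.ndarray | None = None,
    world_mean: np.ndarray | None = None,
    sd_hyperscale: float | None = None,
    world_prior_sd: np.ndarray | None = None,
) -> float:
    """Joint log-density of the hierarchical shrinkage prior.

    ``country_params`` is (C, 7) on unconstrained scales.  Node means default
    to collapsing onto the tree's stored means (useful for degenerate trees and
    unit tests); when ``sd_hyperscale`` is given, half-normal hyperprior terms
    on the three level sds are included, and when ``world_prior_sd`` is given a
    normal root term on the world mean is added.
    """
    country_params = np.asarray(country_params, dtype=float)
    if country_params.shape != (tree.n_countries, N_PARAMS):
        raise ValueError("country_params has wrong shape")
    world_mean = tree.world_mean if world_mean is None else np.asarray(world_mean, dtype=float)
    if top_means is None:
        top_means = np.tile(world_mean, (len(tree.top_nodes), 1))
    if mid_means is None:
        mid_means = top_means[tree.mid_parent]

    total = float(
        np.sum(norm_logpdf(country_params, mid_means[tree.country_parent], tree.sd_country**2))
    )
    total += float(np.sum(norm_logpdf(mid_means, top_means[tree.mid_parent], tree.sd_mid**2)))
    total += float(np.sum(norm_logpdf(top_means, world_mean, tree.sd_top**2)))
    if world_prior_sd is not None:
        total += float(np.sum(norm_logpdf(world_mean, tree.world_mean, np.asarray(world_prior_sd) ** 2)))
    if sd_hyperscale is not None:
        for sds in (tree.sd_country, tree.sd_mid, tree.sd_top):
            total += _halfnormal_logpdf(sds, sd_hyperscale)
    return total
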