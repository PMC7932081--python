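"""Compositional displays: ternary coordinates, balance colours, fan plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["ternary_coordinates", "ternary_color", "trajectory_plot", "TERNARY_PRIMARIES"]

#: default primaries: green (use), pink (unmet need), blue (no need), sRGB
TERNARY_PRIMARIES = (
    (0.0, 0.6, 0.2),
    (0.95, 0.4, 0.6),
    (0.15, 0.35, 0.85),
)

#: reference-triangle vertices for the three components (unit equilateral)
_VERTICES = np.array([[0.5, np.sqrt(3) / 2], [0.0, 0.0], [1.0, 0.0]])

_SUM_TOL = 0.01


def _check_composition3(composition3) -> np.ndarray:
    c = np.asarray(composition3, dtype=float)
    if c.shape != (3,):
        raise ValueError("composition must have exactly three components")
    if np.any(c < 0):
        raise ValueError("composition components must be non-negative")
    if abs(c.sum() - 100.0) > _SUM_TOL:
        raise ValueError(f"components must sum to 100 (got {c.sum()})")
    return c / c.sum()


def ternary_coordinates(composition3) -> tuple:
    """Barycentric map of a three-part composition (percent) into the plane.

    Vertices correspond to pure components; the (33.33, 33.33, 33.33)
    composition maps to the centroid.
    """
    w = _check_composition3(composition3)
    xy = w @ _VERTICES
    return float(xy[0]), float(xy[1])


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _linear_to_srgb(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)


def ternary_color(composition3, primaries=TERNARY_PRIMARIES) -> tuple:
    """Balance colour: convex blend of the three primaries.

    Weights are the components divided by 100; mixing happens in linear RGB
    and the result is gamma-encoded back to sRGB.  Pure components return
    their primary exactly.
    """
    w = _check_composition3(composition3)
    prim = np.asarray(primaries, dtype=float)
    if prim.shape != (3, 3):
        raise ValueError("need three RGB primaries")
    pure = np.where(w == 1.0)[0]
    if pure.size == 1 and w.sum() == 1.0:
        return tuple(float(v) for v in prim[pure[0]])
    mixed = w @ _srgb_to_linear(prim)
    out = np.clip(_linear_to_srgb(mixed), 0.0, 1.0)
    return tuple(float(v) for v in out)


_SOURCE_COLORS = {
    "DHS": "red",
    "MICS": "green",
    "RHS": "green",
    "WFS": "green",
    "PMA": "green",
    "national": "orange",
    "other": "green",
}


def trajectory_plot(records, path, observations=None, ribbon80=None, title=None):
    """Median line, dashed 80% bounds and 95% ribbon for one indicator series.

    ``records`` is a list of EstimateRecord for a single location/indicator/
    marital group.  ``ribbon80`` optionally maps year -> (lo, hi); when absent
    the dashed lines are omitted (with a notice on stderr).  Survey
    observations are overlaid as points coloured by source type.
    """
    if not records:
        raise ValueError("no records to plot")
    records = sorted(records, key=lambda r: r.year)
    years = [r.year for r in records]
    med = [r.median for r in records]
    lo = [r.ui_low for r in records]
    hi = [r.ui_high for r in records]

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.fill_between(years, lo, hi, color="0.8", label="95% interval")
    if ribbon80 is not None:
        lo80 = [ribbon80[y][0] for y in years]
        hi80 = [ribbon80[y][1] for y in years]
        ax.plot(years, lo80, "--", color="0.3")
        ax.plot(years, hi80, "--", color="0.3", label="80% interval")
    else:
        import sys

        print("trajectory_plot: 80% bounds not provided; dashed lines omitted", file=sys.stderr)
    ax.plot(years, med, "-", color="black", label="median")

    if observations:
        attr = {
            "use_any": "p_any",
            "use_modern": "p_modern",
            "use_traditional": "p_traditional",
            "unmet": "p_unmet",
        }.get(records[0].indicator)
        for o in observations:
            v = getattr(o, attr, None) if attr else None
            if v is not None:
                ax.plot(
                    o.ref_year, v, "o",
                    color=_SOURCE_COLORS.get(o.source_type, "green"), markersize=5,
                )
    ax.set_xlabel("year")
    ax.set_ylabel(records[0].indicator)
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
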