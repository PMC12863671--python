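"""Display-layer utilities: interpolating splines, tables, fine-grid export.

The bootstrap median and percentile series live on the 5-year support ages;
for plotting they are carried to a fine age grid by a strictly interpolating
natural cubic spline (zero second derivative at the boundary knots, no
internal knots beyond the support points, no smoothing).  The band bounds
are interpolated independently, so at the knots they equal the bootstrap
percentiles exactly.  Rendering follows the conventional incidence-table
layout: one row per 5-year group (top group open-ended), per-1,000
person-year units, three decimals rounded half-up.
"""

from __future__ import annotations

import decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = ["round_half_up", "format3", "interpolate_series", "fine_grid_export",
           "render_incidence_table", "percentage_share", "plot_incidence"]


def round_half_up(x: float, decimals: int = 3) -> float:
    """Decimal round-half-up (0.0005 -> 0.001), unlike banker's rounding."""
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def format3(x: float) -> str:
    """Three-decimal half-up string; NaN renders as the explicit token 'NA'."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{round_half_up(x, 3):.3f}"


def interpolate_series(support_ages, values, query_ages) -> np.ndarray:
    """Natural cubic spline through (support_ages, values) at query_ages.

    Strictly interpolating: at every support age the returned value equals
    the input exactly.  Queries outside the support range raise (the series
    is a display interpolant, not an extrapolation model).
    """
    x = np.asarray(support_ages, dtype=float)
    y = np.asarray(values, dtype=float)
    q = np.atleast_1d(np.asarray(query_ages, dtype=float))
    if len(x) < 3:
        raise ValueError("need >= 3 support points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("support ages must be strictly increasing")
    if q.min() < x[0] - 1e-12 or q.max() > x[-1] + 1e-12:
        raise ValueError(
            f"query ages outside support range [{x[0]}, {x[-1]}]; "
            "extrapolation is not supported")
    return CubicSpline(x, y, bc_type="natural")(q)


def fine_grid_export(summary: pd.DataFrame, step: float = 0.1) -> pd.DataFrame:
    """Interpolate median/lo95/hi95 per scenario x sex onto a fine age grid.

    Input is a :func:`previnc.bootstrap_engine.summarize` table; output is
    long format: scenario_factor, sex, age, series, value_per_1000py.
    """
    rows = []
    for (factor, sex), sub in summary.groupby(["scenario_factor", "sex"], sort=False):
        sub = sub.sort_values("age")
        ages = sub["age"].to_numpy(dtype=float)
        q = np.arange(ages[0], ages[-1] + step / 2, step)
        for series in ("median", "lo95", "hi95"):
            vals = interpolate_series(ages, sub[series].to_numpy(dtype=float), q)
            rows.extend(
                {"scenario_factor": factor, "sex": sex, "age": a,
                 "series": series, "value_per_1000py": v}
                for a, v in zip(q, vals))
    return pd.DataFrame(rows)


def render_incidence_table(summary: pd.DataFrame,
                           scenario_factor: float = 1.0) -> pd.DataFrame:
    """Wide incidence table: one row per age group, median and CI per sex.

    Values are taken from the per-1,000-py summary and rendered as
    three-decimal half-up strings with '[lo; hi]' interval columns; missing
    points appear as 'NA'.
    """
    sub = summary[summary["scenario_factor"] == scenario_factor]
    if sub.empty:
        raise ValueError(f"no rows for scenario factor {scenario_factor}")
    out = {}
    for sex, g in sub.groupby("sex", sort=False):
        g = g.sort_values("age_lo")
        out[f"{sex}_median"] = [format3(v) for v in g["median"]]
        out[f"{sex}_ci"] = [
            "NA" if not (np.isfinite(l) and np.isfinite(h))
            else f"[{format3(l)}; {format3(h)}]"
            for l, h in zip(g["lo95"], g["hi95"])]
        index = g["age_group"].tolist()
    return pd.DataFrame(out, index=pd.Index(index, name="age_group"))


def percentage_share(part: float, total: float, decimals: int = 1) -> float:
    """Percentage share 100*part/total, rounded half-up (e.g. case shares)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * part / total, decimals)


def plot_incidence(fine: pd.DataFrame, path=None, scenario_factor: float = 1.0):
    """Median curves with interval bands per sex (thin layer over the export)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = {"male": "tab:blue", "female": "tab:red"}
    sub = fine[fine["scenario_factor"] == scenario_factor]
    for sex, g in sub.groupby("sex", sort=False):
        piv = g.pivot(index="age", columns="series", values="value_per_1000py")
        c = colors.get(sex, None)
        ax.plot(piv.index, piv["median"], color=c, label=sex)
        ax.fill_between(piv.index, piv["lo95"], piv["hi95"], color=c, alpha=0.2)
        ax.plot(piv.index, piv["lo95"], ls="--", lw=0.8, color=c)
        ax.plot(piv.index, piv["hi95"], ls="--", lw=0.8, color=c)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("incidence per 1,000 person-years")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
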