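"""Logit-scale prevalence surface: natural-spline age basis, time and sex terms.

The aggregated prevalence table (cases / population per calendar year x sex x
5-year age group) is modelled on the logit scale, separately per sex:

    logit p(t, a) = s(a) + (t - t_c) * s_t(a)

where ``s`` is a natural cubic spline in age with knots at the observed group
midpoints, and ``s_t`` is either a constant (year enters linearly) or a second
spline of the same basis (year x spline interaction, the default), so the
age profile may tilt over time.  Fitting is weighted least squares on the
empirical logits with binomial working weights ``N p (1-p)``; with large
denominators this coincides with the binomial MLE to high order and gives a
closed-form coefficient covariance, hence a standard error for the linear
predictor at any (t, a).

The Lexis-direction derivative D = (d/dt + d/da) p at the anchor year is
obtained from the fitted surface either by a centred finite difference along
the cohort diagonal (default, half-step 4 years so the stencil touches the
first and last prevalence years) or analytically from the basis derivatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "natural_spline_basis",
    "natural_spline_basis_deriv",
    "age_group_midpoints",
    "PrevalenceFit",
    "fit_prevalence",
    "predict_prevalence",
    "linear_predictor",
    "lexis_derivative",
]

OPEN_ENDED_HALF_WIDTH = 2.5  # midpoint of an open-ended "90+" group = 90 + 2.5


def age_group_midpoints(age_lo, age_hi) -> np.ndarray:
    """Midpoint of closed-open [lo, hi+1) groups; open-ended groups get lo+2.5."""
    lo = np.asarray(age_lo, dtype=float)
    hi = np.asarray(age_hi, dtype=float)
    mid = (lo + hi + 1.0) / 2.0
    mid = np.where(np.isnan(hi), lo + OPEN_ENDED_HALF_WIDTH, mid)
    return mid


def _d(x: np.ndarray, knot: float, kmax: float, scale: float) -> np.ndarray:
    # (x - knot)_+^3 - (x - kmax)_+^3, divided by (kmax - knot); scaled for conditioning
    num = np.clip(x - knot, 0, None) ** 3 - np.clip(x - kmax, 0, None) ** 3
    return num / (kmax - knot) / scale


def natural_spline_basis(x, knots: Sequence[float]) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form) with given knots.

    Returns an (n, K) design matrix for K knots, including the constant and
    linear columns; the function space is cubic between knots, linear beyond
    the boundary knots (zero second derivative there).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.asarray(sorted(knots), dtype=float)
    K = len(knots)
    if K < 3:
        raise ValueError("need at least 3 knots for a natural cubic spline basis")
    scale = (knots[-1] - knots[0]) ** 2
    cols = [np.ones_like(x), x]
    dlast = _d(x, knots[-2], knots[-1], scale)
    for k in knots[:-2]:
        cols.append(_d(x, k, knots[-1], scale) - dlast)
    return np.column_stack(cols)


def _d_deriv(x, knot, kmax, scale):
    num = 3 * np.clip(x - knot, 0, None) ** 2 - 3 * np.clip(x - kmax, 0, None) ** 2
    return num / (kmax - knot) / scale


def natural_spline_basis_deriv(x, knots: Sequence[float]) -> np.ndarray:
    """d/dx of :func:`natural_spline_basis`, column by column."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    knots = np.asarray(sorted(knots), dtype=float)
    scale = (knots[-1] - knots[0]) ** 2
    cols = [np.zeros_like(x), np.ones_like(x)]
    dlast = _d_deriv(x, knots[-2], knots[-1], scale)
    for k in knots[:-2]:
        cols.append(_d_deriv(x, k, knots[-1], scale) - dlast)
    return np.column_stack(cols)


@dataclass
class _SexFit:
    knots: np.ndarray
    coef: np.ndarray
    cov: np.ndarray
    year_center: float
    year_range: tuple
    year_by_spline: bool
    scale: float
    resid_logit: np.ndarray


@dataclass
class PrevalenceFit:
    """Per-sex logit-scale spline fits with coefficient covariances."""

    by_sex: Dict[str, _SexFit]
    age_window: tuple  # allowed prediction range in age
    dispersion: str

    @property
    def sexes(self):
        return tuple(self.by_sex)


def _design(sf: _SexFit, years, ages) -> np.ndarray:
    N = natural_spline_basis(ages, sf.knots)
    yc = np.atleast_1d(np.asarray(years, dtype=float)) - sf.year_center
    yc = np.broadcast_to(yc, (N.shape[0],)) if yc.size == 1 else yc
    if sf.year_by_spline:
        return np.column_stack([N, N * yc[:, None]])
    return np.column_stack([N, yc[:, None]])


def fit_prevalence(
    table: pd.DataFrame,
    *,
    year_by_spline: bool = True,
    dispersion: str = "estimated",
) -> PrevalenceFit:
    """Fit the logit-scale prevalence surface per sex by weighted least squares.

    Parameters
    ----------
    table : PrevalenceTable with columns year, sex, age_lo, age_hi,
        population, cases (prevalence_percent is recomputed internally, so a
        table in percent or proportion units gives the identical fit).
    year_by_spline : include year x spline-basis interactions (time-varying
        age profile); if False, year enters linearly only.
    dispersion : "estimated" scales the coefficient covariance by the
        weighted residual mean square (absorbs over-dispersion and
        lack of fit); "fixed" uses the nominal binomial dispersion of 1.

    Raises
    ------
    ValueError : fewer than 2 distinct years or fewer than 4 age groups per
        sex, or a singular design.
    """
    if dispersion not in ("estimated", "fixed"):
        raise ValueError("dispersion must be 'estimated' or 'fixed'")
    table = table.copy()
    by_sex = {}
    for sex, sub in table.groupby("sex", sort=False):
        years = np.asarray(sub["year"], dtype=float)
        if len(np.unique(years)) < 2:
            raise ValueError(f"sex={sex}: need >= 2 distinct years")
        mids = age_group_midpoints(sub["age_lo"], sub["age_hi"])
        knots = np.unique(mids)
        if len(knots) < 4:
            raise ValueError(f"sex={sex}: need >= 4 distinct age groups")
        N_pop = np.asarray(sub["population"], dtype=float)
        cases = np.asarray(sub["cases"], dtype=float)
        phat = cases / N_pop
        bad = (phat <= 0) | (phat >= 1)
        if bad.any():
            logger.warning(
                "prevalence fit sex=%s: %d strata at 0%% or 100%%, "
                "continuity-corrected", sex, int(bad.sum()),
            )
            phat = np.where(bad, (cases + 0.5) / (N_pop + 1.0), phat)
        y = logit(phat)
        w = N_pop * phat * (1.0 - phat)

        year_center = float(years.mean())
        sf = _SexFit(
            knots=knots,
            coef=None,
            cov=None,
            year_center=year_center,
            year_range=(float(years.min()), float(years.max())),
            year_by_spline=year_by_spline,
            scale=1.0,
            resid_logit=None,
        )
        X = _design(sf, years, mids)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"sex={sex}: singular design (collinear spline/year columns); "
                "reduce year_by_spline or merge age groups"
            )
        res = sm.WLS(y, X, weights=w).fit()
        sf.coef = np.asarray(res.params)
        resid = y - X @ sf.coef
        sf.resid_logit = resid
        dof = max(X.shape[0] - X.shape[1], 1)
        scale = float(np.sum(w * resid**2) / dof) if dispersion == "estimated" else 1.0
        sf.scale = scale
        XtWX_inv = np.asarray(res.normalized_cov_params)
        sf.cov = scale * XtWX_inv
        by_sex[sex] = sf
        logger.info(
            "prevalence fit sex=%s: rows=%d params=%d scale=%.4g max|resid|=%.4g",
            sex, X.shape[0], X.shape[1], scale, float(np.max(np.abs(resid))),
        )
    knots_all = np.concatenate([sf.knots for sf in by_sex.values()])
    window = (float(knots_all.min() - 2.5), float(knots_all.max() + 2.5))
    return PrevalenceFit(by_sex=by_sex, age_window=window, dispersion=dispersion)


def linear_predictor(fit: PrevalenceFit, year, ages, sex: str):
    """Return (eta, se_eta) at the given year and ages for one sex."""
    sf = fit.by_sex[sex]
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    lo, hi = fit.age_window
    if np.any(ages < lo) or np.any(ages > hi):
        raise ValueError(
            f"age outside the supported window [{lo}, {hi}] "
            "(extrapolation beyond the fitted age groups is refused)"
        )
    X = _design(sf, year, ages)
    eta = X @ sf.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, sf.cov, X))
    return eta, se


def predict_prevalence(fit: PrevalenceFit, year, ages, sex: str):
    """Fitted prevalence and linear-predictor SE at (year, ages, sex)."""
    eta, se = linear_predictor(fit, year, ages, sex)
    return expit(eta), se


def lexis_derivative(
    fit: PrevalenceFit,
    anchor_year: float,
    ages,
    sex: str,
    half_step: float = 4.0,
    mode: str = "fd",
):
    """Lexis-direction derivative D = (d/dt + d/da) p on the fitted surface.

    mode "fd": centred difference along the cohort diagonal,
    D(a) = [p(t+h, a+h) - p(t-h, a-h)] / (2h) with h = half_step.
    mode "analytic": D = p (1-p) (d_t eta + d_a eta) from basis derivatives.
    """
    sf = fit.by_sex[sex]
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    h = float(half_step)
    y0, y1 = sf.year_range
    if mode == "fd":
        if anchor_year - h < y0 - 1e-9 or anchor_year + h > y1 + 1e-9:
            raise ValueError(
                f"derivative stencil [{anchor_year - h}, {anchor_year + h}] "
                f"outside fitted year span [{y0}, {y1}]"
            )
        p_hi, _ = predict_prevalence(fit, anchor_year + h, ages + h, sex)
        p_lo, _ = predict_prevalence(fit, anchor_year - h, ages - h, sex)
        return (p_hi - p_lo) / (2.0 * h)
    if mode == "analytic":
        eta, _ = linear_predictor(fit, anchor_year, ages, sex)
        p = expit(eta)
        Nd = natural_spline_basis_deriv(ages, sf.knots)
        N = natural_spline_basis(ages, sf.knots)
        yc = anchor_year - sf.year_center
        if sf.year_by_spline:
            deta_da = np.column_stack([Nd, Nd * yc]) @ sf.coef
            deta_dt = np.column_stack([np.zeros_like(N), N]) @ sf.coef
        else:
            k = N.shape[1]
            deta_da = Nd @ sf.coef[:k]
            deta_dt = np.full(len(ages), sf.coef[k])
        return p * (1.0 - p) * (deta_dt + deta_da)
    raise ValueError("mode must be 'fd' or 'analytic'")
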