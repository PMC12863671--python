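"""Sex-specific log-linear models for stratum mortality rate ratios.

Registry studies report the excess mortality of a diseased cohort as the
ratio of observed to expected deaths (expected = general-population rates
applied to the cohort) in 5-year age-by-sex strata.  To obtain a smooth age
function for the PDE inversion, log(MRR) is regressed on the stratum age
midpoint separately per sex:

    MRR(a, sex) = exp(alpha_sex + beta_sex * a) * factor

The calibration ``factor`` (default 1) implements uniform multiplicative
scaling of all predicted MRRs, used by the +/-15% sensitivity scenarios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .prevalence_model import age_group_midpoints

logger = logging.getLogger(__name__)

__all__ = ["MRRFit", "fit_mrr", "predict_mrr", "scale_mrr"]


@dataclass(frozen=True)
class _SexLine:
    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    r2_adj: float
    n: int


@dataclass(frozen=True)
class MRRFit:
    by_sex: Dict[str, _SexLine]
    r2_adj_pooled: float
    factor: float = 1.0


def fit_mrr(table: pd.DataFrame, *, weighted: bool = False) -> MRRFit:
    """OLS of log(mrr) on stratum age midpoint, separately per sex.

    Parameters
    ----------
    table : MRRTable with columns sex, age_lo, age_hi, mrr and optionally
        observed_deaths / expected_deaths.
    weighted : weight strata by expected deaths (requires the count columns);
        default is the unweighted regression.

    Returns per-sex intercept/slope with standard errors and adjusted R^2,
    plus a pooled adjusted R^2 computed over both sexes' fitted values.
    """
    by_sex = {}
    ss_res_tot = 0.0
    ss_tot_parts = []
    n_tot = 0
    k_tot = 0
    for sex, sub in table.groupby("sex", sort=False):
        if len(sub) < 3:
            raise ValueError(f"sex={sex}: need >= 3 MRR strata, got {len(sub)}")
        mrr = np.asarray(sub["mrr"], dtype=float)
        if np.any(mrr <= 0) or np.any(~np.isfinite(mrr)):
            rows = sub.index[(mrr <= 0) | ~np.isfinite(mrr)].tolist()
            raise ValueError(f"sex={sex}: non-positive MRR in strata rows {rows}")
        mids = age_group_midpoints(sub["age_lo"], sub["age_hi"])
        y = np.log(mrr)
        X = sm.add_constant(mids)
        if weighted:
            if "expected_deaths" not in sub:
                raise ValueError("weighted fit requires an expected_deaths column")
            w = np.asarray(sub["expected_deaths"], dtype=float)
            res = sm.WLS(y, X, weights=w).fit()
        else:
            res = sm.OLS(y, X).fit()
        by_sex[sex] = _SexLine(
            alpha=float(res.params[0]),
            beta=float(res.params[1]),
            se_alpha=float(res.bse[0]),
            se_beta=float(res.bse[1]),
            r2_adj=float(res.rsquared_adj),
            n=len(sub),
        )
        resid = y - res.fittedvalues
        ss_res_tot += float(np.sum(resid**2))
        ss_tot_parts.append(y)
        n_tot += len(sub)
        k_tot += 2
        logger.info(
            "mrr fit sex=%s: n=%d alpha=%.4f beta=%.5f adjR2=%.4f",
            sex, len(sub), res.params[0], res.params[1], res.rsquared_adj,
        )
    y_all = np.concatenate(ss_tot_parts)
    ss_tot = float(np.sum((y_all - y_all.mean()) ** 2))
    r2 = 1.0 - ss_res_tot / ss_tot if ss_tot > 0 else 1.0
    dof = n_tot - k_tot
    r2_adj_pooled = 1.0 - (1.0 - r2) * (n_tot - 1) / dof if dof > 0 else np.nan
    return MRRFit(by_sex=by_sex, r2_adj_pooled=float(r2_adj_pooled))


def predict_mrr(fit: MRRFit, age, sex: str, *, alpha=None, beta=None):
    """Model-predicted MRR at the given age(s) for one sex.

    ``alpha``/``beta`` override the fitted coefficients (used by the
    bootstrap's coefficient perturbation); the calibration factor is always
    applied multiplicatively after back-transformation.
    """
    line = fit.by_sex[sex]
    a = line.alpha if alpha is None else alpha
    b = line.beta if beta is None else beta
    age = np.asarray(age, dtype=float)
    out = np.exp(a + b * age) * fit.factor
    return float(out) if out.ndim == 0 else out


def scale_mrr(fit: MRRFit, factor: float) -> MRRFit:
    """Return a fit whose predictions are exactly ``factor`` x the original.

    Coefficient standard errors are unchanged (the scaling is a deterministic
    calibration, not a re-estimation).
    """
    if factor <= 0:
        raise ValueError("calibration factor must be positive")
    return replace(fit, factor=fit.factor * factor)
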