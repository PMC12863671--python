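"""Model-level parametric bootstrap for the PDE incidence estimate.

Aggregated inputs admit no record-level resampling, so uncertainty is
propagated parametrically: per replicate the prevalence model's linear
predictor is perturbed on the logit scale by independent normal deviates
scaled to its standard error (one deviate per evaluation point: the anchor
point and the two Lexis-stencil points, per support age and sex), the MRR
regression's intercept and slope are perturbed by normal deviates scaled to
their standard errors, general-population mortality is kept fixed, and the
Lexis-direction derivative and the PDE inversion are recomputed.  Point
estimates are the replicate medians; uncertainty the empirical 2.5th/97.5th
percentiles.

All randomness flows from one master seed through named substreams
(prevalence deviates, MRR deviates), so different MRR calibration factors
can consume identical draws - the basis of the paired sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .idm_core import LexisGrid, incidence_from_pde
from .io_cli import mortality_rate
from .mrr_model import MRRFit, predict_mrr
from .prevalence_model import PrevalenceFit, lexis_derivative, linear_predictor, predict_prevalence

logger = logging.getLogger(__name__)

__all__ = ["BootstrapConfig", "BootstrapResult", "point_estimate",
           "run_bootstrap", "summarize"]


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 5000
    seed: int = 0
    mrr_scale_factors: Tuple[float, ...] = (1.0,)
    quantiles: Tuple[float, float] = (0.025, 0.975)
    half_step: float = 4.0

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        lo, hi = self.quantiles
        if not (0 < lo < hi < 1):
            raise ValueError("quantiles must be ordered and inside (0, 1)")
        if any(f <= 0 for f in self.mrr_scale_factors):
            raise ValueError("MRR scale factors must be positive")


def point_estimate(
    prev_fit: PrevalenceFit,
    mrr_fit: MRRFit,
    mortality: pd.DataFrame,
    grid: LexisGrid,
    *,
    half_step: float = 4.0,
    floor_at_zero: bool = False,
) -> pd.DataFrame:
    """Unperturbed fit -> Lexis derivative -> PDE inversion, per sex and age."""
    rows = []
    s = grid.support_ages
    for sex in grid.sexes:
        p, _ = predict_prevalence(prev_fit, grid.anchor_year, s, sex)
        D = lexis_derivative(prev_fit, grid.anchor_year, s, sex, half_step=half_step)
        m = mortality_rate(mortality, grid.anchor_year, s, sex)
        mrr = predict_mrr(mrr_fit, s, sex)
        inc = incidence_from_pde(p, D, m, mrr, floor_at_zero=floor_at_zero)
        for k, lo in enumerate(grid.ages):
            rows.append({
                "sex": sex, "age_lo": lo, "age": s[k], "p": p[k], "D": D[k],
                "m": m[k], "mrr": mrr[k], "incidence": inc[k],
                "negative": bool(inc[k] < 0),
            })
    return pd.DataFrame(rows)


@dataclass
class BootstrapResult:
    """Replicate summaries (and optionally full replicate matrices)."""

    table: pd.DataFrame          # scenario_factor, sex, age_lo, age, median, lo, hi, n_excluded
    config: BootstrapConfig
    grid: LexisGrid
    replicates: Optional[Dict[Tuple[float, str], np.ndarray]] = None


def _draws(config: BootstrapConfig, n_sex: int, n_age: int):
    prev_ss, mrr_ss = np.random.SeedSequence(config.seed).spawn(2)
    eps = np.random.default_rng(prev_ss).standard_normal(
        (config.B, 3, n_sex, n_age))
    coef = np.random.default_rng(mrr_ss).standard_normal((config.B, 2, n_sex))
    return eps, coef


def run_bootstrap(
    prev_fit: PrevalenceFit,
    mrr_fit: MRRFit,
    mortality: pd.DataFrame,
    grid: LexisGrid,
    config: BootstrapConfig,
    *,
    keep_replicates: bool = False,
) -> BootstrapResult:
    """Run the parametric bootstrap for every configured MRR scale factor.

    The prevalence and MRR deviates are drawn once and reused across factors
    (common random numbers), so factor-to-factor differences are paired.
    Replicate points with perturbed prevalence outside [0, 1) or a
    non-finite incidence are excluded from the quantiles with a logged count.
    """
    if config.B < 100:
        logger.warning("B=%d < 100: bootstrap intervals will be unstable", config.B)
    s = grid.support_ages
    t, h = grid.anchor_year, config.half_step
    n_age, n_sex = len(s), len(grid.sexes)
    eps, coef = _draws(config, n_sex, n_age)

    stencil = {}
    m_fixed = {}
    for j, sex in enumerate(grid.sexes):
        eta0, se0 = linear_predictor(prev_fit, t, s, sex)
        etam, sem = linear_predictor(prev_fit, t - h, s - h, sex)
        etap, sep = linear_predictor(prev_fit, t + h, s + h, sex)
        stencil[sex] = (eta0, se0, etam, sem, etap, sep)
        m_fixed[sex] = mortality_rate(mortality, t, s, sex)

    rows = []
    reps: Dict[Tuple[float, str], np.ndarray] = {}
    qlo, qhi = config.quantiles
    for factor in config.mrr_scale_factors:
        for j, sex in enumerate(grid.sexes):
            eta0, se0, etam, sem, etap, sep = stencil[sex]
            p0 = expit(eta0 + eps[:, 0, j, :] * se0)          # (B, n_age)
            pm = expit(etam + eps[:, 1, j, :] * sem)
            pp = expit(etap + eps[:, 2, j, :] * sep)
            D = (pp - pm) / (2.0 * h)
            line = mrr_fit.by_sex[sex]
            alpha = line.alpha + coef[:, 0, j] * line.se_alpha
            beta = line.beta + coef[:, 1, j] * line.se_beta
            mrr = np.exp(alpha[:, None] + beta[:, None] * s) * mrr_fit.factor * factor
            m = m_fixed[sex]
            excess = p0 * (mrr - 1.0)
            inc = D / (1.0 - p0) + m * excess / (1.0 + excess)
            valid = (p0 < 1.0) & np.isfinite(inc)
            if keep_replicates:
                reps[(factor, sex)] = inc
            for k, lo in enumerate(grid.ages):
                col = inc[valid[:, k], k]
                n_exc = config.B - col.size
                if n_exc:
                    logger.warning(
                        "factor=%s sex=%s age=%s: %d replicates excluded",
                        factor, sex, s[k], n_exc)
                if col.size == 0:
                    med = lo95 = hi95 = np.nan
                else:
                    med = float(np.median(col))
                    lo95 = float(np.quantile(col, qlo))
                    hi95 = float(np.quantile(col, qhi))
                rows.append({
                    "scenario_factor": factor, "sex": sex, "age_lo": lo,
                    "age": s[k], "median": med, "lo": lo95, "hi": hi95,
                    "n_excluded": int(n_exc),
                })
    table = pd.DataFrame(rows)
    logger.info("bootstrap done: B=%d factors=%s excluded_total=%d",
                config.B, list(config.mrr_scale_factors),
                int(table["n_excluded"].sum()))
    return BootstrapResult(table=table, config=config, grid=grid,
                           replicates=reps if keep_replicates else None)


def summarize(result: BootstrapResult, per_thousand: bool = True) -> pd.DataFrame:
    """Incidence summary table: one row per scenario x sex x age group.

    Values are scaled to events per 1,000 person-years when ``per_thousand``
    and rounded to three decimals (half-up).  Empty quantile sets stay NaN
    (an explicit missing marker), never zero.
    """
    from .reporting import round_half_up  # local import: reporting is a leaf

    scale = 1000.0 if per_thousand else 1.0
    out = result.table.copy()
    labels = dict(zip(result.grid.ages, result.grid.group_labels()))
    out["age_group"] = out["age_lo"].map(labels)
    for col, new in (("median", "median"), ("lo", "lo95"), ("hi", "hi95")):
        out[new] = [round_half_up(v * scale, 3) if np.isfinite(v) else np.nan
                    for v in out[col]]
    out["width"] = out["hi95"] - out["lo95"]
    cols = ["scenario_factor", "sex", "age_group", "age_lo", "age",
            "median", "lo95", "hi95", "width", "n_excluded"]
    return out[cols]
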