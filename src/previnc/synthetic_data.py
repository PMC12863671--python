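"""Synthetic aggregated inputs from a fully known ground-truth scenario.

The generator emulates the statistical shape of the three inputs the
estimation pipeline consumes:

* a claims-style prevalence table (cases / population per calendar year x
  sex x 5-year age group, with binomial sampling of prevalent cases),
* an HMD-style all-cause period death-rate table (single ages x year x sex,
  noise-free: general-population mortality is treated as fixed), and
* a registry-style MRR table (observed/expected deaths of the diseased
  cohort in 5-year age-by-sex strata, with Poisson sampling of deaths).

Ground truth: exponential (Gompertz-type in age) incidence
``i(a) = exp(b0 + b1 a)``, Gompertz healthy mortality ``m0(a) = c exp(g a)``
and log-linear MRR ``exp(alpha + beta a)``, all time-constant; prevalence
follows from the illness-death model cohort ODE with p(0) = 0 at birth.
Because every table derives from a known scenario, each downstream stage is
testable by parameter recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .idm_core import forward_prevalence, general_mortality

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "Truth", "SyntheticBundle", "simulate_truth",
           "generate_prevalence_table", "generate_mortality_table",
           "generate_mrr_table", "make_bundle", "S1"]

_SEXES = ("male", "female")


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth scenario defining all three synthetic inputs.

    Default scenario S1: rising exponential incidence with a male excess,
    shared Gompertz healthy mortality, MRR declining log-linearly with age.
    Population sizes are persons per single year of age x sex x calendar
    year: 200,000 for the prevalence denominators (statutory-claims scale)
    and 25,000 for the MRR source population (Nordic registry scale).
    """

    incidence_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"male": (-12.6, 0.11), "female": (-13.2, 0.11)}
    )
    gompertz_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"male": (2e-5, 0.095), "female": (2e-5, 0.095)}
    )
    mrr_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"male": (2.6, -0.012), "female": (2.6, -0.012)}
    )
    population_size: int = 200_000
    mrr_population_size: int = 25_000
    years: Tuple[int, ...] = tuple(range(2009, 2018))
    seed: int = 1234
    prevalence_noise: bool = True   # binomial sampling of prevalent cases
    mrr_noise: bool = True          # Poisson sampling of observed deaths
    prevalence_age_lo: Tuple[int, ...] = tuple(range(0, 110, 5))
    mrr_age_lo: Tuple[int, ...] = tuple(range(40, 95, 5))
    age_max: float = 110.0

    def incidence(self, age, sex):
        b0, b1 = self.incidence_params[sex]
        return np.exp(b0 + b1 * np.asarray(age, dtype=float))

    def m0(self, age, sex):
        c, g = self.gompertz_params[sex]
        return c * np.exp(g * np.asarray(age, dtype=float))

    def mrr(self, age, sex):
        a, b = self.mrr_params[sex]
        return np.exp(a + b * np.asarray(age, dtype=float))

    def m1(self, age, sex):
        return self.m0(age, sex) * self.mrr(age, sex)


S1 = ScenarioConfig()


@dataclass(frozen=True)
class Truth:
    """Exact scenario surfaces on a fine age grid (rates are time-constant)."""

    config: ScenarioConfig
    grid_ages: np.ndarray
    p_by_sex: Dict[str, np.ndarray]

    def prevalence(self, age, sex):
        return np.interp(np.asarray(age, dtype=float),
                         self.grid_ages, self.p_by_sex[sex])

    def incidence(self, age, sex):
        return self.config.incidence(age, sex)

    def m0(self, age, sex):
        return self.config.m0(age, sex)

    def m1(self, age, sex):
        return self.config.m1(age, sex)

    def mrr(self, age, sex):
        return self.config.mrr(age, sex)

    def general_mortality(self, age, sex):
        p = self.prevalence(age, sex)
        return general_mortality(p, self.m0(age, sex), self.m1(age, sex))

    def lexis_derivative(self, age, sex):
        """Exact D = (1-p)[i - p (m1 - m0)] (the PDE right-hand side)."""
        p = self.prevalence(age, sex)
        return (1.0 - p) * (self.incidence(age, sex)
                            - p * (self.m1(age, sex) - self.m0(age, sex)))


def simulate_truth(config: ScenarioConfig, step: float = 0.05) -> Truth:
    """Solve the cohort ODE from birth (p(0)=0) per sex on a fine age grid.

    Rates are time-constant, so the prevalence surface is the same for every
    calendar year and every birth cohort; one forward solve per sex suffices.
    """
    p_by_sex = {}
    grid = None
    for sex in _SEXES:
        ages, p = forward_prevalence(
            i=lambda a, s=sex: config.incidence(a, s),
            m0=lambda a, s=sex: config.m0(a, s),
            m1=lambda a, s=sex: config.m1(a, s),
            a0=0.0, p0=0.0, a_end=config.age_max, step=step,
        )
        if np.max(p) > 0.99:
            raise ValueError(
                f"scenario drives prevalence to {np.max(p):.3f} (-> 1) for "
                f"sex={sex}; choose weaker incidence or stronger excess mortality"
            )
        grid = ages
        p_by_sex[sex] = p
    return Truth(config=config, grid_ages=grid, p_by_sex=p_by_sex)


def _single_ages(lo: int, width: int = 5) -> np.ndarray:
    # nominal ages of the single-year sub-strata of group [lo, lo+width)
    return np.arange(lo, lo + width) + 0.5


def generate_prevalence_table(
    config: ScenarioConfig, truth: Truth, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Aggregate truth into a claims-style prevalence table.

    Group prevalence is the population-weighted mean over single ages (equal
    single-age populations by construction); with noise on, cases are
    Binomial(N, p_group) draws, otherwise exactly N * p_group.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    rows = []
    for year in config.years:
        for sex in _SEXES:
            for lo in config.prevalence_age_lo:
                ages = _single_ages(lo)
                N = config.population_size * len(ages)
                if N == 0:
                    logger.warning("empty stratum %s %s %s dropped", year, sex, lo)
                    continue
                p_bar = float(np.mean(truth.prevalence(ages, sex)))
                if config.prevalence_noise:
                    cases = float(rng.binomial(N, p_bar))
                else:
                    cases = N * p_bar
                rows.append({
                    "year": year, "sex": sex, "age_lo": lo, "age_hi": lo + 4,
                    "population": N, "cases": cases,
                    "prevalence_percent": 100.0 * cases / N,
                })
    return pd.DataFrame(rows)


def generate_mortality_table(config: ScenarioConfig, truth: Truth) -> pd.DataFrame:
    """HMD-style period death rates m(t, a, sex) on single ages 0-110.

    Noise-free: the pipeline treats general-population mortality as fixed.
    The rate recorded at integer age label ``a`` is the truth at the interval
    midpoint ``a + 0.5``; the Total column is the population-weighted mean of
    the sex-specific columns (equal populations here).
    """
    ages = np.arange(0, int(config.age_max) + 1)
    rows = []
    for year in config.years:
        f = truth.general_mortality(ages + 0.5, "female")
        m = truth.general_mortality(ages + 0.5, "male")
        for a, fr, mr in zip(ages, f, m):
            rows.append({
                "year": year, "age": int(a),
                "open_ended": int(a) == int(config.age_max),
                "female": fr, "male": mr, "total": 0.5 * (fr + mr),
            })
    return pd.DataFrame(rows)


def generate_mrr_table(
    config: ScenarioConfig, truth: Truth, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Registry-style observed/expected death ratios in 5-year strata.

    Per stratum the diseased cohort's person-years are the source
    population's prevalent fraction; expected deaths E apply the healthy
    (general-population) rate m0, observed deaths O carry the true excess:
    O ~ Poisson(E x MRR_bar) with noise on.  Strata with E = 0 or O = 0 are
    dropped with a warning (a log-scale fit cannot use them).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    rows = []
    for sex in _SEXES:
        for lo in config.mrr_age_lo:
            ages = _single_ages(lo)
            py1 = config.mrr_population_size * truth.prevalence(ages, sex)
            E = float(np.sum(py1 * truth.m0(ages, sex)))
            lam = float(np.sum(py1 * truth.m1(ages, sex)))
            if E <= 0:
                logger.warning("MRR stratum %s %d-%d has zero expected deaths; "
                               "dropped", sex, lo, lo + 4)
                continue
            O = float(rng.poisson(lam)) if config.mrr_noise else lam
            if O <= 0:
                logger.warning("MRR stratum %s %d-%d observed zero deaths; "
                               "dropped", sex, lo, lo + 4)
                continue
            rows.append({
                "sex": sex, "age_lo": lo, "age_hi": lo + 4,
                "mrr": O / E, "observed_deaths": O, "expected_deaths": E,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticBundle:
    config: ScenarioConfig
    truth: Truth
    prevalence_table: pd.DataFrame
    mortality_table: pd.DataFrame
    mrr_table: pd.DataFrame


def make_bundle(config: ScenarioConfig = S1) -> SyntheticBundle:
    """Simulate truth and generate all three tables from the scenario seed."""
    truth = simulate_truth(config)
    streams = np.random.SeedSequence(config.seed).spawn(2)
    prev = generate_prevalence_table(config, truth,
                                     np.random.default_rng(streams[0]))
    mort = generate_mortality_table(config, truth)
    mrr = generate_mrr_table(config, truth, np.random.default_rng(streams[1]))
    return SyntheticBundle(config=config, truth=truth, prevalence_table=prev,
                           mortality_table=mort, mrr_table=mrr)
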