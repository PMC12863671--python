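"""Illness-death model: transition rates, the prevalence PDE and its inversion.

The illness-death model (IDM) describes a chronic condition without recovery
through three states -- healthy, diseased, dead -- with transition intensities
``i`` (incidence), ``m0`` (mortality of the healthy) and ``m1`` (mortality of
the diseased).  Along the Lexis diagonal (a fixed birth cohort moving through
calendar time ``t`` and age ``a``) the prevalence ``p(t, a)`` obeys

    (d/dt + d/da) p = (1 - p) * [i - p * (m1 - m0)].

Writing ``m = p*m1 + (1-p)*m0`` for the general (all-cause) mortality and
``MRR = m1/m0`` for the mortality rate ratio, the equation can be solved for
the incidence:

    i = D / (1 - p) + m * p * (MRR - 1) / (1 + p * (MRR - 1)),

where ``D`` is the Lexis-direction derivative of prevalence.  This module
implements that inversion, the rate algebra around it, and a deterministic
forward solver for the cohort ODE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LexisGrid",
    "incidence_from_pde",
    "general_mortality",
    "mortality_split",
    "forward_prevalence",
]


@dataclass(frozen=True)
class LexisGrid:
    """Evaluation grid for incidence estimation.

    ``ages`` are the lower bounds of 5-year age groups (default 20..90 in
    steps of 5, the last group open-ended).  The incidence support points are
    the group midpoints ``ages + midpoint_offset`` (offset 2.5 by default;
    set 0 to evaluate at the lower bounds instead).  ``anchor_year`` is the
    calendar year at which incidence is evaluated.
    """

    ages: tuple = tuple(range(20, 95, 5))
    anchor_year: int = 2013
    sexes: tuple = ("male", "female")
    midpoint_offset: float = 2.5

    def __post_init__(self):
        ages = tuple(float(a) for a in self.ages)
        if len(ages) < 2 or any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing with >= 2 entries")
        object.__setattr__(self, "ages", ages)

    @property
    def support_ages(self) -> np.ndarray:
        """Ages (in years) at which incidence is evaluated."""
        return np.asarray(self.ages) + self.midpoint_offset

    def group_labels(self, width: float = 5.0) -> list:
        labels = [f"{int(a)}–{int(a + width - 1)}" for a in self.ages[:-1]]
        labels.append(f"{int(self.ages[-1])}+")
        return labels


def _validate(p, m=None, mrr=None):
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("prevalence must satisfy 0 <= p < 1")
    if m is not None and np.any(np.asarray(m, dtype=float) < 0):
        raise ValueError("mortality rate must be nonnegative")
    if mrr is not None and np.any(np.asarray(mrr, dtype=float) <= 0):
        raise ValueError("mortality rate ratio must be positive")
    return p


def incidence_from_pde(p, D, m, mrr, *, floor_at_zero: bool = False):
    """Invert the IDM PDE for the incidence rate (per person-year).

    Parameters
    ----------
    p : prevalence in [0, 1)
    D : Lexis-direction derivative (d/dt + d/da) of prevalence, per year
    m : general (all-cause) mortality rate, per person-year
    mrr : mortality rate ratio m1/m0, > 0
    floor_at_zero : clip negative results to 0 (off by default; noisy inputs
        can legitimately produce negative values, which are preserved so the
        caller can flag them)

    Returns
    -------
    incidence rate(s), same shape as the broadcast inputs.
    """
    p = _validate(p, m, mrr)
    D = np.asarray(D, dtype=float)
    m = np.asarray(m, dtype=float)
    mrr = np.asarray(mrr, dtype=float)
    excess = p * (mrr - 1.0)
    denom = 1.0 + excess
    if np.any(denom <= 0):
        raise ValueError("1 + p*(mrr-1) must be positive")
    i = D / (1.0 - p) + m * excess / denom
    if floor_at_zero:
        i = np.maximum(i, 0.0)
    if i.ndim == 0:
        return float(i)
    return i


def general_mortality(p, m0, m1):
    """Population all-cause mortality ``m = p*m1 + (1-p)*m0``."""
    p = np.asarray(p, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("prevalence must lie in [0, 1]")
    if np.any(m0 < 0) or np.any(m1 < 0):
        raise ValueError("mortality rates must be nonnegative")
    out = p * m1 + (1.0 - p) * m0
    return float(out) if out.ndim == 0 else out


def mortality_split(m, p, mrr):
    """Split general mortality into state-specific rates (m0, m1).

    Inverts ``m = p*m1 + (1-p)*m0`` under ``m1 = mrr*m0``:
    ``m0 = m / (1 + p*(mrr-1))``.  The round trip through
    :func:`general_mortality` is exact.
    """
    p = _validate(p, m, mrr)
    m = np.asarray(m, dtype=float)
    mrr = np.asarray(mrr, dtype=float)
    denom = 1.0 + p * (mrr - 1.0)
    if np.any(denom <= 0):
        raise ValueError("1 + p*(mrr-1) must be positive")
    m0 = m / denom
    m1 = mrr * m0
    if m0.ndim == 0:
        return float(m0), float(m1)
    return m0, m1


def forward_prevalence(
    i: Callable[[np.ndarray], np.ndarray],
    m0: Callable[[np.ndarray], np.ndarray],
    m1: Callable[[np.ndarray], np.ndarray],
    a0: float,
    p0: float,
    a_end: float,
    step: float = 0.1,
    tol: float = 1e-9,
):
    """Solve the cohort ODE dp/da = (1-p)[i(a) - p (m1(a) - m0(a))] forward.

    Classic fixed-step 4th-order Runge-Kutta (deterministic, reproducible).
    Rate arguments are callables of age and may be vectorised.

    Returns
    -------
    (ages, p) : ndarrays; ``ages`` runs from a0 to a_end in ``step``
        increments (last step shortened to land on a_end exactly).
    """
    if not 0.0 <= p0 < 1.0:
        raise ValueError("p0 must lie in [0, 1)")
    if step <= 0:
        raise ValueError("step must be positive")
    if a_end < a0:
        raise ValueError("a_end must be >= a0")

    def f(a, p):
        return (1.0 - p) * (float(i(a)) - p * (float(m1(a)) - float(m0(a))))

    ages = [a0]
    ps = [float(p0)]
    a, p = a0, float(p0)
    while a < a_end - 1e-12:
        h = min(step, a_end - a)
        k1 = f(a, p)
        k2 = f(a + h / 2, p + h * k1 / 2)
        k3 = f(a + h / 2, p + h * k2 / 2)
        k4 = f(a + h, p + h * k3)
        p = p + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        a = a + h
        if p < -tol or p > 1.0 + tol:
            raise FloatingPointError(
                f"prevalence left [0, 1] at age {a:.3f} (p={p:.3e}); "
                "try a smaller step"
            )
        p = min(max(p, 0.0), 1.0)
        ages.append(a)
        ps.append(p)
    return np.asarray(ages), np.asarray(ps)
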