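"""Abridged period life tables: age-specific mortality rates to life expectancy.

Given age-specific rates m_j on an abridged grid (interval widths n_j, mean
fraction of the interval lived by those dying a_j), the Chiang construction
gives death probabilities

    q_j = n_j m_j / (1 + n_j (1 - a_j) m_j)        (closed intervals)
    q_J = 1                                        (open-ended last interval)

survivorship l_1 = 1, l_{j+1} = l_j (1 - q_j), deaths d_j = l_j q_j,
person-years L_j = n_j (l_{j+1} + a_j d_j) for closed intervals and
L_J = l_J / m_J for the open one, and life expectancy at birth
e0 = sum_j L_j / l_1.

Defaults follow national-statistics practice for this age grouping:
a_j = 0.5 in closed intervals, a = 0.1 for the infant (<1 year) group.
Posterior summaries are built by applying the table to every posterior draw
of the fitted rates and summarizing e0 across draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MortalityDataset
from .model import PosteriorSamples

__all__ = [
    "AbridgedLifeTableConfig",
    "e0_from_rates",
    "e0_draws_area_year",
    "e0_draws_decile_year",
    "area_year_e0",
    "decile_year_e0",
    "e0_gap",
]

DAYS_PER_YEAR = 365.25
RATE_FLOOR = 1.0e-10


@dataclass
class AbridgedLifeTableConfig:
    """Interval widths and within-interval survival fractions.

    ``widths[j]`` is n_j in years; the last entry is ignored (open interval).
    ``a`` holds the average fraction of the interval lived by those dying in
    it; the last entry is unused since the open interval is closed out as
    L = l / m.
    """

    widths: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.widths.shape != self.a.shape:
            raise ValueError("widths and a must have equal length")
        if np.any((self.a[:-1] <= 0) | (self.a[:-1] >= 1)):
            raise ValueError("a_j must lie strictly between 0 and 1 for closed intervals")
        if np.any(self.widths[:-1] <= 0):
            raise ValueError("closed interval widths must be positive")

    @property
    def n_groups(self) -> int:
        return self.widths.shape[0]

    @classmethod
    def from_age_groups(cls, age_groups, a_infant: float = 0.1,
                        a_default: float = 0.5) -> "AbridgedLifeTableConfig":
        """Build the standard config for a dataset's age grid."""
        widths = []
        for lo, hi in age_groups:
            widths.append(float(hi - lo) if hi is not None else np.nan)
        a = np.full(len(age_groups), a_default)
        if age_groups[0] == (0, 1):
            a[0] = a_infant
        return cls(widths=np.array(widths), a=a)


def e0_from_rates(m, config: AbridgedLifeTableConfig):
    """Life expectancy at birth from age-specific rates.

    ``m`` may be a single length-J vector or any array with trailing axis J;
    the table is computed independently along the last axis. Rates are
    floored at 1e-10 to guard the open-interval division; a negative rate is
    an error.
    """
    m = np.asarray(m, dtype=float)
    J = config.n_groups
    if m.shape[-1] != J:
        raise ValueError(f"rate vector length {m.shape[-1]} != {J} age groups")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError("rates must be finite and non-negative")
    m = np.maximum(m, RATE_FLOOR)

    n = config.widths
    a = config.a
    closed = slice(0, J - 1)
    nm = n[closed] * m[..., closed]
    q_raw = nm / (1.0 + n[closed] * (1.0 - a[closed]) * m[..., closed])
    q = np.ones_like(m)
    q[..., closed] = np.minimum(q_raw, 1.0)

    l = np.ones(m.shape[:-1] + (J + 1,))
    l[..., 1:] = np.cumprod(1.0 - q, axis=-1)

    # L = n*l*(1-(1-a)*q) is algebraically n*(l_{j+1} + a*d_j) but stable for
    # tiny q; where q clamps to 1 the whole cohort dies in the interval and
    # person-years revert to the defining identity L = d/m = l/m.
    L = np.empty_like(m)
    L_reg = n[closed] * l[..., :J - 1] * (1.0 - (1.0 - a[closed]) * q[..., closed])
    L[..., closed] = np.where(q_raw < 1.0, L_reg, l[..., :J - 1] / m[..., closed])
    L[..., -1] = l[..., J - 1] / m[..., -1]
    e0 = L.sum(axis=-1) / l[..., 0]
    return float(e0) if e0.ndim == 0 else e0


def _rates_area_year(samples: PosteriorSamples) -> np.ndarray:
    """Posterior rate draws lambda, shape (S, I, J, T)."""
    d = samples.decile_index
    eta = (
        samples.a0[:, None, None, None]
        + samples.alpha[:, None, :, None]
        + samples.gamma[:, :, None, None]
        + samples.zeta[:, None, None, :]
        + samples.phi[:, d][:, :, None, None]
        + samples.omega[:, :, None, :]
        + samples.delta[:, :, :, None]
        + samples.kappa[:, None, :, :]
        + samples.nu[:, d][:, :, None, :]
    )
    return np.exp(eta)


def e0_draws_area_year(samples: PosteriorSamples,
                       config: AbridgedLifeTableConfig) -> np.ndarray:
    """Per-draw life expectancy at birth, shape (S, I, T)."""
    lam = _rates_area_year(samples)                      # (S, I, J, T)
    m = np.moveaxis(lam, 2, -1)                          # (S, I, T, J)
    return e0_from_rates(m, config)


def e0_draws_decile_year(samples: PosteriorSamples, data: MortalityDataset,
                         config: AbridgedLifeTableConfig) -> np.ndarray:
    """Per-draw decile-level e0, shape (S, D, T), from pooled rates.

    Decile rates are the population-weighted mean of member-area rates:
    m_j(d, t) = sum_{i in d} lambda_ijt Pop_ijt / sum_{i in d} Pop_ijt.
    """
    lam = _rates_area_year(samples)                      # (S, I, J, T)
    D = int(samples.decile_index.max()) + 1
    counts = np.bincount(samples.decile_index, minlength=D)
    if np.any(counts == 0):
        empty = int(np.nonzero(counts == 0)[0][0]) + 1
        raise ValueError(f"decile {empty} has no member areas")
    Z = np.zeros((D, data.n_areas))
    Z[samples.decile_index, np.arange(data.n_areas)] = 1.0
    pop = data.population                                # (I, J, T)
    num = np.einsum("di,sijt,ijt->sdjt", Z, lam, pop)
    den = np.einsum("di,ijt->djt", Z, pop)
    m = num / den[None, :, :, :]
    return e0_from_rates(np.moveaxis(m, 2, -1), config)  # (S, D, T)


def _summarize(e0_draws: np.ndarray, labels: list, unit_name: str,
               years: list[int], sex: str) -> pd.DataFrame:
    S = e0_draws.shape[0]
    mean = e0_draws.mean(axis=0)
    lo = np.quantile(e0_draws, 0.025, axis=0)
    hi = np.quantile(e0_draws, 0.975, axis=0)
    rows = []
    for u, lab in enumerate(labels):
        for t, y in enumerate(years):
            rows.append({
                unit_name: lab, "sex": sex, "year": y,
                "e0_mean": mean[u, t], "e0_low": lo[u, t], "e0_high": hi[u, t],
                "n_draws": S,
            })
    return pd.DataFrame(rows)


def area_year_e0(samples: PosteriorSamples, data: MortalityDataset,
                 config: AbridgedLifeTableConfig) -> pd.DataFrame:
    """Posterior mean and 95% credible interval of e0 per area-year."""
    draws = e0_draws_area_year(samples, config)
    return _summarize(draws, samples.area_ids, "area", samples.years, samples.sex)


def decile_year_e0(samples: PosteriorSamples, data: MortalityDataset,
                   config: AbridgedLifeTableConfig) -> pd.DataFrame:
    """Posterior mean and 95% credible interval of e0 per decile-year."""
    draws = e0_draws_decile_year(samples, data, config)
    labels = list(range(1, draws.shape[1] + 1))
    return _summarize(draws, labels, "decile", samples.years, samples.sex)


def e0_gap(e0_draws: np.ndarray, years: list[int], period_a, period_b,
           labels: list, unit_name: str = "unit") -> pd.DataFrame:
    """Life-expectancy gap between two periods, in days, with 95% intervals.

    The gap is computed per posterior draw as (mean e0 over period_b - mean
    e0 over period_a) * 365.25 and summarized afterwards, so the interval
    reflects the joint posterior of both periods.
    """
    period_a, period_b = list(period_a), list(period_b)
    if not period_a or not period_b:
        raise ValueError("periods must be non-empty")
    idx = {y: t for t, y in enumerate(years)}
    missing = [y for y in period_a + period_b if y not in idx]
    if missing:
        raise ValueError(f"period years outside the series: {missing}")
    ta = [idx[y] for y in period_a]
    tb = [idx[y] for y in period_b]
    gap = (e0_draws[..., tb].mean(axis=-1) - e0_draws[..., ta].mean(axis=-1))
    gap_days = gap * DAYS_PER_YEAR                        # (S, U)
    rows = []
    for u, lab in enumerate(labels):
        rows.append({
            unit_name: lab,
            "gap_days_mean": float(gap_days[:, u].mean()),
            "gap_days_low": float(np.quantile(gap_days[:, u], 0.025)),
            "gap_days_high": float(np.quantile(gap_days[:, u], 0.975)),
        })
    return pd.DataFrame(rows)
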