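"""Abridged life-table life expectancy at birth (Chiang method).

The estimator assumes a constant probability of dying within each age
interval.  With intervals (a_{t-1}, a_t), survival fractions p_t, death
fractions d_t, and m_t the mean years lived within the interval by those who
die in it,

    LEB = sum_t [ (a_t - a_{t-1}) p_t + m_t d_t ].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LifeTable", "chiang_leb", "ons_age_breaks"]


class LifeTableError(ValueError):
    pass


def ons_age_breaks() -> np.ndarray:
    """Standard abridged layout: under-1, 1-4, then 5-year bands to 90 (T=19)."""
    return np.concatenate([[0.0, 1.0], np.arange(5.0, 95.0, 5.0)])


@dataclass
class LifeTable:
    """Abridged life table in fraction-of-birth-cohort form.

    age_breaks : increasing ages a_0 < a_1 < ... < a_T (years), T >= 1
    survive_frac : p_t, fraction of the cohort alive throughout interval t
    die_frac : d_t, fraction of the cohort dying within interval t
    mean_years_lived : m_t, average years lived within interval t by those
        dying in it
    """

    age_breaks: np.ndarray
    survive_frac: np.ndarray
    die_frac: np.ndarray
    mean_years_lived: np.ndarray

    def __post_init__(self) -> None:
        self.age_breaks = np.asarray(self.age_breaks, dtype=float)
        self.survive_frac = np.asarray(self.survive_frac, dtype=float)
        self.die_frac = np.asarray(self.die_frac, dtype=float)
        self.mean_years_lived = np.asarray(self.mean_years_lived, dtype=float)
        T = len(self.age_breaks) - 1
        if T < 1:
            raise LifeTableError("need at least one age interval")
        if np.any(np.diff(self.age_breaks) <= 0):
            raise LifeTableError("age breaks must be strictly increasing")
        for name, arr in (
            ("survive_frac", self.survive_frac),
            ("die_frac", self.die_frac),
            ("mean_years_lived", self.mean_years_lived),
        ):
            if arr.shape != (T,):
                raise LifeTableError(f"{name} must have length {T}")
        if np.any(self.survive_frac < 0) or np.any(self.die_frac < 0):
            raise LifeTableError("fractions must be non-negative")
        total = self.survive_frac + self.die_frac
        if np.any(total > 1 + 1e-12) or np.any(total < -1e-12):
            bad = int(np.argmax((total > 1 + 1e-12) | (total < 0)))
            raise LifeTableError(
                f"p_t + d_t = {total[bad]:.4f} outside [0, 1] in interval {bad}"
            )
        if np.any(self.mean_years_lived < 0):
            raise LifeTableError("mean years lived must be non-negative")


def chiang_leb(table: LifeTable) -> float:
    """Life expectancy at birth from an abridged life table (years)."""
    widths = np.diff(table.age_breaks)
    return float(
        np.sum(widths * table.survive_frac + table.mean_years_lived * table.die_frac)
    )
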