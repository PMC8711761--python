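"""Age-indexed background mortality.

The base-case model needs an all-cause annual death probability by single
year of age. A synthetic Gompertz life table is bundled as the default
fixture: the hazard grows geometrically with age,

    q(x) = 1 - exp(-(B / ln c) * c**x * (c - 1)),

with defaults calibrated so that remaining life expectancy at age 62 is
about 21 years, matching a recent US all-population table. An exact
published table can be substituted from a two-column CSV (age, q_annual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "make_life_table", "background_death_prob"]

GOMPERTZ_B_DEFAULT = 4.0266e-05
GOMPERTZ_C_DEFAULT = 1.094


@dataclass
class LifeTable:
    """Annual death probability per single year of age (0..max age)."""

    ages: np.ndarray
    q_annual: np.ndarray
    gompertz: dict | None = None  # provenance when Gompertz-generated

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.q_annual = np.asarray(self.q_annual, dtype=float)
        if len(self.ages) != len(self.q_annual):
            raise ValueError("ages and q_annual must align")
        if np.any((self.q_annual <= 0) | (self.q_annual >= 1)):
            raise ValueError("annual death probabilities must lie in (0, 1)")

    def annual_q(self, age):
        """Annual death probability at (possibly fractional) age.

        Ages beyond the table range use the terminal row.
        """
        idx = np.clip(np.floor(age).astype(int) - self.ages[0], 0, len(self.ages) - 1)
        out = self.q_annual[idx]
        return float(out) if np.ndim(out) == 0 else out

    def life_expectancy(self, age: int, max_age: int = 120) -> float:
        """Remaining life expectancy by discrete summation of survivorship."""
        e, lx = 0.0, 1.0
        for a in range(int(age), max_age + 1):
            q = self.annual_q(a)
            e += lx * (1.0 - q / 2.0)  # half-year credit in the year of death
            lx *= 1.0 - q
        return e

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["q_annual"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "q_annual": self.q_annual}).to_csv(
            path, index=False
        )


def make_life_table(
    B: float = GOMPERTZ_B_DEFAULT,
    c: float = GOMPERTZ_C_DEFAULT,
    max_age: int = 100,
) -> LifeTable:
    """Generate a Gompertz life table fixture for ages 0..``max_age``."""
    if not B > 0:
        raise ValueError("B must be positive")
    if not c > 1:
        raise ValueError("c must exceed 1")
    ages = np.arange(0, max_age + 1)
    q = 1.0 - np.exp(-(B / np.log(c)) * c**ages * (c - 1.0))
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    return LifeTable(ages, q, gompertz={"B": B, "c": c})


def background_death_prob(age, life_table: LifeTable, delta_months: float):
    """Per-cycle background death probability from the annual one.

    Annual probabilities are rescaled under a constant hazard within the
    year: ``1 - (1 - q_annual)**(delta_years)``.
    """
    if delta_months <= 0:
        raise ValueError("delta must be positive")
    q = life_table.annual_q(age)
    out = 1.0 - (1.0 - q) ** (delta_months / 12.0)
    return float(out) if np.ndim(out) == 0 else out
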