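"""Association test between gene presence and a species trait.

A 2x2 chi-squared test (Yates continuity correction on by default,
matching R's ``chisq.test`` for 2x2 tables) of gene-family presence
against reproduction mode (sexual vs parthenogenetic), optionally within
one clade.  The p-value is the upper tail of the chi-square distribution
with 1 degree of freedom, evaluated through the regularized incomplete
gamma function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaincc

from .profiling import PresenceMatrix

__all__ = ["ContingencyTable", "chi_squared_test", "presence_by_trait"]


@dataclass
class ContingencyTable:
    """2x2 observed counts; rows = {present, absent}, cols = trait levels."""

    observed: np.ndarray
    row_labels: tuple[str, str] = ("present", "absent")
    col_labels: tuple[str, str] = ("sexual", "parthenogenetic")
    excluded: int = 0  # species dropped for unknown trait values

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (self.observed < 0).any():
            raise ValueError("counts must be non-negative")
        if self.observed.sum() <= 0:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def n(self) -> float:
        return float(self.observed.sum())

    @property
    def expected(self) -> np.ndarray:
        rows = self.observed.sum(axis=1, keepdims=True)
        cols = self.observed.sum(axis=0, keepdims=True)
        return rows @ cols / self.n


def chi_squared_test(table: ContingencyTable, yates: bool = True) -> tuple[float, int, float]:
    """Chi-squared test of independence for a 2x2 table.

    Returns ``(statistic, df=1, p_value)`` with
    ``X^2 = sum((|O - E| - c)^2 / E)``, c = 0.5 under the Yates
    continuity correction (capped at |O - E| so the correction can never
    push a deviation past zero), else c = 0.  The upper-tail p-value is
    ``Q(1/2, X^2/2)``, the regularized upper incomplete gamma function.
    Zero expected counts are an error (an exact test would be required).
    """
    O = table.observed
    E = table.expected
    if (E <= 0).any():
        raise ValueError("zero expected count: chi-squared invalid, use an exact test")
    dev = np.abs(O - E)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / E).sum())
    p = float(gammaincc(0.5, stat / 2.0))
    return stat, 1, p


def presence_by_trait(
    matrix: PresenceMatrix,
    family: str = "GH45",
    clade: str | None = None,
) -> ContingencyTable:
    """Cross-tabulate presence (count >= 1) against reproduction mode.

    Species with unknown reproduction mode are excluded and reported in
    ``excluded``; an optional clade filter restricts the cohort first.
    """
    present = matrix.presence(family)
    obs = np.zeros((2, 2))
    excluded = 0
    n_used = 0
    for sp in matrix.species():
        meta = matrix.meta.get(sp)
        if meta is None:
            excluded += 1
            continue
        if clade is not None and meta.clade != clade:
            continue
        if meta.reproduction_mode == "sexual":
            col = 0
        elif meta.reproduction_mode == "parthenogenetic":
            col = 1
        else:
            excluded += 1
            continue
        row = 0 if present[sp] else 1
        obs[row, col] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no species left after filtering")
    return ContingencyTable(observed=obs, excluded=excluded)
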