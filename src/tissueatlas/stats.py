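"""Shared small statistical containers and helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class ChiSquareResult:
    """Result of a chi-squared test over labelled categories.

    ``observed`` and ``expected`` are aligned with ``categories``;
    ``residuals`` are the standardized residuals (O - E) / sqrt(E), whose
    sign gives the direction of departure per category.
    """

    statistic: float
    df: int
    p_value: float
    categories: tuple = ()
    observed: np.ndarray = field(default_factory=lambda: np.array([]))
    expected: np.ndarray = field(default_factory=lambda: np.array([]))
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    method: str = "chi-squared"

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.observed.size and self.expected.size:
            if abs(self.observed.sum() - self.expected.sum()) > 1e-9 * max(
                1.0, self.observed.sum()
            ):
                raise ValueError("observed and expected totals disagree")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "categories": list(self.categories),
            "observed": self.observed.tolist(),
            "expected": self.expected.tolist(),
            "residuals": self.residuals.tolist(),
            "method": self.method,
        }


def goodness_of_fit(observed, expected, categories=(), method="chi-squared") -> ChiSquareResult:
    """Pearson goodness-of-fit chi-square with df = k - 1, no continuity correction."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have the same shape")
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    stat = float(np.sum((observed - expected) ** 2 / expected))
    df = observed.size - 1
    p = float(sps.chi2.sf(stat, df))
    resid = (observed - expected) / np.sqrt(expected)
    return ChiSquareResult(stat, df, p, tuple(categories), observed, expected, resid, method)


def two_by_two_chi2(table) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 contingency table (df = 1, no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty margin")
    stat, p, df, expected = sps.chi2_contingency(table, correction=False)
    resid = (table - expected) / np.sqrt(expected)
    return ChiSquareResult(
        float(stat),
        int(df),
        float(p),
        ("r0c0", "r0c1", "r1c0", "r1c1"),
        table.ravel(),
        expected.ravel(),
        resid.ravel(),
        "chi-squared (2x2)",
    )
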