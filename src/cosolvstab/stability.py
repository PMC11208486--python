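"""Downstream stability comparisons.

Builds on fitted melting temperatures and half-unfolding concentrations:
delta-Tm tables, stability rankings by alternative measures (and how much
they disagree), operating windows in the (temperature, co-solvent
concentration) plane, and Pearson correlation between activity- and
unfolding-derived parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StabilityTable",
    "OperatingWindow",
    "RankedEnzyme",
    "delta_tm",
    "rank_enzymes",
    "rank_divergence",
    "operating_window_contains",
    "pearson",
    "mean_sem",
    "BoundaryTmError",
]


class BoundaryTmError(ValueError):
    """A boundary-flagged Tm (e.g. '> 90 °C') cannot enter numeric analysis."""


def delta_tm(tm_with_solvent: float, tm_native: float) -> tuple[float, float]:
    """Change of melting temperature and its normalised variant.

    Returns (tm_with_solvent - tm_native, delta / tm_native). The relative
    form lies in [-1, 0] for destabilising co-solvents; a positive delta
    (stabilisation) is permitted but flagged with a warning. Boundary Tm
    results (inequalities such as "> 90 °C") must be excluded upstream.
    """
    for v in (tm_with_solvent, tm_native):
        if isinstance(v, str):
            raise BoundaryTmError(
                f"boundary-flagged Tm {v!r}: exclude boundary results before delta_tm"
            )
        if not math.isfinite(v):
            raise ValueError("Tm values must be finite")
    d = tm_with_solvent - tm_native
    rel = d / tm_native
    if d > 0:
        warnings.warn(
            f"positive delta Tm ({d:+.2f} °C): stabilisation, outside the "
            "expected destabilisation range",
            stacklevel=2,
        )
    return d, rel


@dataclass
class StabilityTable:
    """Per-enzyme stability measures; missing entries are explicit.

    ``measures`` maps measure name -> {enzyme -> value}; an enzyme absent
    from a measure's mapping simply lacks that measurement (never a silent
    zero).
    """

    measures: dict[str, dict[str, float]] = field(default_factory=dict)

    def set(self, enzyme: str, measure: str, value: float) -> None:
        self.measures.setdefault(measure, {})[enzyme] = float(value)

    def get(self, enzyme: str, measure: str) -> float | None:
        return self.measures.get(measure, {}).get(enzyme)

    @property
    def enzymes(self) -> list[str]:
        names: list[str] = []
        for m in self.measures.values():
            for e in m:
                if e not in names:
                    names.append(e)
        return names

    @property
    def measure_names(self) -> list[str]:
        return list(self.measures)


@dataclass(frozen=True)
class RankedEnzyme:
    enzyme: str
    value: float
    rank: float  # average rank across ties
    symbols: str  # "+ "-encoding; most stable of n enzymes gets n plusses


def rank_enzymes(table: StabilityTable, measure: str) -> tuple[list[RankedEnzyme], list[str]]:
    """Rank enzymes by one stability measure, most stable first.

    Larger values rank better (rank 1). Ties receive the average rank; the
    symbol string uses the competition (minimum) rank so tied enzymes share
    an integer "+" count: the best of n enzymes shows n plusses, the next
    n-1, and so on. Enzymes missing the measure are returned separately,
    unranked.
    """
    if measure not in table.measures:
        raise KeyError(
            f"unknown measure {measure!r}; available: {table.measure_names}"
        )
    present = table.measures[measure]
    if len(present) < 2:
        raise ValueError(f"measure {measure!r} present for < 2 enzymes")
    enzymes = list(present)
    values = np.array([present[e] for e in enzymes], dtype=float)
    avg_rank = stats.rankdata(-values, method="average")
    min_rank = stats.rankdata(-values, method="min")
    n = len(enzymes)
    ranked = [
        RankedEnzyme(
            enzyme=e,
            value=float(v),
            rank=float(ar),
            symbols=" ".join("+" * int(n - mr + 1)),
        )
        for e, v, ar, mr in zip(enzymes, values, avg_rank, min_rank)
    ]
    ranked.sort(key=lambda r: (r.rank, r.enzyme))
    missing = [e for e in table.enzymes if e not in present]
    return ranked, missing


def rank_divergence(
    table: StabilityTable, measure_a: str, measure_b: str
) -> tuple[dict[str, tuple[float, float, float]], float | None]:
    """How two stability measures reorder the same enzymes.

    For each enzyme present under both measures: (rank_a, rank_b,
    rank_a - rank_b). Also returns the Spearman rank correlation of the
    two orders as a supporting agreement statistic, or None when fewer
    than 3 enzymes are shared.
    """
    ranked_a, _ = rank_enzymes(table, measure_a)
    ranked_b, _ = rank_enzymes(table, measure_b)
    ra = {r.enzyme: r.rank for r in ranked_a}
    rb = {r.enzyme: r.rank for r in ranked_b}
    shared = [e for e in ra if e in rb]
    if not shared:
        raise ValueError("no enzymes shared between the two measures")
    shifts = {e: (ra[e], rb[e], ra[e] - rb[e]) for e in shared}
    if len(shared) < 3:
        return shifts, None
    rho = float(stats.spearmanr([ra[e] for e in shared], [rb[e] for e in shared]).statistic)
    return shifts, rho


@dataclass(frozen=True)
class OperatingWindow:
    """Boundary of usable (temperature, co-solvent) conditions for an enzyme.

    The boundary is the half-unfolding concentration as a function of
    temperature; conditions strictly below the interpolated curve are
    considered inside the window.
    """

    enzyme: str
    solvent: str
    boundary: tuple[tuple[float, float], ...]  # sorted (temperature_C, c_u50)

    def __post_init__(self) -> None:
        b = tuple(sorted((float(t), float(c)) for t, c in self.boundary))
        object.__setattr__(self, "boundary", b)
        if len(b) < 2:
            raise ValueError("a window boundary needs >= 2 points")
        temps = [t for t, _ in b]
        if len(set(temps)) != len(temps):
            raise ValueError("boundary temperatures must be distinct")


def operating_window_contains(
    window: OperatingWindow,
    temperature_c: float,
    c_solv: float,
    clamp: bool = False,
) -> tuple[bool, float]:
    """Is a (temperature, concentration) condition inside the window?

    The threshold concentration at the query temperature is linearly
    interpolated along the boundary; the condition is inside iff
    c_solv < threshold (strict: a point exactly on the curve is outside).
    Returns (inside, margin) with margin = threshold - c_solv. Queries
    outside the boundary's temperature span raise unless ``clamp`` holds
    the threshold at the nearest boundary point.
    """
    temps = np.array([t for t, _ in window.boundary])
    concs = np.array([c for _, c in window.boundary])
    if not clamp and not (temps[0] <= temperature_c <= temps[-1]):
        raise ValueError(
            f"temperature {temperature_c} °C outside boundary span "
            f"[{temps[0]}, {temps[-1]}] (pass clamp=True to clamp)"
        )
    threshold = float(np.interp(temperature_c, temps, concs))
    margin = threshold - c_solv
    return (c_solv < threshold), margin


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Pearson product-moment correlation with pairwise missing handling.

    Pairs where either member is NaN are dropped; the count of pairs used
    is returned alongside the coefficient. Requires >= 3 complete pairs and
    nonzero variance in both series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    r = float(stats.pearsonr(x, y).statistic)
    return r, n


def mean_sem(replicates: Sequence[float]) -> tuple[float, float | None]:
    """Mean and standard error of the mean (sample sd / sqrt(n)).

    For a single replicate the SEM is undefined and returned as None.
    """
    vals = np.asarray(replicates, dtype=float)
    if vals.size == 0:
        raise ValueError("empty replicate series")
    mean = float(vals.mean())
    if vals.size == 1:
        return mean, None
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return mean, sem
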