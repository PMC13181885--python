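"""Soil quality index (SQI), ecological multifunctionality (EMF) and
nitrogen-use-efficiency indices.

SQI uses the total-dataset method: each indicator x is min-max scored over
a pool of samples,

    S = (x - L) / (H - L)          (more is better)
    S = (H - x) / (H - L)          (less is better)

with H and L the pool maximum and minimum, and the scores combined by the
radar-chart area formula

    SQI = 0.5 * sum_i S_i^2 * sin(2*pi/n)

for n indicators.  The formula is the area of the polygon whose spokes are
the scores, so it degenerates for n <= 2 (sin(2*pi/n) <= 0) and is bounded
by 0.5 * n * sin(2*pi/n).

EMF is the averaged z-score of a set of soil functions (six enzyme
activities by default): each function is standardized over a pool (per
year by default — the published per-year treatment means of EMF sum to
zero, which pins down that convention) and the z-scores are averaged per
sample.

Nitrogen partial factor productivity and agronomic efficiency are

    PFP_N = Y_T / F_N        AE_N = (Y_T - Y_0) / F_N

with Y_T the fertilized grain yield, Y_0 the unfertilized-control yield
and F_N the N application rate (all kg ha^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import table1
from .io import SoilSampleTable


class DegenerateFormulaError(ValueError):
    """The SQI area formula is undefined for fewer than 3 indicators."""


@dataclass
class IndicatorSpec:
    """Ordered SQI indicators with scoring directions and pooling rule.

    ``pool`` chooses the sample set over which H and L are taken:
    ``per_year`` (default) scores each year separately, ``global`` pools
    all samples.  All defaults are ``more_is_better`` — including pH,
    whose positive contribution is required to reproduce the published
    control-treatment SQI on this alkaline soil.
    """

    indicators: tuple[str, ...] = table1.SQI_INDICATORS
    directions: dict = field(default_factory=dict)
    pool: str = "per_year"
    constant_policy: str = "half"  # 'half' -> score 0.5, 'error' -> raise

    def __post_init__(self) -> None:
        if len(self.indicators) < 3:
            raise DegenerateFormulaError(
                "SQI needs >= 3 indicators: the polygon-area formula is "
                f"degenerate for n = {len(self.indicators)} "
                "(sin(2*pi/n) <= 0)")
        if self.pool not in ("per_year", "global"):
            raise ValueError(f"unknown pool {self.pool!r}")
        for name, d in self.directions.items():
            if d not in ("more_is_better", "less_is_better"):
                raise ValueError(f"unknown direction {d!r} for {name!r}")

    def direction(self, indicator: str) -> str:
        return self.directions.get(indicator, "more_is_better")


@dataclass
class EMFSpec:
    """Functions and pooling for ecological multifunctionality."""

    functions: tuple[str, ...] = table1.EMF_FUNCTIONS
    pool: str = "per_year"

    def __post_init__(self) -> None:
        if len(self.functions) < 2:
            raise ValueError("EMF needs >= 2 functions")
        if self.pool not in ("per_year", "global"):
            raise ValueError(f"unknown pool {self.pool!r}")


def minmax_score(values, direction: str = "more_is_better",
                 constant_policy: str = "half") -> np.ndarray:
    """Linear 0-1 score of ``values`` over their own pool.

    A constant pool (H == L) leaves the score undefined; by default every
    sample gets 0.5 with a warning, or set ``constant_policy='error'``.
    """
    x = np.asarray(values, dtype=float)
    H, L = x.max(), x.min()
    if H == L:
        if constant_policy == "error":
            raise ValueError("constant indicator: H == L over the pool; "
                             "drop it or score it 0.5")
        warnings.warn("constant indicator scored 0.5 for all samples",
                      stacklevel=2)
        return np.full_like(x, 0.5)
    if direction == "more_is_better":
        return (x - L) / (H - L)
    if direction == "less_is_better":
        return (H - x) / (H - L)
    raise ValueError(f"unknown direction {direction!r}")


def score_indicators(table: SoilSampleTable,
                     spec: IndicatorSpec) -> pd.DataFrame:
    """Per-sample min-max scores for every indicator in ``spec`` order.

    Returns a frame aligned to ``table.data`` rows with one column per
    indicator, scores in [0, 1].
    """
    missing = [v for v in spec.indicators if v not in table.variables]
    if missing:
        raise KeyError(f"indicators not in table: {missing}")
    df = table.data
    out = pd.DataFrame(index=df.index, columns=list(spec.indicators),
                       dtype=float)
    pools = [df.index] if spec.pool == "global" else [
        df.index[df["year"] == y] for y in sorted(df["year"].unique())]
    for idx in pools:
        for ind in spec.indicators:
            out.loc[idx, ind] = minmax_score(
                df.loc[idx, ind].to_numpy(), spec.direction(ind),
                spec.constant_policy)
    return out


def compute_sqi(table: SoilSampleTable,
                spec: IndicatorSpec | None = None) -> pd.Series:
    """Per-sample SQI = 0.5 * sum(S_i^2) * sin(2*pi/n)."""
    spec = spec or IndicatorSpec()
    scores = score_indicators(table, spec)
    n = len(spec.indicators)
    sqi = 0.5 * (scores ** 2).sum(axis=1) * np.sin(2 * np.pi / n)
    return pd.Series(sqi, index=table.data.index, name="SQI")


def sqi_upper_bound(n: int) -> float:
    """Maximum attainable SQI for n indicators (all scores at 1)."""
    if n < 3:
        raise DegenerateFormulaError("SQI undefined for n < 3")
    return 0.5 * n * np.sin(2 * np.pi / n)


def compute_emf(table: SoilSampleTable,
                spec: EMFSpec | None = None) -> pd.Series:
    """Per-sample EMF as the mean of per-function z-scores.

    z-scores use the sample SD (ddof 1) over the standardization pool;
    functions with zero pool variance are dropped with a warning.  Within
    each pool the returned EMF values average to zero by construction.
    """
    spec = spec or EMFSpec()
    missing = [f for f in spec.functions if f not in table.variables]
    if missing:
        raise KeyError(f"functions not in table: {missing}")
    df = table.data
    emf = pd.Series(np.nan, index=df.index, name="EMF")
    pools = [df.index] if spec.pool == "global" else [
        df.index[df["year"] == y] for y in sorted(df["year"].unique())]
    for idx in pools:
        zcols = []
        for fn in spec.functions:
            v = df.loc[idx, fn].to_numpy(float)
            sd = v.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                warnings.warn(f"function {fn!r} has zero variance in its "
                              "pool; dropped from EMF", stacklevel=2)
                continue
            zcols.append((v - v.mean()) / sd)
        if not zcols:
            raise ValueError("no function with nonzero variance in pool")
        emf.loc[idx] = np.mean(zcols, axis=0)
    return emf


def compute_pfp(y_t, f_n: float = 225.0):
    """N partial factor productivity, kg grain per kg applied N."""
    if f_n <= 0:
        raise ValueError("N rate must be positive")
    y = np.asarray(y_t, dtype=float)
    if (y < 0).any():
        raise ValueError("yield must be non-negative")
    return y / f_n


def compute_aen(y_t, y_0, f_n: float = 225.0):
    """N agronomic efficiency, kg grain gained over the unfertilized
    control per kg applied N.  May be negative."""
    if f_n <= 0:
        raise ValueError("N rate must be positive")
    return (np.asarray(y_t, dtype=float) - np.asarray(y_0, dtype=float)) / f_n


def index_summary(table: SoilSampleTable,
                  indicator_spec: IndicatorSpec | None = None,
                  emf_spec: EMFSpec | None = None) -> pd.DataFrame:
    """SQI and EMF per sample plus group mean +/- SE per (treatment, year)."""
    sqi = compute_sqi(table, indicator_spec)
    emf = compute_emf(table, emf_spec)
    per_sample = table.data[["treatment", "year", "replicate"]].copy()
    per_sample["SQI"] = sqi
    per_sample["EMF"] = emf
    return per_sample
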