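"""Dot-blot quantification statistics.

Each spot carries a glycan-probe signal (lectin or anti-HRP) and an anti-Chp
signal for the same purified Chaoptin sample.  The informative quantity is
the probe/Chp ratio; it is log-transformed (natural log) so that blot-to-blot
multiplicative loading differences become additive offsets that cancel in
the ratio.  Hit strength is the z-score of the log ratio against the
GFP-knockdown control distribution; reproducibility and secondary validation
use two-sided pooled-variance Student's t-tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    BelowDetectionError,
    DegenerateControlsError,
    DegenerateVarianceError,
    InsufficientControlsError,
)

#: Probes measured per line; antiChp is the loading reference, the other
#: five are the glycan probes used for hit calling.
PROBES = ("antiChp", "antiHRP", "WGA", "ConA", "LCA", "DSA")
GLYCAN_PROBES = ("antiHRP", "WGA", "ConA", "LCA", "DSA")

CONTROL_GENE = "control"

SPOT_COLUMNS = ["line_id", "gene_id", "probe", "probe_signal", "chp_signal", "replicate", "blot_id"]


@dataclass(frozen=True)
class BlotSpot:
    """A single quantified dot-blot spot."""

    line_id: str
    probe: str
    probe_signal: float
    chp_signal: float
    replicate: int = 1
    blot_id: str = ""

    def __post_init__(self) -> None:
        if self.probe not in PROBES:
            raise ValueError(f"unknown probe {self.probe!r}; expected one of {PROBES}")
        if self.probe_signal < 0:
            raise ValueError(f"negative probe_signal for line {self.line_id!r}")


@dataclass(frozen=True)
class NormalizedMeasure:
    """Natural-log probe/Chp ratio for one non-excluded spot."""

    line_id: str
    probe: str
    L: float
    replicate: int = 1


@dataclass(frozen=True)
class ControlStats:
    """Per-probe control mean, sample sd (n-1), and count."""

    mu: float
    sigma: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class LinearityFit:
    """Log-log OLS of intensity on relative amount; slope 1 = linear range."""

    slope: float
    intercept: float
    r_squared: float


def normalize_spot(spot: BlotSpot, chp_floor: float = 0.0) -> NormalizedMeasure:
    """L = ln(probe_signal / chp_signal); excludes below-detection spots."""
    if spot.chp_signal <= chp_floor:
        raise BelowDetectionError(
            f"line {spot.line_id!r} {spot.probe}: chp_signal {spot.chp_signal} "
            f"at or below floor {chp_floor}"
        )
    if spot.probe_signal <= 0:
        raise BelowDetectionError(
            f"line {spot.line_id!r} {spot.probe}: probe signal below detection"
        )
    return NormalizedMeasure(
        spot.line_id, spot.probe, math.log(spot.probe_signal / spot.chp_signal), spot.replicate
    )


def normalize_table(df: pd.DataFrame, chp_floor: float = 0.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized :func:`normalize_spot` over a spot table.

    Returns (normalized, excluded); excluded rows carry an ``exclude_reason``.
    """
    df = df.copy()
    bad_chp = df["chp_signal"] <= chp_floor
    bad_probe = df["probe_signal"] <= 0
    excluded = df[bad_chp | bad_probe].copy()
    excluded["exclude_reason"] = np.where(
        bad_chp[bad_chp | bad_probe], "chp_below_floor", "probe_below_detection"
    )
    kept = df[~(bad_chp | bad_probe)].copy()
    kept["L"] = np.log(kept["probe_signal"] / kept["chp_signal"])
    return kept, excluded


def aggregate_control_stats(
    controls: Iterable[NormalizedMeasure] | pd.DataFrame,
) -> dict[str, ControlStats]:
    """Per-probe mean and sample standard deviation over control lines."""
    if isinstance(controls, pd.DataFrame):
        groups = {probe: g["L"].to_numpy(float) for probe, g in controls.groupby("probe")}
    else:
        groups = {}
        for m in controls:
            groups.setdefault(m.probe, []).append(m.L)
        groups = {p: np.asarray(v, float) for p, v in groups.items()}
    stats = {}
    for probe, values in sorted(groups.items()):
        if len(values) < 2:
            raise InsufficientControlsError(
                f"probe {probe}: {len(values)} control measure(s), need >= 2"
            )
        sigma = float(np.std(values, ddof=1))
        if sigma == 0.0:
            raise DegenerateControlsError(f"probe {probe}: zero control variance")
        stats[probe] = ControlStats(mu=float(np.mean(values)), sigma=sigma, n=len(values))
    return stats


def compute_z(measure: NormalizedMeasure, stats: Mapping[str, ControlStats]) -> float:
    """z = (L - mu_c) / sigma_c against the control distribution."""
    try:
        cs = stats[measure.probe]
    except KeyError:
        raise KeyError(f"no control statistics for probe {measure.probe!r}") from None
    return (measure.L - cs.mu) / cs.sigma


def z_table(normalized: pd.DataFrame, stats: Mapping[str, ControlStats]) -> pd.DataFrame:
    """Add a z column to a normalized table (controls included for self-checks)."""
    out = normalized.copy()
    mu = out["probe"].map({p: s.mu for p, s in stats.items()})
    sigma = out["probe"].map({p: s.sigma for p, s in stats.items()})
    if mu.isna().any():
        unknown = sorted(out.loc[mu.isna(), "probe"].unique())
        raise KeyError(f"no control statistics for probe(s) {unknown}")
    out["z"] = (out["L"] - mu) / sigma
    return out


def ttest_two_sided(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sided Student's t-test.

    Degenerate zero-variance inputs: equal means give t=0, p=1; unequal
    means raise (the statistic is undefined, not infinite evidence).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 values per group, got {len(a)} and {len(b)}")
    if len(a) == 2 or len(b) == 2:
        warnings.warn("t-test with n=2 in a group has a single degree of freedom "
                      "contribution; interpret p with care", stacklevel=2)
    df = len(a) + len(b) - 2
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if np.mean(a) == np.mean(b):
            return TTestResult(t=0.0, df=df, p=1.0)
        raise DegenerateVarianceError(
            "zero pooled variance with unequal means; t undefined"
        )
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(t), df=df, p=float(p))


def dilution_linearity(
    dilution_factors: Sequence[float], intensities: Sequence[float]
) -> LinearityFit:
    """OLS of ln(intensity) on ln(relative amount) over a dilution series.

    Slope near 1 certifies the quantification range of the blot; a slope
    below 1 indicates saturation at the high end.
    """
    x = np.asarray(dilution_factors, float)
    y = np.asarray(intensities, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired dilution points")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("dilution factors and intensities must be strictly positive")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(ly) == 0.0:
        # constant readout: flat fit, coefficient of determination undefined
        return LinearityFit(slope=0.0, intercept=float(ly[0]), r_squared=float("nan"))
    fit = sps.linregress(lx, ly)
    return LinearityFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
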