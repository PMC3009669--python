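"""Post-screen quantitative analyses: mRNA decay, nuclear export, glycoforms.

Decay: an actinomycin-D chase yields abundances normalized to time 0; under
first-order decay N(t) = exp(-k t), so ln N is fit through the origin and
t1/2 = ln2 / k.

Export: RT-qPCR relative quantities (rpl32-normalized) in nuclear and
cytoplasmic fractions give per-condition nuclear/cytoplasmic ratios R; the
export-block readout is fold = R_kd / R_ctrl.

Glycoforms: N-glycan compositions in M{m}F{f}Gn{g} notation (mannose,
fucose, N-acetylglucosamine counts; a count of 1 omits the digit, zero
counts omit the element).  Difucosylated forms (fuc >= 2) carry both an
alpha1,6- and an alpha1,3-linked core fucose, so the alpha1,3-fucosylated
share of a site is the summed percentage of fuc >= 2 forms.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IncompleteDesignError

DECAY_TIMES_DEFAULT = (0.0, 30.0, 60.0, 90.0)  # minutes after actinomycin D


# ---------------------------------------------------------------------------
# mRNA decay


@dataclass(frozen=True)
class DecaySeries:
    """Abundance time course normalized to t=0 (value[0] == 1)."""

    times: tuple[float, ...]  # minutes, starting at 0, strictly increasing
    values: tuple[float, ...]  # unitless, > 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.values, float)
        if len(t) != len(v) or len(t) < 3:
            raise ValueError("need >= 3 paired time points (t=0 plus >= 2 more)")
        if t[0] != 0.0:
            raise ValueError("series must start at t=0")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("abundances must be strictly positive")
        if abs(v[0] - 1.0) > 1e-9:
            raise ValueError("value at t=0 must equal 1 (normalize first)")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "values", tuple(float(x) for x in v))


@dataclass(frozen=True)
class DecayFit:
    """First-order decay rate k (1/min) and half-life t1/2 = ln2/k (min)."""

    k: float
    t_half: float

    @property
    def non_decaying(self) -> bool:
        return self.k == 0.0


def fit_decay(series: DecaySeries) -> DecayFit:
    """Least-squares fit of ln(value) on time with the intercept fixed at 0.

    The intercept is pinned because values are normalized to t=0; the
    closed-form slope is k = -sum(t*ln v) / sum(t^2) over t > 0.  A positive
    unconstrained slope (apparent growth) is clamped to k = 0 with a warning
    and reported as non-decaying.
    """
    t = np.asarray(series.times[1:], float)
    y = np.log(np.asarray(series.values[1:], float))
    k = float(-(t @ y) / (t @ t))
    if k < 0.0:
        warnings.warn(
            f"apparent negative decay rate ({k:.3g}/min) clamped to 0",
            stacklevel=2,
        )
        k = 0.0
    t_half = math.log(2) / k if k > 0 else math.inf
    return DecayFit(k=k, t_half=t_half)


@dataclass(frozen=True)
class DecayComparison:
    """Difference and bootstrap CI for the ratio of two decay rates."""

    k_a: float
    k_b: float
    k_diff: float
    k_ratio: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_boot: int

    def contains_unity(self) -> bool:
        if self.ci_low is None or self.ci_high is None:
            return math.isclose(self.k_ratio, 1.0)
        return self.ci_low <= 1.0 <= self.ci_high


def _bootstrap_k(series: DecaySeries, fit: DecayFit, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    t = np.asarray(series.times[1:], float)
    y = np.log(np.asarray(series.values[1:], float))
    # inflate residuals by sqrt(n/(n-p)) to undo the downward bias of
    # least-squares residual spread (p = 1 fitted parameter)
    residuals = (y + fit.k * t) * math.sqrt(len(t) / max(len(t) - 1, 1))
    idx = rng.integers(0, len(t), size=(n_boot, len(t)))
    y_boot = -fit.k * t[None, :] + residuals[idx]
    return -(y_boot @ t) / (t @ t)


def compare_decay(
    fit_a: DecayFit,
    fit_b: DecayFit,
    series_a: DecaySeries,
    series_b: DecaySeries,
    n_boot: int = 1000,
    ci: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> DecayComparison:
    """Residual-resampling bootstrap CI for k_a / k_b (seeded, >= 1000 reps).

    With fewer than 3 points beyond t=0 in either series the bootstrap is
    uninformative and only the analytic point estimates are reported.
    """
    ratio = fit_a.k / fit_b.k if fit_b.k > 0 else math.inf
    if len(series_a.times) < 4 or len(series_b.times) < 4:
        return DecayComparison(fit_a.k, fit_b.k, fit_a.k - fit_b.k, ratio, None, None, 0)
    if rng is None:
        rng = np.random.default_rng(0)
    ka = _bootstrap_k(series_a, fit_a, n_boot, rng)
    kb = _bootstrap_k(series_b, fit_b, n_boot, rng)
    with np.errstate(divide="ignore"):
        ratios = np.where(kb != 0, ka / np.where(kb != 0, kb, 1.0), np.inf)
    lo, hi = np.quantile(ratios, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return DecayComparison(
        fit_a.k, fit_b.k, fit_a.k - fit_b.k, ratio, float(lo), float(hi), n_boot
    )


# ---------------------------------------------------------------------------
# Nuclear export


FRACTIONS = ("nuclear", "cytoplasmic")
FRACTIONATION_COLUMNS = ["gene_id", "fraction", "condition", "replicate", "rel_quantity"]


@dataclass(frozen=True)
class ExportEnrichment:
    """Nuclear/cytoplasmic ratios per condition and their fold change."""

    gene_id: str
    r_kd: float
    r_ctrl: float

    @property
    def fold(self) -> float:
        return self.r_kd / self.r_ctrl


def export_enrichment(
    measures: pd.DataFrame,
    gene_id: str,
    kd_condition: str = "kd",
    ctrl_condition: str = "control",
) -> ExportEnrichment:
    """R = mean nuclear / mean cytoplasmic per condition; fold = R_kd / R_ctrl."""
    sub = measures[measures["gene_id"] == gene_id]
    means: dict[tuple[str, str], float] = {}
    for condition in (kd_condition, ctrl_condition):
        for fraction in FRACTIONS:
            cell = sub[(sub["condition"] == condition) & (sub["fraction"] == fraction)]
            if cell.empty:
                raise IncompleteDesignError(
                    f"gene {gene_id!r}: no measurement for "
                    f"condition={condition!r}, fraction={fraction!r}"
                )
            means[(condition, fraction)] = float(cell["rel_quantity"].mean())
    r_kd = means[(kd_condition, "nuclear")] / means[(kd_condition, "cytoplasmic")]
    r_ctrl = means[(ctrl_condition, "nuclear")] / means[(ctrl_condition, "cytoplasmic")]
    return ExportEnrichment(gene_id=gene_id, r_kd=r_kd, r_ctrl=r_ctrl)


def rel_quantity_from_ct(ct_target: float, ct_reference: float) -> float:
    """2^-(dCt) relative quantity assuming perfect amplification efficiency.

    Convenience plumbing for qPCR inputs; the reference is rpl32 by
    convention.
    """
    return 2.0 ** -(ct_target - ct_reference)


# ---------------------------------------------------------------------------
# Glycoform composition


_GLYCO_RE = re.compile(r"^(?:M(?P<m>\d*))?(?:F(?P<f>\d*))?(?:Gn(?P<g>\d*))?$")


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of an N-glycan: mannose, fucose, GlcNAc."""

    man: int = 0
    fuc: int = 0
    glcnac: int = 0

    def __post_init__(self) -> None:
        if min(self.man, self.fuc, self.glcnac) < 0:
            raise ValueError("counts must be non-negative")
        if self.man == self.fuc == self.glcnac == 0:
            raise ValueError("empty composition")

    @property
    def notation(self) -> str:
        parts = []
        for symbol, count in (("M", self.man), ("F", self.fuc), ("Gn", self.glcnac)):
            if count > 0:
                parts.append(symbol if count == 1 else f"{symbol}{count}")
        return "".join(parts)

    @property
    def alpha13_fucosylated(self) -> bool:
        """Difucosylated forms carry alpha1,6 + alpha1,3 core fucose."""
        return self.fuc >= 2


def parse_glycoform(notation: str) -> GlycanComposition:
    """Parse M{m}F{f}Gn{g} notation (canonical order, omitted digit = 1)."""
    if not notation:
        raise ValueError("empty glycoform notation")
    match = _GLYCO_RE.fullmatch(notation)
    if match is None:
        raise ValueError(
            f"unparseable glycoform {notation!r}: expected element codes "
            f"M, F, Gn in that order"
        )

    def count(group: Optional[str]) -> int:
        if group is None:
            return 0
        return int(group) if group else 1

    return GlycanComposition(
        man=count(match.group("m")),
        fuc=count(match.group("f")),
        glcnac=count(match.group("g")),
    )


GLYCOFORM_COLUMNS = ["site", "composition", "condition", "percent"]
ND = "ND"  # not detected


def read_glycoform_table(path, tolerance: float = 1.0, partial: bool = False) -> pd.DataFrame:
    """Read a glycoform percentage table; 'ND' percents become NaN + nd flag.

    Detected percentages must sum to 100 +/- tolerance per (site, condition)
    unless the table is flagged partial.
    """
    df = pd.read_csv(path, sep="\t", dtype={"site": str, "composition": str, "condition": str})
    return validate_glycoform_table(df, tolerance=tolerance, partial=partial)


def validate_glycoform_table(
    df: pd.DataFrame, tolerance: float = 1.0, partial: bool = False
) -> pd.DataFrame:
    df = df.copy()
    df["nd"] = df["percent"].astype(str).str.strip().eq(ND)
    df["percent"] = pd.to_numeric(df["percent"], errors="coerce")
    df.loc[df["nd"], "percent"] = np.nan
    # every composition must parse
    for notation in df["composition"].unique():
        parse_glycoform(str(notation))
    if not partial:
        sums = df.groupby(["site", "condition"])["percent"].sum(min_count=1)
        bad = sums[(sums - 100.0).abs() > tolerance]
        if not bad.empty:
            raise ValueError(
                f"detected percentages do not sum to 100 +/- {tolerance}: "
                f"{bad.to_dict()}"
            )
    return df


@dataclass(frozen=True)
class Alpha13Summary:
    """Summed alpha1,3-fucosylated percent per condition plus per-form deltas."""

    site: str
    percent_by_condition: dict[str, float]
    per_form: pd.DataFrame  # composition, alpha13, percent per condition, delta, nd flags


def alpha13_summary(
    table: pd.DataFrame,
    conditions: Sequence[str],
    site: Optional[str] = None,
) -> Alpha13Summary:
    """Per-condition alpha1,3-fucosylated percentage and per-form changes.

    A form is classed alpha1,3-fucose-bearing iff fuc >= 2.  ND percentages
    enter sums as 0 but keep their flag, so a decrease and a disappearance
    stay distinguishable.  Deltas are relative to the first condition.
    """
    df = table if "nd" in table.columns else validate_glycoform_table(table, partial=True)
    if site is not None:
        df = df[df["site"] == site]
    sites = df["site"].unique()
    if len(sites) != 1:
        raise ValueError(f"expected one site, found {sorted(sites)}; pass site=")
    present = set(df["condition"].unique())
    missing = [c for c in conditions if c not in present]
    if missing:
        raise KeyError(f"condition(s) {missing} absent from table")

    df = df[df["condition"].isin(conditions)]
    filled = df.assign(percent_filled=df["percent"].fillna(0.0))
    alpha13 = {
        comp: parse_glycoform(str(comp)).alpha13_fucosylated
        for comp in filled["composition"].unique()
    }
    filled["alpha13"] = filled["composition"].map(alpha13)

    totals = {
        cond: float(
            filled[(filled["condition"] == cond) & filled["alpha13"]]["percent_filled"].sum()
        )
        for cond in conditions
    }

    wide_pct = filled.pivot_table(
        index="composition", columns="condition", values="percent_filled", aggfunc="first"
    ).reindex(columns=list(conditions))
    wide_nd = filled.pivot_table(
        index="composition", columns="condition", values="nd", aggfunc="first"
    ).reindex(columns=list(conditions)).fillna(False)
    per_form = pd.DataFrame(index=wide_pct.index)
    per_form["alpha13"] = [alpha13[c] for c in per_form.index]
    ref = conditions[0]
    for cond in conditions:
        per_form[f"percent_{cond}"] = wide_pct[cond]
        per_form[f"nd_{cond}"] = wide_nd[cond].astype(bool)
    for cond in conditions[1:]:
        per_form[f"delta_{cond}"] = wide_pct[cond].fillna(0.0) - wide_pct[ref].fillna(0.0)
    per_form = per_form.reset_index()
    return Alpha13Summary(
        site=str(sites[0]), percent_by_condition=totals, per_form=per_form
    )
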