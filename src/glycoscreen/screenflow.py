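"""The screen's decision procedure, from z-scores to validated ranks.

Stages: a gene becomes a *primary candidate* when any glycan probe shows
|z| > 3 in the single primary round; candidates are *reproducible* when an
n=3 repeat round gives a two-sided Student p < 0.005 on an aberrant probe;
validation then assigns exactly one rank per gene:

- ``rank1``   — an independent, non-overlapping secondary dsRNA reproduces
  the defect (p < 0.05, n=2);
- ``rank2``   — no passing secondary test, but the primary construct's
  off-target probability score is below 3 and knockdown of every suspected
  off-target gene shows no glycosylation defect;
- ``excluded`` — a suspected off-target knockdown reproduces the defect
  (the primary hit is attributed to off-target silencing);
- ``candidate_unvalidated`` — reproducible but neither validated nor
  resolvable (high OTPS without rescreens, untestable secondary, ...);
- ``not_hit`` — fails reproducibility.

All thresholds are strict inequalities; boundary values fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .blotstats import GLYCAN_PROBES, ttest_two_sided
from .errors import IntegrityError
from .seqcore import DsRNAConstruct

RANKS = ("rank1", "rank2", "candidate_unvalidated", "not_hit", "excluded")

DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_P_REPRODUCIBLE = 0.005
DEFAULT_P_SECONDARY = 0.05
DEFAULT_OTPS_THRESHOLD = 3


@dataclass
class ScreenCall:
    """Per-gene evidence accumulated across screen stages, plus the rank."""

    gene_id: str
    z_by_probe: dict[str, float] = field(default_factory=dict)
    primary_candidate: bool = False
    reproducible: Optional[bool] = None
    secondary_p: Optional[float] = None
    otps: Optional[int] = None
    offtarget_rescreen: Optional[dict[str, bool]] = None  # suspect -> defect seen
    rank: Optional[str] = None
    rationale: str = ""


@dataclass(frozen=True)
class HrpSpecificityCall:
    """Is the defect restricted to the anti-HRP (alpha1,3-fucose) probe?"""

    gene_id: str
    hrp_aberrant: bool
    other_probes_normal: bool

    @property
    def alpha13_specific(self) -> bool:
        return self.hrp_aberrant and self.other_probes_normal


def aberrant_probes(
    z_by_probe: Mapping[str, float], threshold: float = DEFAULT_Z_THRESHOLD
) -> list[str]:
    """Glycan probes with |z| strictly above the threshold."""
    return [p for p in GLYCAN_PROBES if p in z_by_probe and abs(z_by_probe[p]) > threshold]


def call_primary(
    z_by_probe: Mapping[str, float], threshold: float = DEFAULT_Z_THRESHOLD
) -> bool:
    """Primary candidate iff |z| > threshold on at least one glycan probe.

    Raises KeyError when any glycan probe is missing (incomplete lines are
    flagged upstream, not called).
    """
    missing = [p for p in GLYCAN_PROBES if p not in z_by_probe]
    if missing:
        raise KeyError(f"incomplete z row: missing probe(s) {missing}")
    return len(aberrant_probes(z_by_probe, threshold)) > 0


def call_reproducible(
    kd_by_probe: Mapping[str, Sequence[float]],
    controls_by_probe: Mapping[str, Sequence[float]],
    probes: Sequence[str],
    p_threshold: float = DEFAULT_P_REPRODUCIBLE,
) -> tuple[bool, dict[str, float]]:
    """Repeat-round test: p < threshold on at least one aberrant probe.

    ``probes`` is the list of probes flagged aberrant in the primary round;
    each is tested with a two-sided pooled-variance Student's t against the
    control measures of the same round.
    """
    p_by_probe: dict[str, float] = {}
    for probe in probes:
        result = ttest_two_sided(kd_by_probe[probe], controls_by_probe[probe])
        p_by_probe[probe] = result.p
    reproducible = any(p < p_threshold for p in p_by_probe.values())
    return reproducible, p_by_probe


def validate_secondary(
    primary: DsRNAConstruct,
    secondary: DsRNAConstruct,
    kd_by_probe: Mapping[str, Sequence[float]],
    controls_by_probe: Mapping[str, Sequence[float]],
    probes: Sequence[str],
    p_threshold: float = DEFAULT_P_SECONDARY,
) -> tuple[float, bool]:
    """Independent n=2 retest with a non-overlapping dsRNA.

    Returns (secondary_p, rank1_flag) where secondary_p is the smallest p
    over the tested probes and the flag is p < threshold (strict).
    """
    if primary.overlaps(secondary):
        raise IntegrityError(
            f"secondary construct {secondary.construct_id!r} overlaps the "
            f"primary interval [{primary.start}, {primary.end})"
        )
    _, p_by_probe = call_reproducible(kd_by_probe, controls_by_probe, probes, p_threshold)
    secondary_p = min(p_by_probe.values())
    return secondary_p, secondary_p < p_threshold


def assign_rank(
    call: ScreenCall,
    p_secondary: float = DEFAULT_P_SECONDARY,
    otps_threshold: int = DEFAULT_OTPS_THRESHOLD,
) -> ScreenCall:
    """Apply the validation decision table; total and deterministic.

    Contradictory evidence (rank-2 conditions met *and* a passing secondary
    test) resolves to rank1 — the independent dsRNA is the stronger
    evidence — and the rationale records the conflict.
    """
    if call.reproducible is None:
        raise IntegrityError(f"gene {call.gene_id!r}: reproducibility not set")
    rescreens = call.offtarget_rescreen
    low_otps = call.otps is not None and call.otps < otps_threshold
    rescreens_all_negative = rescreens is not None and not any(rescreens.values())
    rescreen_defect = rescreens is not None and any(rescreens.values())

    if not call.reproducible:
        rank = "not_hit"
        rationale = (
            f"repeat round (n=3) not reproducible at p < {DEFAULT_P_REPRODUCIBLE}"
        )
    elif call.secondary_p is not None and call.secondary_p < p_secondary:
        rank = "rank1"
        rationale = (
            f"independent non-overlapping secondary dsRNA reproduced the "
            f"glycosylation defect: p = {call.secondary_p:.3g} < {p_secondary} (n=2)"
        )
        if low_otps and rescreens_all_negative:
            rationale += "; rank-2 conditions also held (secondary evidence is stronger)"
    elif low_otps and rescreens_all_negative:
        rank = "rank2"
        rationale = (
            f"off-target probability score {call.otps} < {otps_threshold} and "
            f"knockdown of every suspected off-target gene showed no "
            f"glycosylation defect; no passing secondary test recorded"
        )
    elif rescreen_defect:
        rank = "excluded"
        culprits = sorted(g for g, d in (rescreens or {}).items() if d)
        rationale = (
            f"knockdown of suspected off-target gene(s) {', '.join(culprits)} "
            f"reproduced the defect; primary hit attributed to off-target silencing"
        )
    else:
        rank = "candidate_unvalidated"
        reasons = []
        if call.secondary_p is not None:
            reasons.append(f"secondary p = {call.secondary_p:.3g} not < {p_secondary}")
        else:
            reasons.append("no secondary test available")
        if call.otps is None:
            reasons.append("off-target score unavailable")
        elif not low_otps:
            reasons.append(f"off-target score {call.otps} >= {otps_threshold}")
        elif rescreens is None:
            reasons.append("off-target rescreens not performed")
        rationale = "unresolved: " + "; ".join(reasons)

    return replace(call, rank=rank, rationale=rationale)


def classify_hrp_specific(
    gene_id: str,
    z_by_probe: Mapping[str, float],
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> HrpSpecificityCall:
    """Alpha1,3-fucosylation-specific: only the anti-HRP probe is aberrant."""
    missing = [p for p in GLYCAN_PROBES if p not in z_by_probe]
    if missing:
        raise KeyError(f"gene {gene_id!r}: missing probe(s) {missing}")
    hrp_aberrant = abs(z_by_probe["antiHRP"]) > threshold
    others_normal = all(
        abs(z_by_probe[p]) <= threshold for p in GLYCAN_PROBES if p != "antiHRP"
    )
    return HrpSpecificityCall(gene_id, hrp_aberrant, others_normal)
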