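"""Chromatographic metrics and screening-level aggregation.

Implements the primary observables of an enantioseparation experiment —
retention factor k = (tR - t0)/t0, selectivity alpha = k2/k1, resolution
Rs = 2(t2 - t1)/(w1 + w2) and the signed "directed" resolution — plus
screening-table aggregation (success rate, baseline-separation count,
sum-Rs rankings) and exhaustive detection of enantiomer elution order
(EEO) reversals along the backbone / substituent / mobile-phase axes.
Temperature-driven reversals are handled by :mod:`enantiosep.thermo`
(via the isoenantioselective temperature), because a single screening
table holds only one temperature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .dataio import EEO, Analyte, ScreeningTable, SeparationRecord, ValidationError

__all__ = [
    "PeakPair",
    "ScreeningSummary",
    "ReversalEvent",
    "EEOReversalReport",
    "retention_factor",
    "selectivity",
    "resolution_from_peaks",
    "directed_resolution",
    "extraction_rate",
    "screening_summary",
    "detect_eeo_reversals",
]


@dataclass(frozen=True)
class PeakPair:
    """Two peak apexes with baseline widths and the column dead time (min)."""

    t1: float
    t2: float
    w1: float
    w2: float
    t0: float

    def __post_init__(self):
        if self.t0 <= 0:
            raise ValidationError("dead time t0 must be positive")
        if not self.t2 >= self.t1 >= self.t0:
            raise ValidationError("need t2 >= t1 >= t0")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValidationError("peak widths must be positive")


def retention_factor(tR: float, t0: float) -> float:
    """k = (tR - t0)/t0. Raises for a peak eluting before the dead time."""
    if t0 <= 0:
        raise ValueError("dead time t0 must be positive")
    if tR < t0:
        raise ValueError(f"retention time {tR} precedes dead time {t0}")
    return (tR - t0) / t0


def selectivity(k1: float, k2: float) -> float:
    """alpha = k2/k1 for the second- vs first-eluting enantiomer (>= 1)."""
    if k1 <= 0:
        raise ValueError("selectivity undefined for k1 <= 0")
    if k2 < k1:
        raise ValidationError(f"k2 ({k2}) < k1 ({k1})")
    return k2 / k1


def resolution_from_peaks(p: PeakPair) -> float:
    """Rs = 2(t2 - t1)/(w1 + w2); zero exactly at coelution."""
    return 2.0 * (p.t2 - p.t1) / (p.w1 + p.w2)


def directed_resolution(rs: float | None, eeo: EEO) -> float:
    """Sign Rs by elution order: negative when the S enantiomer elutes first.

    Coelution maps to 0.  A resolved pair with unknown EEO cannot be
    signed and is rejected so callers exclude it from signed analyses.
    """
    if eeo is EEO.COELUTION:
        return 0.0
    if rs is None:
        return 0.0
    if eeo is EEO.UNKNOWN:
        raise ValueError("cannot sign a resolved pair with unknown elution order")
    return -rs if eeo is EEO.S_FIRST else +rs


def extraction_rate(collected_mg: float, injected_racemate_mg: float) -> float:
    """Semi-preparative extraction rate in percent.

    A racemate carries each enantiomer at half the injected mass, so the
    rate is collected mass over (injected mass / 2).
    """
    if injected_racemate_mg <= 0:
        raise ValueError("injected mass must be positive")
    return 100.0 * collected_mg / (injected_racemate_mg / 2.0)


@dataclass
class ScreeningSummary:
    n_total: int
    n_separated: int
    success_rate: float  # percent
    n_baseline: int  # Rs strictly above the baseline threshold
    baseline_threshold: float
    sum_rs_by_csp_eluent: dict[tuple[str, str], float]
    sum_rs_by_csp_analyte: dict[tuple[str, str], float]
    max_rs_by_analyte: dict[str, tuple[float, str, str]]  # value, csp, eluent

    def to_json_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_separated": self.n_separated,
            "success_rate_pct": self.success_rate,
            "n_baseline": self.n_baseline,
            "baseline_threshold": self.baseline_threshold,
            "sum_rs_by_csp_eluent": {
                f"{c}|{e}": v for (c, e), v in self.sum_rs_by_csp_eluent.items()
            },
            "sum_rs_by_csp_analyte": {
                f"{c}|{a}": v for (c, a), v in self.sum_rs_by_csp_analyte.items()
            },
            "max_rs_by_analyte": {
                a: {"rs": v, "csp": c, "eluent": e}
                for a, (v, c, e) in self.max_rs_by_analyte.items()
            },
        }


def screening_summary(
    table: ScreeningTable, baseline_threshold: float = 1.5
) -> ScreeningSummary:
    """Aggregate a screening table.

    Separation counts every record with enantiorecognition (non-coelution);
    baseline separations require Rs strictly above ``baseline_threshold``.
    Sum-Rs rankings treat unresolved cells as contributing zero, and the
    per-analyte maximum reports the arg-max system.
    """
    if len(table) == 0:
        raise ValueError("screening table is empty")
    n_total = len(table)
    n_separated = sum(1 for r in table if r.is_separated)
    n_baseline = sum(
        1 for r in table if r.rs is not None and r.rs > baseline_threshold
    )
    sum_ce: dict[tuple[str, str], float] = {}
    sum_ca: dict[tuple[str, str], float] = {}
    max_ra: dict[str, tuple[float, str, str]] = {}
    for r in table:
        rs = r.rs or 0.0
        csp, eluent, analyte = r.key
        sum_ce[(csp, eluent)] = sum_ce.get((csp, eluent), 0.0) + rs
        sum_ca[(csp, analyte)] = sum_ca.get((csp, analyte), 0.0) + rs
        best = max_ra.get(analyte)
        if best is None or rs > best[0]:
            max_ra[analyte] = (rs, csp, eluent)
    return ScreeningSummary(
        n_total=n_total,
        n_separated=n_separated,
        success_rate=100.0 * n_separated / n_total,
        n_baseline=n_baseline,
        baseline_threshold=baseline_threshold,
        sum_rs_by_csp_eluent=sum_ce,
        sum_rs_by_csp_analyte=sum_ca,
        max_rs_by_analyte=max_ra,
    )


@dataclass(frozen=True)
class ReversalEvent:
    analyte: str
    axis: str
    condition_a: tuple[str, str]  # (csp, eluent)
    condition_b: tuple[str, str]
    eeo_a: EEO
    eeo_b: EEO

    def to_json_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "axis": self.axis,
            "condition_a": list(self.condition_a),
            "condition_b": list(self.condition_b),
            "eeo_a": self.eeo_a.to_label(),
            "eeo_b": self.eeo_b.to_label(),
        }


@dataclass
class EEOReversalReport:
    axis: str
    events: list[ReversalEvent] = field(default_factory=list)
    not_assessable: list[dict] = field(default_factory=list)
    warning: str | None = None

    def to_json_dict(self) -> dict:
        return {
            "axis": self.axis,
            "events": [e.to_json_dict() for e in self.events],
            "not_assessable": self.not_assessable,
            "warning": self.warning,
        }


_AXES = ("backbone", "substituent", "mobile_phase")


def detect_eeo_reversals(table: ScreeningTable, axis: str) -> EEOReversalReport:
    """Exhaustively list elution-order reversals along one contrast axis.

    axis="backbone": CSP pairs sharing the selector substituent but
    differing in backbone (amylose vs cellulose), same eluent/analyte.
    axis="substituent": CSP pairs sharing the backbone but differing in
    substituent.  axis="mobile_phase": same CSP, different eluents.
    Contrasts where either side shows coelution are reported as "not
    assessable" rather than as reversals.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
    by_key = {r.key: r for r in table}
    report = EEOReversalReport(axis=axis)

    def assess(a: SeparationRecord, b: SeparationRecord):
        if EEO.COELUTION in (a.eeo, b.eeo) or EEO.UNKNOWN in (a.eeo, b.eeo):
            report.not_assessable.append(
                {
                    "analyte": a.analyte.value,
                    "condition_a": list(a.key[:2]),
                    "condition_b": list(b.key[:2]),
                    "reason": "coelution or unknown EEO on at least one side",
                }
            )
            return
        if a.eeo is not b.eeo:
            report.events.append(
                ReversalEvent(
                    analyte=a.analyte.value,
                    axis=axis,
                    condition_a=a.key[:2],
                    condition_b=b.key[:2],
                    eeo_a=a.eeo,
                    eeo_b=b.eeo,
                )
            )

    csps = sorted({r.system.csp_id for r in table})
    eluents = sorted({r.system.eluent_label for r in table})
    analytes = sorted({r.analyte.value for r in table})
    systems = {r.system.csp_id: r.system for r in table}

    n_contrasts = 0
    if axis in ("backbone", "substituent"):
        for c1, c2 in itertools.combinations(csps, 2):
            s1, s2 = systems[c1], systems[c2]
            if axis == "backbone":
                match = (
                    s1.backbone is not s2.backbone
                    and s1.selector_substituent == s2.selector_substituent
                )
            else:
                match = (
                    s1.backbone is s2.backbone
                    and s1.selector_substituent != s2.selector_substituent
                )
            if not match:
                continue
            for eluent in eluents:
                for analyte in analytes:
                    a = by_key.get((c1, eluent, analyte))
                    b = by_key.get((c2, eluent, analyte))
                    if a is None or b is None:
                        continue
                    n_contrasts += 1
                    assess(a, b)
    else:  # mobile_phase
        for csp in csps:
            for e1, e2 in itertools.combinations(eluents, 2):
                for analyte in analytes:
                    a = by_key.get((csp, e1, analyte))
                    b = by_key.get((csp, e2, analyte))
                    if a is None or b is None:
                        continue
                    n_contrasts += 1
                    assess(a, b)

    if n_contrasts == 0:
        report.warning = f"no valid contrast pairs for axis {axis!r}"
    return report
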