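"""Van 't Hoff thermodynamics of enantioseparation.

Retention in a linear van 't Hoff regime follows

    ln k = -dH/(R T) + dS*/R

where dH is the standard enthalpy of solute transfer to the stationary
phase and dS* = dS + R ln(phi) absorbs the unknown phase ratio phi.
Regressing ln k on 1/T gives dH from the slope and dS* from the
intercept.  For an enantiomer pair the same regression applied to
ln alpha = ln(k2/k1) yields the enantioselective differences ddH and
ddS, from which follow

    ddG(T)  = ddH - T * ddS        (= -R T ln alpha)
    T_iso   = ddH / ddS            (isoenantioselective temperature)
    Q(Tref) = ddH / (Tref * ddS)

At T_iso the enthalpic and entropic contributions cancel, ddG = 0, the
enantiomers co-elute, and the elution order reverses on crossing it.
|Q| > 1 marks enthalpy-controlled separation, |Q| < 1 entropy-controlled;
values near one indicate mixed control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dataio import Analyte, SeparationSystem

__all__ = [
    "R_GAS",
    "VanTHoffSeries",
    "VanTHoffFit",
    "EnantioThermo",
    "fit_vant_hoff",
    "enantio_thermo",
    "predict_temperature_reversal",
]

R_GAS = 8.314  # J/(mol K)

#: default minimum number of distinct temperatures for a fit
MIN_TEMPERATURES = 3

#: ln k vs 1/T linearity QC threshold on |r|
QC_R_THRESHOLD = 0.98

#: half-width of the |Q - 1| band classified as mixed control
MIXED_CONTROL_BAND = 0.05


@dataclass
class VanTHoffSeries:
    """Per-enantiomer (T, k) measurements for one (system, analyte)."""

    points_1: Sequence[tuple[float, float]]  # (T kelvin, k) first enantiomer
    points_2: Sequence[tuple[float, float]]  # second enantiomer
    system: SeparationSystem | None = None
    analyte: Analyte | None = None
    labels: tuple[str, str] = ("R", "S")

    def __post_init__(self):
        for pts in (self.points_1, self.points_2):
            if any(k <= 0 for _, k in pts):
                raise ValueError("all retention factors must be positive")

    def shared_grid(self) -> bool:
        t1 = sorted(T for T, _ in self.points_1)
        t2 = sorted(T for T, _ in self.points_2)
        return len(t1) == len(t2) and all(
            math.isclose(a, b, rel_tol=0, abs_tol=1e-9) for a, b in zip(t1, t2)
        )


@dataclass
class VanTHoffFit:
    """OLS fit of ln k on 1/T with derived transfer thermodynamics."""

    slope: float  # kelvin
    intercept: float  # dimensionless
    dH: float  # J/mol
    dS_star: float  # J/(mol K), phase-ratio-absorbed entropy
    r: float  # Pearson correlation of the regression
    stderr_slope: float
    stderr_intercept: float
    n: int
    qc_pass: bool  # |r| >= QC threshold

    def predict_lnk(self, T: float) -> float:
        return self.slope / T + self.intercept

    def to_json_dict(self) -> dict:
        return {
            "slope_K": self.slope,
            "intercept": self.intercept,
            "dH_J_per_mol": self.dH,
            "dS_star_J_per_molK": self.dS_star,
            "r": self.r,
            "n": self.n,
            "qc_pass": self.qc_pass,
            "units": {"dH": "J/mol", "dS_star": "J/(mol K)", "slope": "K"},
        }


def fit_vant_hoff(
    points: Sequence[tuple[float, float]],
    min_temperatures: int = MIN_TEMPERATURES,
) -> VanTHoffFit:
    """Ordinary least squares of ln k on 1/T.

    dH = -R * slope and dS* = R * intercept.  A QC flag records whether
    |r| reaches the linearity threshold (0.98) typical of well-behaved
    van 't Hoff plots.
    """
    T = np.asarray([p[0] for p in points], dtype=float)
    k = np.asarray([p[1] for p in points], dtype=float)
    if np.any(k <= 0):
        raise ValueError("all retention factors must be positive")
    if len(np.unique(T)) < min_temperatures:
        raise ValueError(
            f"need >= {min_temperatures} distinct temperatures, got {len(np.unique(T))}"
        )
    x = 1.0 / T
    y = np.log(k)
    res = stats.linregress(x, y)
    r = float(res.rvalue) if not math.isnan(res.rvalue) else 1.0
    return VanTHoffFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        dH=-R_GAS * float(res.slope),
        dS_star=R_GAS * float(res.intercept),
        r=r,
        stderr_slope=float(res.stderr),
        stderr_intercept=float(res.intercept_stderr),
        n=len(T),
        qc_pass=abs(r) >= QC_R_THRESHOLD,
    )


@dataclass
class EnantioThermo:
    """Enantioselective thermodynamics derived from the ln alpha regression."""

    ddH: float  # J/mol
    ddS: float  # J/(mol K)
    Tref: float  # kelvin
    ddG_at_Tref: float  # J/mol
    T_iso: float | None  # kelvin; None when ddS == 0
    Q: float | None  # dimensionless at Tref; None when ddS == 0
    control: str  # "enthalpy" | "entropy" | "mixed" | "no_enantiorecognition"
    r: float
    n: int

    def ddG(self, T: float) -> float:
        return self.ddH - T * self.ddS

    def to_json_dict(self) -> dict:
        return {
            "ddH_J_per_mol": self.ddH,
            "ddS_J_per_molK": self.ddS,
            "Tref_K": self.Tref,
            "ddG_at_Tref_J_per_mol": self.ddG_at_Tref,
            "T_iso_K": self.T_iso,
            "Q": self.Q,
            "control": self.control,
            "r": self.r,
            "n": self.n,
            "units": {
                "ddH": "J/mol",
                "ddS": "J/(mol K)",
                "ddG": "J/mol",
                "T_iso": "K",
                "Tref": "K",
            },
        }


def classify_control(Q: float | None, band: float = MIXED_CONTROL_BAND) -> str:
    """Enthalpy vs entropy control from the Q value at the reference T."""
    if Q is None:
        return "no_enantiorecognition"
    if abs(Q - 1.0) <= band:
        return "mixed"
    return "enthalpy" if abs(Q) > 1.0 else "entropy"


def enantio_thermo(
    series: VanTHoffSeries,
    Tref: float = 298.0,
    mixed_band: float = MIXED_CONTROL_BAND,
    min_temperatures: int = MIN_TEMPERATURES,
) -> EnantioThermo:
    """Regress ln alpha on 1/T to obtain ddH, ddS and derived quantities.

    Both enantiomers must share the temperature grid, so that alpha =
    k2/k1 is defined per temperature.  A series that co-elutes at every
    temperature (alpha == 1) yields ddH = ddS = 0 with undefined T_iso,
    flagged as "no enantiorecognition".
    """
    if not series.shared_grid():
        raise ValueError("enantiomer series must share the temperature grid")
    pts1 = sorted(series.points_1)
    pts2 = sorted(series.points_2)
    T = np.asarray([p[0] for p in pts1], dtype=float)
    alpha = np.asarray([p2[1] / p1[1] for p1, p2 in zip(pts1, pts2)], dtype=float)

    if np.allclose(np.log(alpha), 0.0, atol=1e-12):
        return EnantioThermo(
            ddH=0.0,
            ddS=0.0,
            Tref=Tref,
            ddG_at_Tref=0.0,
            T_iso=None,
            Q=None,
            control="no_enantiorecognition",
            r=0.0,
            n=len(T),
        )

    if len(np.unique(T)) < min_temperatures:
        raise ValueError(f"need >= {min_temperatures} distinct temperatures")
    res = stats.linregress(1.0 / T, np.log(alpha))
    ddH = -R_GAS * float(res.slope)
    ddS = R_GAS * float(res.intercept)
    T_iso = ddH / ddS if ddS != 0.0 else None
    Q = ddH / (Tref * ddS) if ddS != 0.0 else None
    return EnantioThermo(
        ddH=ddH,
        ddS=ddS,
        Tref=Tref,
        ddG_at_Tref=ddH - Tref * ddS,
        T_iso=T_iso,
        Q=Q,
        control=classify_control(Q, mixed_band),
        r=float(res.rvalue),
        n=len(T),
    )


def predict_temperature_reversal(
    thermo: EnantioThermo, T_range: tuple[float, float]
) -> tuple[bool, float | None, str]:
    """Flag whether the elution order reverses inside a temperature window.

    Returns ``(flag, T_iso, reason)``; the flag is true iff T_iso lies
    strictly inside ``T_range``, since crossing T_iso flips the sign of
    ln alpha and hence the elution order.
    """
    lo, hi = T_range
    if lo >= hi:
        raise ValueError("T_range must be (low, high) with low < high")
    if thermo.T_iso is None:
        return False, None, "T_iso undefined (ddS = 0 or no enantiorecognition)"
    inside = lo < thermo.T_iso < hi
    reason = (
        "T_iso strictly inside measured range"
        if inside
        else "T_iso outside measured range"
    )
    return inside, thermo.T_iso, reason
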