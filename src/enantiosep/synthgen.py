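"""Synthetic chromatographic data with known ground truth.

Generates the three data shapes the analysis consumes — screening
tables, van 't Hoff temperature series, and hysteresis loops — from
explicit generating parameters, so that every downstream stage can be
checked by parameter recovery.

Retention follows the linear van 't Hoff model
``ln k = -dH/(R T) + dS*/R`` with enantiomer-specific (dH, dS*) and
optional Gaussian noise on the ln k scale (multiplicative on k, matching
the variance stabilization the linear fit assumes).  Peak widths come
from a plate-count model, ``w = 4 tR / sqrt(N)``, so resolution follows
from the standard formula.  Hysteresis loops place a smooth offset
``delta(x)`` between the reverse and forward branches of ln k over the
modifier fraction x, zero at the pure solvents by default (bump shape
``a * (x/100)(1 - x/100)``), with an optional divergence term that grows
toward high MeOH content; per-enantiomer offsets allow planting an
elution-order reversal at a known composition.

All randomness flows from the single config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .dataio import (
    CSP_LIBRARY,
    EEO,
    Analyte,
    ScreeningTable,
    SeparationRecord,
    SeparationSystem,
    celsius_to_kelvin,
)
from .thermo import R_GAS, VanTHoffSeries
from .hysteresis import HysteresisLoop

import pandas as pd

__all__ = [
    "SynthConfig",
    "SynthGroundTruth",
    "gen_vant_hoff_series",
    "gen_screening_table",
    "gen_hysteresis_loop",
    "DEFAULT_TEMPERATURES_C",
]

#: default temperature grid (degC) for thermodynamic series
DEFAULT_TEMPERATURES_C = (10.0, 20.0, 25.0, 30.0, 40.0)


@dataclass(frozen=True)
class SynthConfig:
    """Generating parameters; defaults mirror the screening study design.

    Enthalpies are J/mol, entropies J/(mol K); ``sigma_lnk`` is the
    standard deviation of Gaussian noise added to ln k.  ``plate_number``
    controls peak widths (w = 4 tR / sqrt(N)); dead time ``t0_min`` sets
    an arbitrary time scale (k itself is scale-free).
    """

    seed: int = 0
    n_csps: int = 7
    n_eluents: int = 4
    n_analytes: int = 3
    temperatures_c: Sequence[float] = DEFAULT_TEMPERATURES_C
    screening_temperature_c: float = 20.0
    # ranges for randomized per-(system, analyte, enantiomer) parameters
    dH_range: tuple[float, float] = (-20000.0, -5000.0)  # J/mol
    dS_star_range: tuple[float, float] = (-60.0, -10.0)  # J/(mol K)
    # enantioselectivity draws follow enthalpy-entropy compensation: a
    # second-enantiomer offset ddH with |ddH| in the clear-recognition
    # range below, random sign, and ddS = ddH / T_iso with T_iso drawn
    # from its own range, as observed for compensated chiral systems
    ddH_magnitude_range: tuple[float, float] = (5000.0, 15000.0)  # J/mol
    T_iso_range: tuple[float, float] = (250.0, 450.0)  # kelvin
    plate_number: float = 5000.0
    sigma_lnk: float = 0.01
    missing_rate: float = 0.3  # fraction of cells rendered as coelution
    t0_min: float = 1.0
    # hysteresis loop controls
    compositions: Sequence[float] = tuple(range(100, -10, -10))
    hysteresis_amplitude: float = 0.4  # bump amplitude a in delta(x)
    hysteresis_amplitude_ratio: float = 1.0  # enantiomer-2 amplitude / enantiomer-1
    divergence: float = 0.0  # extra offset growing with MeOH fraction

    def __post_init__(self):
        if self.plate_number <= 0:
            raise ValueError("plate number must be positive")
        if self.sigma_lnk < 0:
            raise ValueError("sigma_lnk must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SynthGroundTruth:
    """The generating parameters plus the exactly-derived target quantities."""

    seed: int
    params: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.params[key]


def _lnk(dH: float, dS_star: float, T: float) -> float:
    return -dH / (R_GAS * T) + dS_star / R_GAS


def _draw_enantioselectivity(
    rng: np.random.Generator, config: SynthConfig
) -> tuple[float, float]:
    """Draw a compensated (ddH, ddS) pair with ddS = ddH / T_iso."""
    sign = 1.0 if rng.uniform() < 0.5 else -1.0
    ddH = sign * rng.uniform(*config.ddH_magnitude_range)
    T_iso = rng.uniform(*config.T_iso_range)
    return ddH, ddH / T_iso


def gen_vant_hoff_series(
    config: SynthConfig,
    dH1: float | None = None,
    dS1: float | None = None,
    dH2: float | None = None,
    dS2: float | None = None,
) -> tuple[VanTHoffSeries, SynthGroundTruth]:
    """One enantiomer pair's (T, k) series on the default temperature grid.

    Parameters may be pinned explicitly; otherwise enantiomer 1 draws
    (dH, dS*) from the configured ranges and enantiomer 2 adds a drawn
    (ddH, ddS).  Ground truth records the exact ddH, ddS, T_iso and Q.
    """
    rng = config.rng()
    if dH1 is None:
        dH1 = rng.uniform(*config.dH_range)
    if dS1 is None:
        dS1 = rng.uniform(*config.dS_star_range)
    if dH2 is None or dS2 is None:
        ddH, ddS = _draw_enantioselectivity(rng, config)
        if dH2 is None:
            dH2 = dH1 + ddH
        if dS2 is None:
            dS2 = dS1 + ddS
    T_grid = [celsius_to_kelvin(t) for t in config.temperatures_c]
    pts1, pts2 = [], []
    for T in T_grid:
        eps1 = rng.normal(0.0, config.sigma_lnk) if config.sigma_lnk else 0.0
        eps2 = rng.normal(0.0, config.sigma_lnk) if config.sigma_lnk else 0.0
        pts1.append((T, math.exp(_lnk(dH1, dS1, T) + eps1)))
        pts2.append((T, math.exp(_lnk(dH2, dS2, T) + eps2)))
    ddH, ddS = dH2 - dH1, dS2 - dS1
    truth = SynthGroundTruth(
        seed=config.seed,
        params={
            "dH1": dH1, "dS1": dS1, "dH2": dH2, "dS2": dS2,
            "ddH": ddH, "ddS": ddS,
            "T_iso": ddH / ddS if ddS != 0 else None,
            "Q_298": ddH / (298.0 * ddS) if ddS != 0 else None,
        },
    )
    return VanTHoffSeries(points_1=pts1, points_2=pts2), truth


def gen_screening_table(config: SynthConfig) -> tuple[ScreeningTable, SynthGroundTruth]:
    """A screening table shaped like the real study (CSPs x eluents x analytes).

    Retention comes from the van 't Hoff model at the screening
    temperature; peak times tR = t0 (1 + k), widths from the plate-count
    model, Rs from the resolution formula, and the elution order from
    the sign of the true ln alpha.  A configured fraction of cells is
    rendered as coelution to emulate the missing-cell pattern of real
    screens.
    """
    rng = config.rng()
    T = celsius_to_kelvin(config.screening_temperature_c)
    library_ids = list(CSP_LIBRARY)
    if config.n_csps > len(library_ids):
        raise ValueError(f"at most {len(library_ids)} CSPs available")
    csps = library_ids[: config.n_csps]
    eluents = ["MeOH", "EtOH", "1-PrOH", "2-PrOH"][: config.n_eluents]
    analytes = [Analyte.OMEPRAZOLE, Analyte.RABEPRAZOLE, Analyte.LANSOPRAZOLE][
        : config.n_analytes
    ]
    records, truth_cells = [], {}
    for csp in csps:
        for eluent in eluents:
            system = SeparationSystem.from_library(
                csp, eluent, config.screening_temperature_c
            )
            for analyte in analytes:
                dH_R = rng.uniform(*config.dH_range)
                dS_R = rng.uniform(*config.dS_star_range)
                ddH, ddS = _draw_enantioselectivity(rng, config)
                dH_S, dS_S = dH_R + ddH, dS_R + ddS
                coelute = rng.uniform() < config.missing_rate
                lnk_R = _lnk(dH_R, dS_R, T)
                lnk_S = _lnk(dH_S, dS_S, T)
                if config.sigma_lnk:
                    lnk_R += rng.normal(0.0, config.sigma_lnk)
                    lnk_S += rng.normal(0.0, config.sigma_lnk)
                if coelute:
                    lnk_S = lnk_R
                k_R, k_S = math.exp(lnk_R), math.exp(lnk_S)
                k1, k2 = min(k_R, k_S), max(k_R, k_S)
                t0 = config.t0_min
                t1, t2 = t0 * (1 + k1), t0 * (1 + k2)
                w1 = 4.0 * t1 / math.sqrt(config.plate_number)
                w2 = 4.0 * t2 / math.sqrt(config.plate_number)
                rs = 2.0 * (t2 - t1) / (w1 + w2)
                if coelute or rs == 0.0:
                    rs_val, eeo = None, EEO.COELUTION
                else:
                    rs_val = rs
                    eeo = EEO.R_FIRST if k_R < k_S else EEO.S_FIRST
                records.append(
                    SeparationRecord(
                        system=system, analyte=analyte, k1=k1, k2=k2,
                        rs=rs_val, eeo=eeo,
                    )
                )
                truth_cells[(csp, eluent, analyte.value)] = {
                    "dH_R": dH_R, "dS_R": dS_R, "dH_S": dH_S, "dS_S": dS_S,
                    "coelution": coelute, "true_eeo": eeo.value,
                    "k_R": k_R, "k_S": k_S, "rs": rs_val,
                }
    truth = SynthGroundTruth(seed=config.seed, params={"cells": truth_cells})
    return ScreeningTable(records), truth


def _bump(a: float, x: float) -> float:
    return a * (x / 100.0) * (1.0 - x / 100.0)


def gen_hysteresis_loop(
    config: SynthConfig,
    base_lnk_R: Callable[[float], float] | None = None,
    base_lnk_S: Callable[[float], float] | None = None,
) -> tuple[HysteresisLoop, SynthGroundTruth]:
    """A closed forward/reverse loop over the composition grid.

    Forward ln k is log-linear in the MeOH fraction by default (an
    LSS-like retention model); the reverse branch adds per-enantiomer
    offsets ``delta(x) = a * (x/100)(1 - x/100) + divergence * x/100``.
    True hystereticity is exp(delta) exactly.  Setting the two
    enantiomers' amplitudes to opposite effect (amplitude ratio != 1)
    moves the composition at which the elution order flips, which the
    hysteresis stage should recover.
    """
    rng = config.rng()
    if base_lnk_R is None:
        sel = rng.uniform(0.05, 0.3)  # enantioselectivity gap in ln k
        slope = rng.uniform(-0.8, -0.2)  # retention falls with MeOH content
        icpt = rng.uniform(-0.5, 0.5)
        base_lnk_R = lambda x: icpt + slope * (x / 100.0)  # noqa: E731
        base_lnk_S = lambda x: icpt + sel + slope * (x / 100.0)  # noqa: E731
    elif base_lnk_S is None:
        raise ValueError("provide both base curves or neither")

    a_R = config.hysteresis_amplitude
    a_S = config.hysteresis_amplitude * config.hysteresis_amplitude_ratio

    def delta(a: float, x: float) -> float:
        return _bump(a, x) + config.divergence * (x / 100.0)

    rows, true_v = [], {}
    comps = list(config.compositions)
    for x in comps:
        lnk_R_f, lnk_S_f = base_lnk_R(x), base_lnk_S(x)
        rows.append(
            {"pct_meoh": float(x), "direction": "forward",
             "k_R": math.exp(lnk_R_f), "k_S": math.exp(lnk_S_f)}
        )
    for x in reversed(comps):
        lnk_R_r = base_lnk_R(x) - delta(a_R, x)
        lnk_S_r = base_lnk_S(x) - delta(a_S, x)
        rows.append(
            {"pct_meoh": float(x), "direction": "reverse",
             "k_R": math.exp(lnk_R_r), "k_S": math.exp(lnk_S_r)}
        )
        true_v[float(x)] = {
            "v_R": math.exp(delta(a_R, x)),
            "v_S": math.exp(delta(a_S, x)),
        }
    loop = HysteresisLoop(
        data=pd.DataFrame(rows), csp="synthetic", analyte="synthetic",
        solvent_pair="MeOH-2-PrOH",
    )
    truth = SynthGroundTruth(
        seed=config.seed,
        params={
            "amplitude_R": a_R, "amplitude_S": a_S,
            "divergence": config.divergence, "true_hystereticity": true_v,
        },
    )
    return loop, truth
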