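"""Retention hysteresis over eluent composition and hystereticity inference.

On amylose-type chiral stationary phases the retention measured while
stepping the mobile phase from 100% MeOH toward the co-solvent
("forward") differs from the retention measured stepping back
("reverse"): the column remembers the solvent history.  The
hystereticity of an enantiomer quantifies this as

    v = k_forward / k_reverse

and the ratio of the two enantiomers' hystereticities, v_R/v_S, encodes
what happened to the separation in the reverse branch.  Writing A for
the forward first-eluter, the oriented ratio obeys the identity

    v_A / v_B = (k_Af * k_Br) / (k_Ar * k_Bf) = alpha_rev(signed) / alpha_fwd

so with a separated forward branch (case A, alpha_fwd > 1):

    ratio = 1  ->  selectivity unchanged
    ratio > 1  ->  selectivity increased (elution order preserved)
    ratio < 1  ->  selectivity decreased, OR coelution, OR elution order
                   reversed (the three cannot be distinguished from the
                   ratio alone)

and with a co-eluting forward branch (case B, k_Af = k_Bf) the ratio is
k_Br/k_Ar, so ratio class and reverse elution order are in bijection.
When the forward elution order is S-first, the conventional v_R/v_S
ratio must be compared to 1 through its reciprocal to obtain the
oriented ratio above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import EEO

__all__ = [
    "ForwardCase",
    "ReverseOutcome",
    "HysteresisLoop",
    "HystereticityProfile",
    "ReverseInference",
    "hystereticity",
    "hystereticity_ratio",
    "classify_forward_case",
    "infer_reverse_outcomes",
    "realized_reverse_outcome",
    "detect_hysteresis",
    "hystereticity_profile",
    "infer_loop",
    "read_loop_csv",
    "write_loop_csv",
]

#: default relative tolerance declaring two k values co-eluting
COELUTION_TOL = 1e-3

#: default relative tolerance declaring a hystereticity ratio equal to 1
RATIO_TOL = 1e-3


class ForwardCase(str, Enum):
    A_SEPARATED = "A_separated"
    B_COELUTION = "B_coelution"


class ReverseOutcome(str, Enum):
    SELECTIVITY_INCREASED = "selectivity_increased"
    SELECTIVITY_EQUAL = "selectivity_equal"
    SELECTIVITY_DECREASED_EEO_PRESERVED = "selectivity_decreased_EEO_preserved"
    COELUTION = "coelution"
    EEO_REVERSED = "EEO_reversed"
    EEO_A_FIRST = "EEO_A_first"
    EEO_B_FIRST = "EEO_B_first"


def hystereticity(k_forward: float, k_reverse: float) -> float:
    """v = k_forward / k_reverse for one enantiomer at one composition."""
    if k_reverse <= 0:
        raise ValueError("reverse-branch retention factor must be positive")
    if k_forward == 0.0:
        warnings.warn("k_forward = 0 gives v = 0 (unretained forward peak)")
    return k_forward / k_reverse


def hystereticity_ratio(
    k_R_fwd: float,
    k_S_fwd: float,
    k_R_rev: float,
    k_S_rev: float,
    forward_eeo: EEO | None = None,
) -> tuple[float, float]:
    """Return ``(ratio, oriented)`` where ratio = v_R/v_S.

    ``oriented`` is the ratio expressed with A = the forward first-eluter
    in the numerator: identical to ``ratio`` for R-first (or unknown)
    forward order, and its reciprocal for S-first, which is the value to
    compare against 1.
    """
    v_R = hystereticity(k_R_fwd, k_R_rev)
    v_S = hystereticity(k_S_fwd, k_S_rev)
    if v_S == 0.0:
        raise ValueError("v_S = 0: ratio undefined")
    ratio = v_R / v_S
    if forward_eeo is EEO.S_FIRST:
        if ratio == 0.0:
            raise ValueError("v_R = 0: reciprocal ratio undefined")
        return ratio, 1.0 / ratio
    return ratio, ratio


def classify_forward_case(
    k_R_fwd: float, k_S_fwd: float, tol: float = COELUTION_TOL
) -> tuple[ForwardCase, EEO]:
    """Separated (case A) vs co-eluting (case B) forward branch.

    Two k values within relative tolerance ``tol`` of each other count
    as coelution — the printed precision of retention factors is 2-3
    decimals, so exact equality is too strict for real tables.
    """
    if k_R_fwd < 0 or k_S_fwd < 0:
        raise ValueError("retention factors must be non-negative")
    scale = max(k_R_fwd, k_S_fwd)
    if scale == 0.0 or abs(k_R_fwd - k_S_fwd) <= tol * scale:
        return ForwardCase.B_COELUTION, EEO.COELUTION
    eeo = EEO.R_FIRST if k_R_fwd < k_S_fwd else EEO.S_FIRST
    return ForwardCase.A_SEPARATED, eeo


def infer_reverse_outcomes(
    case: ForwardCase, ratio: float | None, tol: float = RATIO_TOL
) -> tuple[frozenset[ReverseOutcome], str | None]:
    """Possible reverse-branch outcomes from the oriented hystereticity ratio.

    ``ratio`` must be oriented so that enantiomer A is the forward
    first-eluter (case A) or R (case B).  Returns the outcome set and an
    optional reason when it is empty.  Note the case-A / ratio < 1 branch
    admits three outcomes: a ratio below one says only that the signed
    reverse selectivity dropped below the forward one, which covers
    decreased-but-preserved order, coelution, and full reversal alike.
    """
    if ratio is None:
        return frozenset(), "hystereticity ratio missing"
    if ratio <= 0:
        raise ValueError("oriented ratio must be positive")
    if abs(ratio - 1.0) <= tol:
        cls = "eq"
    elif ratio > 1.0:
        cls = "gt"
    else:
        cls = "lt"
    if case is ForwardCase.A_SEPARATED:
        mapping = {
            "eq": {ReverseOutcome.SELECTIVITY_EQUAL},
            "gt": {ReverseOutcome.SELECTIVITY_INCREASED},
            "lt": {
                ReverseOutcome.SELECTIVITY_DECREASED_EEO_PRESERVED,
                ReverseOutcome.COELUTION,
                ReverseOutcome.EEO_REVERSED,
            },
        }
    else:
        mapping = {
            "eq": {ReverseOutcome.COELUTION},
            "gt": {ReverseOutcome.EEO_A_FIRST},
            "lt": {ReverseOutcome.EEO_B_FIRST},
        }
    return frozenset(mapping[cls]), None


def realized_reverse_outcome(
    case: ForwardCase,
    k_A_fwd: float,
    k_B_fwd: float,
    k_A_rev: float,
    k_B_rev: float,
    tol: float = 0.0,
) -> ReverseOutcome:
    """The outcome actually observed in the reverse branch.

    Enantiomer labels follow the same orientation as the inference: A is
    the forward first-eluter in case A, or R in case B.  Serves as the
    independent check that the inferred outcome set always contains the
    realized outcome.
    """
    scale = max(k_A_rev, k_B_rev)
    coelute = scale == 0.0 or abs(k_A_rev - k_B_rev) <= tol * scale
    if case is ForwardCase.B_COELUTION:
        if coelute:
            return ReverseOutcome.COELUTION
        return (
            ReverseOutcome.EEO_A_FIRST
            if k_A_rev < k_B_rev
            else ReverseOutcome.EEO_B_FIRST
        )
    if coelute:
        return ReverseOutcome.COELUTION
    if k_A_rev > k_B_rev:
        return ReverseOutcome.EEO_REVERSED
    alpha_fwd = k_B_fwd / k_A_fwd
    alpha_rev = k_B_rev / k_A_rev
    if math.isclose(alpha_rev, alpha_fwd, rel_tol=tol if tol > 0 else 1e-12):
        return ReverseOutcome.SELECTIVITY_EQUAL
    if alpha_rev > alpha_fwd:
        return ReverseOutcome.SELECTIVITY_INCREASED
    return ReverseOutcome.SELECTIVITY_DECREASED_EEO_PRESERVED


@dataclass
class HysteresisLoop:
    """Forward/reverse retention branches over a composition grid.

    ``data`` holds one row per (pct_meoh, direction) with columns
    ``pct_meoh``, ``direction`` ("forward" = sweep starting from 100%
    MeOH), ``k_R``, ``k_S`` and optional ``rs``/``eeo``.
    """

    data: pd.DataFrame
    csp: str = ""
    analyte: str = ""
    solvent_pair: str = "MeOH-2-PrOH"

    def __post_init__(self):
        required = {"pct_meoh", "direction", "k_R", "k_S"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"loop data missing columns {sorted(missing)}")
        bad = set(self.data["direction"]) - {"forward", "reverse"}
        if bad:
            raise ValueError(f"unknown direction labels {sorted(bad)}")
        if (self.data[["k_R", "k_S"]] < 0).any().any():
            raise ValueError("retention factors must be non-negative")
        fwd = self.data[self.data["direction"] == "forward"]
        if len(fwd) and fwd["pct_meoh"].max() != self.data["pct_meoh"].max():
            raise ValueError("forward branch must start at the highest MeOH fraction")

    def branch(self, direction: str) -> pd.DataFrame:
        return (
            self.data[self.data["direction"] == direction]
            .sort_values("pct_meoh")
            .reset_index(drop=True)
        )

    def compositions(self, both: bool = True) -> np.ndarray:
        """Compositions present (in both branches when ``both``)."""
        fwd = set(self.branch("forward")["pct_meoh"])
        rev = set(self.branch("reverse")["pct_meoh"])
        vals = fwd & rev if both else fwd | rev
        return np.asarray(sorted(vals), dtype=float)


@dataclass
class HystereticityProfile:
    """Per-composition hystereticity of each enantiomer and their ratio."""

    table: pd.DataFrame  # columns: pct_meoh, v_R, v_S, ratio, log_v_R, log_v_S,
    #          abs_dev_R, abs_dev_S

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def hystereticity_profile(loop: HysteresisLoop) -> HystereticityProfile:
    """Compute v_R, v_S, v_R/v_S, log v and |v - 1| at every shared composition."""
    fwd = loop.branch("forward").set_index("pct_meoh")
    rev = loop.branch("reverse").set_index("pct_meoh")
    rows = []
    for x in loop.compositions():
        kRf, kSf = fwd.loc[x, "k_R"], fwd.loc[x, "k_S"]
        kRr, kSr = rev.loc[x, "k_R"], rev.loc[x, "k_S"]
        if min(kRr, kSr) <= 0 or min(kRf, kSf) <= 0:
            rows.append(
                {"pct_meoh": x, "v_R": np.nan, "v_S": np.nan, "ratio": np.nan,
                 "log_v_R": np.nan, "log_v_S": np.nan,
                 "abs_dev_R": np.nan, "abs_dev_S": np.nan}
            )
            continue
        v_R = hystereticity(kRf, kRr)
        v_S = hystereticity(kSf, kSr)
        rows.append(
            {
                "pct_meoh": x,
                "v_R": v_R,
                "v_S": v_S,
                "ratio": v_R / v_S,
                "log_v_R": math.log(v_R),
                "log_v_S": math.log(v_S),
                "abs_dev_R": abs(v_R - 1.0),
                "abs_dev_S": abs(v_S - 1.0),
            }
        )
    return HystereticityProfile(pd.DataFrame(rows))


@dataclass
class ReverseInference:
    """Per-composition case/ratio inference with observed-outcome check."""

    table: pd.DataFrame
    # columns: pct_meoh, forward_case, forward_eeo, ratio, oriented_ratio,
    #          inferred (tuple of outcome names), observed, consistent

    @property
    def all_consistent(self) -> bool:
        obs = self.table.dropna(subset=["observed"])
        return bool(obs["consistent"].all()) if len(obs) else True


def infer_loop(
    loop: HysteresisLoop,
    coelution_tol: float = COELUTION_TOL,
    ratio_tol: float = RATIO_TOL,
) -> ReverseInference:
    """Run the full case/ratio inference at every shared composition.

    For each composition: classify the forward branch, orient the
    hystereticity ratio (A = forward first-eluter, or R under forward
    coelution), infer the admissible reverse outcomes, and — since the
    reverse branch is measured — record the realized outcome and whether
    it falls inside the inferred set.
    """
    fwd = loop.branch("forward").set_index("pct_meoh")
    rev = loop.branch("reverse").set_index("pct_meoh")
    rows = []
    for x in loop.compositions():
        kRf, kSf = float(fwd.loc[x, "k_R"]), float(fwd.loc[x, "k_S"])
        kRr, kSr = float(rev.loc[x, "k_R"]), float(rev.loc[x, "k_S"])
        case, forward_eeo = classify_forward_case(kRf, kSf, coelution_tol)
        if min(kRf, kSf, kRr, kSr) <= 0:
            rows.append(
                {"pct_meoh": x, "forward_case": case.value,
                 "forward_eeo": forward_eeo.to_label(), "ratio": np.nan,
                 "oriented_ratio": np.nan, "inferred": (),
                 "observed": None, "consistent": None}
            )
            continue
        ratio, oriented = hystereticity_ratio(kRf, kSf, kRr, kSr, forward_eeo)
        outcomes, _ = infer_reverse_outcomes(case, oriented, ratio_tol)
        if forward_eeo is EEO.S_FIRST:  # A = S eluting first
            k_A_fwd, k_B_fwd, k_A_rev, k_B_rev = kSf, kRf, kSr, kRr
        else:  # A = R (first-eluter in case A, or the convention in case B)
            k_A_fwd, k_B_fwd, k_A_rev, k_B_rev = kRf, kSf, kRr, kSr
        observed = realized_reverse_outcome(
            case, k_A_fwd, k_B_fwd, k_A_rev, k_B_rev, coelution_tol
        )
        rows.append(
            {
                "pct_meoh": x,
                "forward_case": case.value,
                "forward_eeo": forward_eeo.to_label(),
                "ratio": ratio,
                "oriented_ratio": oriented,
                "inferred": tuple(sorted(o.value for o in outcomes)),
                "observed": observed.value,
                "consistent": observed.value in {o.value for o in outcomes},
            }
        )
    return ReverseInference(pd.DataFrame(rows))


def detect_hysteresis(
    loop: HysteresisLoop, threshold: float = 0.05
) -> tuple[bool, pd.DataFrame]:
    """Is there hysteresis anywhere in the interior of the loop?

    Hysteresis is declared when |v - 1| exceeds ``threshold`` for either
    enantiomer at any interior composition (endpoints at the pure
    solvents are excluded: a closed loop re-measures the starting eluent
    where v = 1 by construction).
    """
    comps = loop.compositions()
    if len(comps) < 2:
        raise ValueError("loop must cover more than one composition")
    profile = hystereticity_profile(loop).table
    interior = profile[
        (profile["pct_meoh"] > comps.min()) & (profile["pct_meoh"] < comps.max())
    ]
    flags = interior.assign(
        flagged=(interior["abs_dev_R"] > threshold)
        | (interior["abs_dev_S"] > threshold)
    )
    present = bool(flags["flagged"].any())
    return present, flags[["pct_meoh", "abs_dev_R", "abs_dev_S", "flagged"]]


_LOOP_COLUMNS = ("csp", "analyte", "solvent_pair", "pct_meoh", "direction", "k_R", "k_S")


def read_loop_csv(path: str | Path) -> HysteresisLoop:
    """Read a hysteresis-loop CSV (one row per composition x direction)."""
    df = pd.read_csv(path)
    missing = [c for c in _LOOP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    meta = df.iloc[0]
    return HysteresisLoop(
        data=df[[c for c in df.columns if c not in ("csp", "analyte", "solvent_pair")]],
        csp=str(meta["csp"]),
        analyte=str(meta["analyte"]),
        solvent_pair=str(meta["solvent_pair"]),
    )


def write_loop_csv(loop: HysteresisLoop, path: str | Path) -> Path:
    """Write a loop with one row per (composition, direction)."""
    path = Path(path)
    df = loop.data.copy()
    df.insert(0, "solvent_pair", loop.solvent_pair)
    df.insert(0, "analyte", loop.analyte)
    df.insert(0, "csp", loop.csp)
    df.to_csv(path, index=False)
    return path
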