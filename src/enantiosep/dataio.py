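"""Domain types, CSV/JSON readers and writers, and packaged fixtures.

The central objects are :class:`SeparationSystem` (a CSP + eluent +
operating conditions), :class:`SeparationRecord` (one screening
measurement: retention factors ``k1``/``k2``, resolution ``Rs`` and
enantiomer elution order), and :class:`ScreeningTable` (the keyed
collection of records).  The packaged screening fixture covers seven
polysaccharide chiral stationary phases x four neat alcohol eluents x
three proton pump inhibitors (84 cells), exactly as printed.

Temperatures cross the I/O boundary in degrees Celsius and are stored in
kelvin internally.  Coelution is encoded as ``rs = None`` together with
``eeo = COELUTION``: the printed tables mark unresolved pairs with
identical retention factors and a dash, which is a different statement
from "Rs = 0 was measured".
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "EEO",
    "Analyte",
    "Backbone",
    "SeparationSystem",
    "SeparationRecord",
    "ScreeningTable",
    "SchemaError",
    "ValidationError",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "read_screening_csv",
    "write_screening_csv",
    "write_tidy_results",
    "load_table1",
    "load_semiprep_table",
    "CSP_LIBRARY",
]

KELVIN_OFFSET = 273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + KELVIN_OFFSET


def kelvin_to_celsius(t_kelvin: float) -> float:
    return t_kelvin - KELVIN_OFFSET


class SchemaError(ValueError):
    """A table is missing required columns or has a malformed header."""


class ValidationError(ValueError):
    """A row violates a domain invariant (e.g. k2 < k1)."""


class Backbone(str, Enum):
    AMYLOSE = "amylose"
    CELLULOSE = "cellulose"


class Analyte(str, Enum):
    OMEPRAZOLE = "omeprazole"
    RABEPRAZOLE = "rabeprazole"
    LANSOPRAZOLE = "lansoprazole"
    OTHER = "other"


class EEO(str, Enum):
    """Enantiomer elution order: which configured enantiomer elutes first."""

    R_FIRST = "R_first"
    S_FIRST = "S_first"
    COELUTION = "coelution"
    UNKNOWN = "unknown"

    @classmethod
    def from_label(cls, label: str) -> "EEO":
        label = label.strip()
        if label in ("R-S", "R>S", "R_first"):
            return cls.R_FIRST
        if label in ("S-R", "S>R", "S_first"):
            return cls.S_FIRST
        if label in ("-", "", "coelution"):
            return cls.COELUTION
        return cls.UNKNOWN

    def to_label(self) -> str:
        return {
            EEO.R_FIRST: "R-S",
            EEO.S_FIRST: "S-R",
            EEO.COELUTION: "-",
            EEO.UNKNOWN: "?",
        }[self]

    def flipped(self) -> "EEO":
        if self is EEO.R_FIRST:
            return EEO.S_FIRST
        if self is EEO.S_FIRST:
            return EEO.R_FIRST
        return self


# Column metadata for the stationary phases used throughout: backbone,
# selector substituent and whether the selector is immobilized on silica.
CSP_LIBRARY: dict[str, dict] = {
    "OD": {
        "backbone": Backbone.CELLULOSE,
        "selector_substituent": "3,5-dimethylphenylcarbamate",
        "immobilized": False,
        "full_name": "Chiralcel OD",
    },
    "OJ": {
        "backbone": Backbone.CELLULOSE,
        "selector_substituent": "4-methylbenzoate",
        "immobilized": False,
        "full_name": "Chiralcel OJ",
    },
    "Cell2": {
        "backbone": Backbone.CELLULOSE,
        "selector_substituent": "3-chloro-4-methylphenylcarbamate",
        "immobilized": False,
        "full_name": "Lux Cellulose-2",
    },
    "Cell4": {
        "backbone": Backbone.CELLULOSE,
        "selector_substituent": "4-chloro-3-methylphenylcarbamate",
        "immobilized": False,
        "full_name": "Lux Cellulose-4",
    },
    "AD": {
        "backbone": Backbone.AMYLOSE,
        "selector_substituent": "3,5-dimethylphenylcarbamate",
        "immobilized": False,
        "full_name": "Chiralpak AD",
    },
    "AS": {
        "backbone": Backbone.AMYLOSE,
        "selector_substituent": "(S)-alpha-methylbenzylcarbamate",
        "immobilized": False,
        "full_name": "Chiralpak AS",
    },
    "IA": {
        "backbone": Backbone.AMYLOSE,
        "selector_substituent": "3,5-dimethylphenylcarbamate",
        "immobilized": True,
        "full_name": "Chiralpak IA",
    },
}


def _parse_eluent(label: str) -> dict[str, float]:
    """Parse an eluent label into a solvent -> V/V% map.

    Neat eluents ("MeOH") become 100% single-solvent maps.  Mixtures use
    the form "MeOH:2-PrOH=60:40".
    """
    label = label.strip()
    if "=" in label:
        names, fracs = label.split("=", 1)
        solvent_names = [s.strip() for s in names.split(":")]
        fractions = [float(x) for x in fracs.split(":")]
        if len(solvent_names) != len(fractions):
            raise SchemaError(f"malformed eluent label {label!r}")
        return dict(zip(solvent_names, fractions))
    return {label: 100.0}


def _format_eluent(eluent: Mapping[str, float]) -> str:
    if len(eluent) == 1:
        ((name, frac),) = eluent.items()
        if math.isclose(frac, 100.0):
            return name
    names = ":".join(eluent)
    fracs = ":".join(f"{v:g}" for v in eluent.values())
    return f"{names}={fracs}"


@dataclass(frozen=True)
class SeparationSystem:
    """A chromatographic system: CSP + eluent + operating conditions."""

    csp_id: str
    backbone: Backbone
    selector_substituent: str
    immobilized: bool
    eluent: Mapping[str, float]  # solvent -> V/V%, summing to 100
    temperature: float = celsius_to_kelvin(20.0)  # kelvin
    flow_rate: float = 0.7  # mL/min

    def __post_init__(self):
        total = sum(self.eluent.values())
        if not math.isclose(total, 100.0, abs_tol=1e-9):
            raise ValidationError(
                f"eluent fractions must sum to 100 V/V%, got {total}"
            )
        if any(not 0.0 <= v <= 100.0 for v in self.eluent.values()):
            raise ValidationError("eluent fractions must lie in [0, 100]")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive kelvin")
        if self.flow_rate <= 0:
            raise ValidationError("flow rate must be positive")
        object.__setattr__(self, "eluent", dict(self.eluent))

    @property
    def eluent_label(self) -> str:
        return _format_eluent(self.eluent)

    @property
    def system_id(self) -> str:
        """Unique identifier combining CSP and mobile phase."""
        return f"{self.csp_id}-{self.eluent_label}"

    @classmethod
    def from_library(
        cls,
        csp_id: str,
        eluent: str | Mapping[str, float],
        temperature_c: float = 20.0,
        flow_rate: float = 0.7,
    ) -> "SeparationSystem":
        try:
            meta = CSP_LIBRARY[csp_id]
        except KeyError:
            raise ValidationError(f"unknown CSP identifier {csp_id!r}") from None
        if isinstance(eluent, str):
            eluent = _parse_eluent(eluent)
        return cls(
            csp_id=csp_id,
            backbone=meta["backbone"],
            selector_substituent=meta["selector_substituent"],
            immobilized=meta["immobilized"],
            eluent=eluent,
            temperature=celsius_to_kelvin(temperature_c),
            flow_rate=flow_rate,
        )


@dataclass(frozen=True)
class SeparationRecord:
    """One (system, analyte) screening measurement."""

    system: SeparationSystem
    analyte: Analyte
    k1: float
    k2: float
    rs: float | None  # None encodes "not resolved" (printed '-')
    eeo: EEO
    raw_peaks: tuple | None = None  # ((t1, w1), (t2, w2), t0) in minutes

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise ValidationError("retention factors must be non-negative")
        if self.k2 < self.k1 - 1e-12:
            raise ValidationError(f"k2 ({self.k2}) < k1 ({self.k1})")
        if self.rs is not None and self.rs < 0:
            raise ValidationError("resolution must be non-negative")
        if self.raw_peaks is not None:
            (t1, w1), (t2, w2), t0 = self.raw_peaks
            k1 = (t1 - t0) / t0
            k2 = (t2 - t0) / t0
            rs = 2.0 * (t2 - t1) / (w1 + w2)
            stored_rs = 0.0 if self.rs is None else self.rs
            if (
                abs(k1 - self.k1) > 1e-9
                or abs(k2 - self.k2) > 1e-9
                or abs(rs - stored_rs) > 1e-9
            ):
                raise ValidationError(
                    "raw peaks inconsistent with stored k1/k2/rs"
                )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.system.csp_id, self.system.eluent_label, self.analyte.value)

    @property
    def is_separated(self) -> bool:
        return self.eeo is not EEO.COELUTION and self.rs is not None


@dataclass
class ScreeningTable:
    """Collection of screening records keyed by (csp, eluent, analyte)."""

    records: list[SeparationRecord] = field(default_factory=list)

    def __post_init__(self):
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate (csp, eluent, analyte) keys: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeparationRecord]:
        return iter(self.records)

    def get(self, csp: str, eluent: str, analyte: str | Analyte) -> SeparationRecord:
        analyte = Analyte(analyte)
        for r in self.records:
            if r.key == (csp, eluent, analyte.value):
                return r
        raise KeyError((csp, eluent, analyte.value))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "csp": r.system.csp_id,
                    "eluent": r.system.eluent_label,
                    "analyte": r.analyte.value,
                    "k1": r.k1,
                    "k2": r.k2,
                    "rs": r.rs,
                    "eeo": r.eeo.to_label(),
                }
            )
        return pd.DataFrame(rows)


_SCREENING_COLUMNS = ("csp", "eluent", "analyte", "k1", "k2", "rs", "eeo")


def read_screening_csv(
    path: str | Path,
    temperature_c: float = 20.0,
    flow_rate: float = 0.7,
) -> ScreeningTable:
    """Read a tidy screening CSV into a validated :class:`ScreeningTable`.

    Rows with a ``-`` resolution become coelution records with ``rs``
    stored as missing.  Raises :class:`SchemaError` when a required
    column is absent and :class:`ValidationError` (with the row index)
    when a row violates ``k2 >= k1``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header row")
        missing = [c for c in _SCREENING_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        records = []
        for i, row in enumerate(reader):
            rs_raw = (row["rs"] or "").strip()
            rs = None if rs_raw in ("-", "") else float(rs_raw)
            eeo = EEO.from_label(row["eeo"] or "-")
            if rs is None:
                eeo = EEO.COELUTION
            k1, k2 = float(row["k1"]), float(row["k2"])
            if k2 < k1 - 1e-12:
                raise ValidationError(f"{path} row {i}: k2 ({k2}) < k1 ({k1})")
            system = SeparationSystem.from_library(
                row["csp"], row["eluent"], temperature_c, flow_rate
            )
            records.append(
                SeparationRecord(
                    system=system,
                    analyte=Analyte(row["analyte"]),
                    k1=k1,
                    k2=k2,
                    rs=rs,
                    eeo=eeo,
                )
            )
    return ScreeningTable(records)


def write_screening_csv(table: ScreeningTable, path: str | Path) -> Path:
    """Write a :class:`ScreeningTable` so that reading it back round-trips."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCREENING_COLUMNS)
        for r in table:
            writer.writerow(
                [
                    r.system.csp_id,
                    r.system.eluent_label,
                    r.analyte.value,
                    repr(r.k1),
                    repr(r.k2),
                    "-" if r.rs is None else repr(r.rs),
                    r.eeo.to_label(),
                ]
            )
    return path


def write_tidy_results(results, path: str | Path) -> Path:
    """Serialize a stage output to disk (CSV for tables, JSON otherwise).

    ``ScreeningTable`` -> tidy CSV; pandas objects -> CSV; mappings and
    dataclass-like objects -> JSON with a ``units`` block preserved when
    present.  Round-trip reads return an equal object for the tabular
    types.
    """
    path = Path(path)
    if isinstance(results, ScreeningTable):
        return write_screening_csv(results, path)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=True)
        return path
    if hasattr(results, "to_json_dict"):
        payload = results.to_json_dict()
    elif isinstance(results, Mapping):
        payload = dict(results)
    else:
        raise TypeError(f"do not know how to serialize {type(results).__name__}")
    with path.open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "to_json_dict"):
        return obj.to_json_dict()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def _data_path(name: str):
    return resources.files("enantiosep.data").joinpath(name)


def load_table1() -> ScreeningTable:
    """Load the packaged screening fixture (7 CSPs x 4 eluents x 3 PPIs).

    The screening was run at 20 degC and 0.7 mL/min; numbers are stored
    exactly as printed.
    """
    with resources.as_file(_data_path("table1_screening.csv")) as p:
        return read_screening_csv(p, temperature_c=20.0, flow_rate=0.7)


def load_semiprep_table() -> pd.DataFrame:
    """Load the semi-preparative collection fixture (masses and purities)."""
    with resources.as_file(_data_path("table3_semiprep.csv")) as p:
        return pd.read_csv(p)


def load_schema() -> dict:
    """The CSV column schema shipped with the package."""
    with resources.as_file(_data_path("schema.json")) as p:
        return json.loads(Path(p).read_text())
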