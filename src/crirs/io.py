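"""Inventory CSV schema, per-row validation, and scoring-table configuration.

One row per chemical. Columns:

``name, cas`` — identity. CAS check-digit failures warn but do not block
(regulatory lists contain family pseudo-CAS entries, e.g. solvent naphtha
groups, that must still be scorable).

``T1`` .. ``T9`` — GHS class labels ``1, 1A, 1B, 2, 3, 4, ND, NC, NA``.
Several source assignments may share a cell separated by ``|``
(``"2|1B"``) and are resolved to the most conservative. A blank hazard
cell means No Data. An undivided ``1`` for a CMR indicator (T6–T8) is
read as ``1A`` — conservative when the source scheme does not subdivide.

``handling_volume_tpy, circulation_tpy`` — tons/year; ``workers,
workplaces`` — counts; ``state`` — ``LG`` (liquid/gas) or ``S`` (solid);
``boiling_point_C`` (required iff LG); ``dust_form`` — ``TLV`` / ``POWDER``
/ ``PELLET`` (required iff S); ``measured_exposure`` with ``exposure_unit``
``ppm`` (LG) or ``mg/m3`` (S). Blank exposure cells mean missing and band
as Not Classified.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .exposure import (
    DustForm,
    ExposureClass,
    ExposureIndicator,
    ExposureProfile,
    ExposureScoringTable,
    PhysicalForm,
)
from .hazard import (
    VALID_CLASSES,
    HazardClass,
    HazardIndicator,
    HazardProfile,
    HazardScoringTable,
    merge_classifications,
)
from .records import ChemicalRecord, cas_checksum_ok

__all__ = [
    "INVENTORY_COLUMNS",
    "InventoryError",
    "ScoringConfig",
    "read_inventory",
    "write_inventory",
    "validate_inventory",
    "load_scoring_config",
]

HAZARD_COLUMNS = [i.name for i in HazardIndicator]
EXPOSURE_COLUMNS = [
    "handling_volume_tpy",
    "circulation_tpy",
    "workers",
    "workplaces",
    "state",
    "boiling_point_C",
    "dust_form",
    "measured_exposure",
    "exposure_unit",
]
INVENTORY_COLUMNS = ["name", "cas"] + HAZARD_COLUMNS + EXPOSURE_COLUMNS

_DUST_LABELS = {d.value: d for d in DustForm}
_UNIT_FOR_STATE = {"liquid_gas": "ppm", "solid": "mg/m3"}


class InventoryError(ValueError):
    """Inventory-level failure carrying per-row diagnostics."""

    def __init__(self, diagnostics: Sequence[tuple[int, str]]):
        self.diagnostics = list(diagnostics)
        lines = "\n".join(f"  row {row}: {msg}" for row, msg in self.diagnostics)
        super().__init__(f"{len(self.diagnostics)} invalid row(s):\n{lines}")


def _parse_hazard_cell(
    raw: str, indicator: HazardIndicator, table: HazardScoringTable
) -> HazardClass:
    raw = (raw or "").strip()
    if not raw:
        return HazardClass.NO_DATA
    candidates = []
    for token in raw.split("|"):
        token = token.strip().upper()
        if token == "1" and indicator.is_cmr:
            token = "1A"  # undivided class 1: conservative sub-class
        try:
            cls = HazardClass(token)
        except ValueError:
            raise ValueError(
                f"{indicator.name}: unknown hazard class label {token!r}"
            ) from None
        if cls not in VALID_CLASSES[indicator]:
            raise ValueError(
                f"{indicator.name}: class {token!r} is not a valid label for "
                f"this indicator"
            )
        candidates.append(cls)
    return merge_classifications(candidates, indicator, table)


def _parse_float(raw: str, column: str) -> Optional[float]:
    raw = (raw or "").strip()
    if not raw:
        return None
    try:
        v = float(raw)
    except ValueError:
        raise ValueError(f"{column}: malformed numeric value {raw!r}") from None
    if v < 0:
        raise ValueError(f"{column}: must be non-negative, got {v}")
    return v


def _parse_int(raw: str, column: str) -> Optional[int]:
    v = _parse_float(raw, column)
    if v is None:
        return None
    if v != int(v):
        raise ValueError(f"{column}: expected an integer, got {v}")
    return int(v)


def _parse_row(
    row: dict[str, str], hazard_table: HazardScoringTable
) -> ChemicalRecord:
    name = (row.get("name") or "").strip()
    cas = (row.get("cas") or "").strip()
    if not name:
        raise ValueError("name: must be non-empty")
    if not cas:
        raise ValueError("cas: must be non-empty")
    if not cas_checksum_ok(cas):
        warnings.warn(
            f"CAS {cas!r} ({name}) fails the check-digit test; "
            "accepted as a pseudo-CAS identifier",
            stacklevel=4,
        )

    assignments = {
        ind: _parse_hazard_cell(row.get(ind.name, ""), ind, hazard_table)
        for ind in HazardIndicator
    }

    state_raw = (row.get("state") or "").strip().upper()
    bp = _parse_float(row.get("boiling_point_C", ""), "boiling_point_C")
    dust_raw = (row.get("dust_form") or "").strip().upper()
    if state_raw == "LG":
        if bp is None:
            raise ValueError("boiling_point_C: required for state=LG")
        if dust_raw:
            raise ValueError("dust_form: must be blank for state=LG")
        form: Optional[PhysicalForm] = PhysicalForm("liquid_gas", boiling_point_C=bp)
    elif state_raw == "S":
        if dust_raw not in _DUST_LABELS:
            raise ValueError(
                f"dust_form: required for state=S, one of {sorted(_DUST_LABELS)}"
            )
        if bp is not None:
            raise ValueError("boiling_point_C: must be blank for state=S")
        form = PhysicalForm("solid", dust_form=_DUST_LABELS[dust_raw])
    elif not state_raw:
        if bp is not None or dust_raw:
            raise ValueError("state: required when boiling_point_C/dust_form given")
        form = None
    else:
        raise ValueError(f"state: must be LG or S, got {state_raw!r}")

    measured = _parse_float(row.get("measured_exposure", ""), "measured_exposure")
    unit = (row.get("exposure_unit") or "").strip().lower()
    if measured is not None and form is None:
        raise ValueError("measured_exposure: requires a physical state to fix the unit")
    if unit:
        if form is None:
            raise ValueError("exposure_unit: given without a physical state")
        expected = _UNIT_FOR_STATE[form.state]
        if unit != expected:
            raise ValueError(
                f"exposure_unit: {unit!r} does not match state "
                f"({form.state} takes {expected})"
            )

    exposure = ExposureProfile(
        handling_volume_tpy=_parse_float(
            row.get("handling_volume_tpy", ""), "handling_volume_tpy"
        ),
        circulation_tpy=_parse_float(row.get("circulation_tpy", ""), "circulation_tpy"),
        worker_count=_parse_int(row.get("workers", ""), "workers"),
        workplace_count=_parse_int(row.get("workplaces", ""), "workplaces"),
        form=form,
        measured_exposure=measured,
    )
    return ChemicalRecord(name=name, cas=cas, hazard=HazardProfile(assignments), exposure=exposure)


def validate_inventory(
    path: Union[str, Path], hazard_table: Optional[HazardScoringTable] = None
) -> tuple[list[ChemicalRecord], list[tuple[int, str]]]:
    """Parse an inventory CSV, collecting per-row diagnostics.

    Returns ``(records, diagnostics)`` where diagnostics are ``(row_number,
    message)`` pairs (row numbers count the header as row 1). Duplicate CAS
    numbers within the file are diagnosed. Unknown columns warn.
    """
    path = Path(path)
    hazard_table = hazard_table or HazardScoringTable()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InventoryError([(1, "empty file: no header row")])
        unknown = [c for c in reader.fieldnames if c not in INVENTORY_COLUMNS]
        if unknown:
            warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)
        missing_cols = [c for c in ("name", "cas") if c not in reader.fieldnames]
        if missing_cols:
            raise InventoryError(
                [(1, f"header missing required columns: {missing_cols}")]
            )
        records: list[ChemicalRecord] = []
        diagnostics: list[tuple[int, str]] = []
        seen_cas: dict[str, int] = {}
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = _parse_row(row, hazard_table)
            except ValueError as exc:
                diagnostics.append((lineno, str(exc)))
                continue
            if rec.cas in seen_cas:
                diagnostics.append(
                    (lineno, f"cas: duplicate CAS {rec.cas!r} (first at row {seen_cas[rec.cas]})")
                )
                continue
            seen_cas[rec.cas] = lineno
            records.append(rec)
    if not records and not diagnostics:
        raise InventoryError([(1, "empty inventory: no data rows")])
    return records, diagnostics


def read_inventory(
    path: Union[str, Path], hazard_table: Optional[HazardScoringTable] = None
) -> list[ChemicalRecord]:
    """Read and validate an inventory CSV; raise on any invalid row."""
    records, diagnostics = validate_inventory(path, hazard_table)
    if diagnostics:
        raise InventoryError(diagnostics)
    return records


def _format_float(v: Optional[float]) -> str:
    if v is None:
        return ""
    return repr(float(v))  # shortest round-tripping decimal form


def write_inventory(records: Sequence[ChemicalRecord], path: Union[str, Path]) -> None:
    """Write records to the standard inventory CSV (lossless round trip)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(INVENTORY_COLUMNS)
        for rec in records:
            exp = rec.exposure
            form = exp.form
            state = "" if form is None else ("LG" if form.state == "liquid_gas" else "S")
            writer.writerow(
                [rec.name, rec.cas]
                + [rec.hazard.assignments[ind].value for ind in HazardIndicator]
                + [
                    _format_float(exp.handling_volume_tpy),
                    _format_float(exp.circulation_tpy),
                    "" if exp.worker_count is None else str(exp.worker_count),
                    "" if exp.workplace_count is None else str(exp.workplace_count),
                    state,
                    _format_float(None if form is None else form.boiling_point_C),
                    "" if form is None or form.dust_form is None else form.dust_form.value,
                    _format_float(exp.measured_exposure),
                    ""
                    if form is None or exp.measured_exposure is None
                    else _UNIT_FOR_STATE[form.state],
                ]
            )


@dataclass(frozen=True)
class ScoringConfig:
    """Both scoring tables plus a content hash for provenance logging."""

    hazard_table: HazardScoringTable
    exposure_table: ExposureScoringTable

    @property
    def sha256(self) -> str:
        payload = {
            "hazard": {
                ind.name: {
                    cls.value: int(p) for cls, p in self.hazard_table.points[ind].items()
                }
                for ind in HazardIndicator
            },
            "exposure": {
                ind.name: {
                    cls.value: int(p)
                    for cls, p in self.exposure_table.points[ind].items()
                }
                for ind in ExposureIndicator
            },
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def default(cls) -> "ScoringConfig":
        return cls(HazardScoringTable(), ExposureScoringTable())


def load_scoring_config(path: Union[str, Path]) -> ScoringConfig:
    """Load scoring tables from a YAML file mirroring the point grids.

    Structure::

        hazard:
          T1: {"1": 6, "2": 4, "3": 2, "4": 1, ND: 6}
          T8: {1A: 20, 1B: 16, "2": 12, ND: 20}
          ...
        exposure:
          E1: {Class1: 30, Class2: 24, Class3: 18, Class4: 12, Class5: 6}
          ...

    Omitted indicators keep their defaults; NC/NA cells default to 0.
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}

    from .exposure import _default_exposure_points  # default grids as baseline
    from .hazard import _default_points

    hz = _default_points()
    for ind_name, cells in (data.get("hazard") or {}).items():
        ind = HazardIndicator[ind_name]
        parsed: dict[HazardClass, int] = {}
        for label, pts in cells.items():
            cls = HazardClass(str(label).upper())
            parsed[cls] = int(pts)
        parsed.setdefault(HazardClass.NOT_CLASSIFIED, 0)
        parsed.setdefault(HazardClass.NOT_APPLICABLE, 0)
        hz[ind] = parsed
    ex = _default_exposure_points()
    for ind_name, cells in (data.get("exposure") or {}).items():
        ind = ExposureIndicator[ind_name]
        parsed_e: dict[ExposureClass, int] = {}
        for label, pts in cells.items():
            parsed_e[ExposureClass(str(label))] = int(pts)
        parsed_e.setdefault(ExposureClass.NOT_CLASSIFIED, 0)
        ex[ind] = parsed_e
    return ScoringConfig(HazardScoringTable(hz), ExposureScoringTable(ex))
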