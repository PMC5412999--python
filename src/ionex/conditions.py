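"""Titration bookkeeping, envelope datasets, and the published data offsets.

A strong acid cannot be added without its conjugate base: every mmol of HCl
used to lower the pH of a batch adds the same mmol of Cl- to that batch's
total, and every mmol of NaOH adds Na+.  ``build_conditions`` turns a
titration schedule (background electrolyte, fixed additions, per-condition
titrant doses) into per-condition component totals in mol/L of final volume.

``apply_offsets`` implements the constant corrections applied to measured
surface densities (e.g. aligning the back-titration proton scale to the
point of zero salt effect, and crediting autochthonous chloride desorbing at
high pH) together with the matching increments to total concentrations.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .chemistry import GeometryContext
from .solver import Condition

__all__ = [
    "Titrant",
    "TitrantDose",
    "TitrationSchedule",
    "EnvelopeDataset",
    "DataError",
    "build_conditions",
    "apply_offsets",
    "read_dataset",
    "write_dataset",
]

#: canonical CSV schema (mM for totals, umol/m^2 for gamma columns)
CSV_COLUMNS = [
    "condition_id", "pH", "acid_added_mmol", "base_added_mmol",
    "total_Na_mM", "total_Cl_mM", "total_L_mM",
    "gamma_H", "gamma_Cl", "gamma_L", "gamma_Na",
]
GAMMA_COLUMNS = ["gamma_H", "gamma_Cl", "gamma_L", "gamma_Na"]
TOTAL_COLUMNS = {"Na": "total_Na_mM", "Cl": "total_Cl_mM", "L": "total_L_mM"}


class DataError(ValueError):
    """Malformed schedule or dataset."""


class Titrant(BaseModel):
    """A strong acid or base stock: which conjugate ion it carries, and molarity."""

    conjugate: str
    molarity: float = Field(gt=0, description="mol/L of stock")


class TitrantDose(BaseModel):
    """Per-condition titrant addition, as stock volume (mL) or absolute mmol."""

    acid_ml: float = Field(default=0.0, ge=0.0)
    base_ml: float = Field(default=0.0, ge=0.0)
    acid_mmol: float = Field(default=0.0, ge=0.0)
    base_mmol: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _one_titrant(self) -> "TitrantDose":
        acid = self.acid_ml > 0 or self.acid_mmol > 0
        base = self.base_ml > 0 or self.base_mmol > 0
        if acid and base:
            raise ValueError("acid and base must never both be added to one condition")
        return self


class TitrationSchedule(BaseModel):
    """Background electrolyte plus per-condition acid/base doses.

    ``background`` and ``fixed_additions`` are mol/L in the final volume;
    doses are converted with the stock molarities and the final volume.
    """

    background: Dict[str, float] = Field(default_factory=dict)
    fixed_additions: Dict[str, float] = Field(default_factory=dict)
    acid: Optional[Titrant] = None
    base: Optional[Titrant] = None
    final_volume_ml: float = Field(default=35.0, gt=0)
    doses: List[TitrantDose] = Field(default_factory=list)

    def acid_mmol(self, dose: TitrantDose) -> float:
        extra = dose.acid_ml * self.acid.molarity if (self.acid and dose.acid_ml) else 0.0
        return dose.acid_mmol + extra

    def base_mmol(self, dose: TitrantDose) -> float:
        extra = dose.base_ml * self.base.molarity if (self.base and dose.base_ml) else 0.0
        return dose.base_mmol + extra


def build_conditions(
    schedule: TitrationSchedule,
    pH_per_condition: List[float],
    geometry: GeometryContext,
    ids: Optional[List[str]] = None,
) -> List[Condition]:
    """Totals per condition = background + fixed additions + titrant conjugates.

    The pH list and the schedule's dose list must align one-to-one (an empty
    dose list means no titrant anywhere).
    """
    doses = schedule.doses or [TitrantDose() for _ in pH_per_condition]
    if len(doses) != len(pH_per_condition):
        raise DataError(
            f"{len(pH_per_condition)} pH values but {len(doses)} titrant doses"
        )
    if ids is None:
        ids = [f"c{k + 1:02d}" for k in range(len(pH_per_condition))]
    vol_l = schedule.final_volume_ml / 1000.0
    out = []
    for cid, ph, dose in zip(ids, pH_per_condition, doses):
        totals: Dict[str, float] = dict(schedule.background)
        for comp, conc in schedule.fixed_additions.items():
            totals[comp] = totals.get(comp, 0.0) + conc
        a_mmol = schedule.acid_mmol(dose)
        if a_mmol > 0:
            if schedule.acid is None:
                raise DataError(f"condition {cid}: acid dose given but no acid stock defined")
            comp = schedule.acid.conjugate
            totals[comp] = totals.get(comp, 0.0) + a_mmol * 1e-3 / vol_l
        b_mmol = schedule.base_mmol(dose)
        if b_mmol > 0:
            if schedule.base is None:
                raise DataError(f"condition {cid}: base dose given but no base stock defined")
            comp = schedule.base.conjugate
            totals[comp] = totals.get(comp, 0.0) + b_mmol * 1e-3 / vol_l
        for comp, tot in totals.items():
            if tot < 0:
                raise DataError(f"condition {cid}: negative total for {comp}")
        out.append(Condition(id=cid, pH=ph, totals=totals, geometry=geometry))
    return out


@dataclass
class EnvelopeDataset:
    """Conditions plus measured surface densities (umol/m^2, missing allowed)."""

    conditions: List[Condition]
    observations: Dict[Tuple[str, str], float]   # (condition_id, ion) -> gamma
    offsets_applied: Dict[str, object] = field(default_factory=dict)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {c.id for c in self.conditions}
        for cid, ion in self.observations:
            if cid not in ids:
                raise DataError(f"observation references unknown condition {cid}")

    def observed_ions(self) -> List[str]:
        return sorted({ion for _, ion in self.observations})

    def condition(self, cid: str) -> Condition:
        for c in self.conditions:
            if c.id == cid:
                return c
        raise KeyError(cid)


def apply_offsets(
    dataset: EnvelopeDataset,
    proton_offset: float = 0.0,
    ion_offsets: Optional[Dict[str, float]] = None,
    total_increments: Optional[Dict[str, float]] = None,
) -> EnvelopeDataset:
    """Shift observed surface densities and increment totals; one-shot only.

    Offsets (umol/m^2) are *added* to the raw gammas, the default sign chosen
    so a raw proton curve reading zero at the point of zero salt effect moves
    up to its stoichiometric value.  ``total_increments`` (mol/L) are added to
    the named component totals of every condition.  Applying offsets to a
    dataset that already carries them is refused; reverse by applying the
    negated offsets to a dataset whose correction record was cleared.
    """
    ion_offsets = dict(ion_offsets or {})
    total_increments = dict(total_increments or {})
    for v in [proton_offset, *ion_offsets.values(), *total_increments.values()]:
        if not math.isfinite(v):
            raise DataError("offsets must be finite")
    if dataset.offsets_applied:
        raise DataError("offsets already applied to this dataset")
    shifts = dict(ion_offsets)
    if proton_offset:
        shifts["H"] = shifts.get("H", 0.0) + proton_offset
    observations = {
        (cid, ion): gamma + shifts.get(ion, 0.0)
        for (cid, ion), gamma in dataset.observations.items()
    }
    conditions = []
    for cond in dataset.conditions:
        totals = dict(cond.totals)
        for comp, inc in total_increments.items():
            totals[comp] = totals.get(comp, 0.0) + inc
            if totals[comp] < 0:
                raise DataError(f"condition {cond.id}: increment drives {comp} negative")
        conditions.append(cond.model_copy(update={"totals": totals}))
    record = {
        "proton_offset": proton_offset,
        "ion_offsets": ion_offsets,
        "total_increments": total_increments,
    }
    return EnvelopeDataset(
        conditions=conditions,
        observations=observations,
        offsets_applied=record,
        metadata=dict(dataset.metadata),
    )


def _format(value: float) -> str:
    return format(value, ".10g")


def write_dataset(dataset: EnvelopeDataset, path) -> None:
    """Write the canonical CSV (UTF-8, '.' decimal, '#' metadata header)."""
    geom = dataset.conditions[0].geometry if dataset.conditions else None
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if geom is not None:
            fh.write(f"# surface_area_m2_g: {_format(geom.surface_area)}\n")
            fh.write(f"# solids_conc_g_L: {_format(geom.solids_conc)}\n")
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for cond in dataset.conditions:
            row = [cond.id, _format(cond.pH), "", ""]
            for comp in ("Na", "Cl", "L"):
                tot = cond.totals.get(comp)
                row.append(_format(tot * 1e3) if tot is not None else "")
            for col in GAMMA_COLUMNS:
                ion = col.split("_", 1)[1]
                obs = dataset.observations.get((cond.id, ion))
                row.append(_format(obs) if obs is not None else "")
            writer.writerow(row)


def read_dataset(path, geometry: Optional[GeometryContext] = None) -> EnvelopeDataset:
    """Read the canonical CSV back into an :class:`EnvelopeDataset`.

    Unknown columns are a schema error; malformed cells report their line
    number.  Gamma columns are optional.  Geometry comes from the '#' header
    unless overridden.
    """
    header_meta: Dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    data_start = 0
    for line in lines:
        if line.startswith("#"):
            data_start += 1
            try:
                key, val = line[1:].split(":", 1)
                header_meta[key.strip()] = float(val)
            except ValueError:
                continue
        else:
            break
    if geometry is None:
        try:
            geometry = GeometryContext(
                surface_area=header_meta["surface_area_m2_g"],
                solids_conc=header_meta["solids_conc_g_L"],
            )
        except KeyError as exc:
            raise DataError(f"{path}: no geometry header and none supplied") from exc

    reader = csv.reader(lines[data_start:])
    try:
        header = next(reader)
    except StopIteration:
        raise DataError(f"{path}: empty dataset")
    unknown = [c for c in header if c not in CSV_COLUMNS]
    if unknown:
        raise DataError(f"{path}: unknown columns {unknown}")
    if "condition_id" not in header or "pH" not in header:
        raise DataError(f"{path}: condition_id and pH columns are required")
    col = {name: header.index(name) for name in header}

    conditions: List[Condition] = []
    observations: Dict[Tuple[str, str], float] = {}
    for offset, row in enumerate(reader):
        line_no = data_start + 2 + offset  # 1-based, after header
        if not row or all(not cell.strip() for cell in row):
            continue

        def cell(name: str) -> Optional[float]:
            if name not in col:
                return None
            raw = row[col[name]].strip()
            if raw == "":
                return None
            try:
                return float(raw)
            except ValueError:
                raise DataError(f"{path}:{line_no}: bad value {raw!r} in {name}")

        cid = row[col["condition_id"]].strip()
        ph = cell("pH")
        if ph is None or not 0.0 <= ph <= 14.0:
            raise DataError(f"{path}:{line_no}: pH {ph} outside [0, 14]")
        totals = {}
        for comp, name in TOTAL_COLUMNS.items():
            tot = cell(name)
            if tot is not None:
                if tot < 0:
                    raise DataError(f"{path}:{line_no}: negative total for {comp}")
                totals[comp] = tot * 1e-3
        conditions.append(Condition(id=cid, pH=ph, totals=totals, geometry=geometry))
        for gcol in GAMMA_COLUMNS:
            val = cell(gcol)
            if val is not None:
                observations[(cid, gcol.split("_", 1)[1])] = val
    return EnvelopeDataset(conditions=conditions, observations=observations)
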