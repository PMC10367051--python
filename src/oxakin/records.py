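"""Domain records and their file formats.

Record types
------------
``MoleculeGeometry``       atoms (symbol, mass/amu, Cartesian Å)
``FrequencySet``           signed harmonic wavenumbers in cm⁻¹ (negative =
                           imaginary) tagged with the stationary-point role
``EnergyComponents``       QM/MM, single-point and COSMO-RS energy pieces
``StationaryPointRecord``  one stationary point on a reaction surface
``TimeCourse``             assay or simulated concentrations vs time

File formats
------------
* XYZ (count / comment / ``El x y z`` lines) for geometries.
* A YAML record file with a top-level ``points`` list for stationary-point
  collections; energies may be given in kcal/mol (default) or hartree
  (converted on input by 627.509 kcal/mol per hartree).
* CSV for time courses with columns ``time_min, cpd8_uM, cpd6_uM, cpd4_uM``
  (additional ``*_uM`` columns are accepted).
* A tabular profile export with one row per stationary point and one column
  per protocol, values rounded to 0.1 kcal/mol.

Native quantum-chemistry program outputs (logs, checkpoints) are out of
scope; users supply extracted records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import HARTREE_TO_KCAL

__all__ = [
    "RecordError",
    "ParseError",
    "ValidationError",
    "MoleculeGeometry",
    "FrequencySet",
    "EnergyComponents",
    "StationaryPointRecord",
    "TimeCourse",
    "ATOMIC_MASSES",
    "MINIMUM",
    "TRANSITION_STATE",
    "read_xyz",
    "write_xyz",
    "read_stationary_points",
    "write_stationary_points",
    "read_time_course",
    "write_time_course",
    "write_profile_table",
]


class RecordError(ValueError):
    """Base class for record-level problems."""


class ParseError(RecordError):
    """A file does not conform to its documented schema."""


class ValidationError(RecordError):
    """A record violates a domain invariant."""


MINIMUM = "minimum"
TRANSITION_STATE = "transition_state"
_ROLES = (MINIMUM, TRANSITION_STATE)

# Standard atomic weights (amu) for the elements that occur in organic and
# bio-inorganic stationary points; extend as needed.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "He": 4.0026,
    "Li": 6.94, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078,
    "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546,
    "Zn": 65.38, "Br": 79.904, "I": 126.904,
}


def _check_role(role: str) -> str:
    if role not in _ROLES:
        raise ValidationError(f"unknown role {role!r}; expected one of {_ROLES}")
    return role


@dataclass(frozen=True)
class MoleculeGeometry:
    """Atoms with element symbols, masses (amu) and Cartesian coordinates (Å)."""

    symbols: tuple[str, ...]
    masses: tuple[float, ...]
    coords: np.ndarray  # shape (n_atoms, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = len(self.symbols)
        if n < 1:
            raise ValidationError("geometry needs at least one atom")
        if len(self.masses) != n or coords.shape != (n, 3):
            raise ValidationError("symbols, masses and coords must agree in length")
        if any(m <= 0 for m in self.masses):
            raise ValidationError("all atomic masses must be positive")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("all coordinates must be finite")

    @classmethod
    def from_symbols(cls, symbols: Sequence[str], coords) -> "MoleculeGeometry":
        """Build a geometry assigning masses from the built-in element table."""
        masses = []
        for sym in symbols:
            try:
                masses.append(ATOMIC_MASSES[sym])
            except KeyError:
                raise ParseError(f"unknown element symbol {sym!r}") from None
        return cls(tuple(symbols), tuple(masses), np.asarray(coords, dtype=float))

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def total_mass(self) -> float:
        """Total molecular mass in amu."""
        return float(sum(self.masses))


@dataclass(frozen=True)
class FrequencySet:
    """Signed vibrational wavenumbers in cm⁻¹; negative encodes imaginary.

    ``cleaned`` marks a set processed by :func:`oxakin.thermochem.clean_frequencies`
    (spurious imaginaries flipped, reactive mode removed for transition states).
    """

    wavenumbers: tuple[float, ...]
    role: str
    cleaned: bool = False

    def __post_init__(self) -> None:
        _check_role(self.role)
        wn = tuple(float(w) for w in self.wavenumbers)
        object.__setattr__(self, "wavenumbers", wn)
        if not wn and not self.cleaned:
            raise ValidationError("frequency set must be non-empty")
        if any(w == 0.0 or not math.isfinite(w) for w in wn):
            raise ValidationError("wavenumbers must be finite and nonzero")
        if self.cleaned and any(w < 0 for w in wn):
            raise ValidationError("a cleaned frequency set cannot contain imaginaries")

    @property
    def n_imaginary(self) -> int:
        return sum(1 for w in self.wavenumbers if w < 0)


_QMMM_FIELDS = ("e_qm_pchg", "e_mm123", "e_mm1")
_CRS_FIELDS = ("e_cosmo_inf", "delta_e_diel", "mu_chem")


@dataclass(frozen=True)
class EnergyComponents:
    """Energy pieces of one stationary point, all in kcal/mol.

    At least one of the three groups must be populated: the subtractive
    QM/MM triple, a protocol-tagged single-point energy, or the COSMO-RS
    triple (ε = ∞ energy, averaged dielectric correction, chemical potential).
    """

    e_qm_pchg: float | None = None
    e_mm123: float | None = None
    e_mm1: float | None = None
    single_point: Mapping[str, float] = field(default_factory=dict)
    e_cosmo_inf: float | None = None
    delta_e_diel: float | None = None
    mu_chem: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "single_point", dict(self.single_point))
        for name in _QMMM_FIELDS + _CRS_FIELDS:
            v = getattr(self, name)
            if v is not None and not math.isfinite(float(v)):
                raise ValidationError(f"energy component {name} must be finite")
        for tag, v in self.single_point.items():
            if not math.isfinite(float(v)):
                raise ValidationError(f"single-point energy {tag} must be finite")
        has_qmmm = all(getattr(self, f) is not None for f in _QMMM_FIELDS)
        has_crs = all(getattr(self, f) is not None for f in _CRS_FIELDS)
        if not (has_qmmm or has_crs or self.single_point):
            raise ValidationError(
                "at least one of the QM/MM triple, a single-point entry or the "
                "COSMO-RS triple must be populated"
            )

    def scaled(self, factor: float) -> "EnergyComponents":
        """Return a copy with every populated energy multiplied by *factor*."""
        def conv(v):
            return None if v is None else float(v) * factor
        return EnergyComponents(
            e_qm_pchg=conv(self.e_qm_pchg),
            e_mm123=conv(self.e_mm123),
            e_mm1=conv(self.e_mm1),
            single_point={k: float(v) * factor for k, v in self.single_point.items()},
            e_cosmo_inf=conv(self.e_cosmo_inf),
            delta_e_diel=conv(self.delta_e_diel),
            mu_chem=conv(self.mu_chem),
        )


@dataclass(frozen=True)
class StationaryPointRecord:
    """One stationary point (minimum or transition state) on a reaction surface."""

    label: str
    role: str
    energies: EnergyComponents
    geometry: MoleculeGeometry | None = None
    frequencies: FrequencySet | None = None
    symmetry_number: int = 1
    net_charge_note: str = ""

    def __post_init__(self) -> None:
        _check_role(self.role)
        if not self.label:
            raise ValidationError("record label must be non-empty")
        if self.symmetry_number < 1:
            raise ValidationError("symmetry number must be a positive integer")
        if self.frequencies is not None and self.frequencies.role != self.role:
            raise ValidationError(
                f"record {self.label}: frequency-set role {self.frequencies.role!r} "
                f"does not match record role {self.role!r}"
            )


@dataclass(frozen=True)
class TimeCourse:
    """Species concentrations (µM) tabulated against time (minutes)."""

    times: np.ndarray
    concentrations: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        conc = {k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()}
        object.__setattr__(self, "concentrations", conc)
        if times.ndim != 1 or times.size < 1:
            raise ValidationError("times must be a 1-D non-empty array")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")
        for name, series in conc.items():
            if series.shape != times.shape:
                raise ValidationError(f"series {name!r} length differs from times")
            if np.any(series < 0) or not np.all(np.isfinite(series)):
                raise ValidationError(f"series {name!r} must be finite and ≥ 0")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.concentrations)

    def initial(self, species: str) -> float:
        return float(self.concentrations[species][0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_min": self.times})
        for name, series in self.concentrations.items():
            df[f"{name}_uM"] = series
        return df


# ---------------------------------------------------------------------------
# XYZ geometries
# ---------------------------------------------------------------------------

def read_xyz(path) -> MoleculeGeometry:
    """Read a standard XYZ file (count, comment, ``El x y z`` records)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: first line must be the atom count") from None
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count:
        raise ParseError(
            f"{path}: header declares {count} atoms but {len(body)} atom lines found"
        )
    symbols, coords = [], []
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: malformed atom line {i + 3}: {ln!r}")
        symbols.append(parts[0])
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError:
            raise ParseError(f"{path}: non-numeric coordinate on line {i + 3}") from None
    return MoleculeGeometry.from_symbols(symbols, coords)


def write_xyz(geom: MoleculeGeometry, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{geom.n_atoms}\n{comment}\n")
        for sym, xyz in zip(geom.symbols, geom.coords):
            fh.write(f"{sym} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")


# ---------------------------------------------------------------------------
# Stationary-point record files (YAML schema)
# ---------------------------------------------------------------------------

def _energies_from_mapping(entry: Mapping, label: str) -> EnergyComponents:
    known = set(_QMMM_FIELDS) | set(_CRS_FIELDS) | {"single_point"}
    unknown = set(entry) - known
    if unknown:
        raise ParseError(f"entry {label!r}: unknown energy fields {sorted(unknown)}")
    try:
        return EnergyComponents(
            e_qm_pchg=entry.get("e_qm_pchg"),
            e_mm123=entry.get("e_mm123"),
            e_mm1=entry.get("e_mm1"),
            single_point=entry.get("single_point") or {},
            e_cosmo_inf=entry.get("e_cosmo_inf"),
            delta_e_diel=entry.get("delta_e_diel"),
            mu_chem=entry.get("mu_chem"),
        )
    except ValidationError as exc:
        raise ValidationError(f"entry {label!r}: {exc}") from None


def read_stationary_points(path, energy_unit: str = "kcal/mol") -> list[StationaryPointRecord]:
    """Read a YAML record file into a list of :class:`StationaryPointRecord`.

    ``energy_unit`` may be ``"kcal/mol"`` (default) or ``"hartree"``; hartree
    inputs are converted by 627.509 kcal/mol per hartree.  Labels must be
    unique within the file.
    """
    if energy_unit not in ("kcal/mol", "hartree"):
        raise ValueError(f"unsupported energy unit {energy_unit!r}")
    factor = HARTREE_TO_KCAL if energy_unit == "hartree" else 1.0
    if str(path).endswith(".csv"):
        return _read_stationary_points_csv(path, factor)
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: not valid YAML ({exc})") from None
    if not isinstance(doc, Mapping) or "points" not in doc:
        raise ParseError(f"{path}: expected a mapping with a top-level 'points' list")
    records: list[StationaryPointRecord] = []
    seen: set[str] = set()
    for i, entry in enumerate(doc["points"]):
        label = entry.get("label") if isinstance(entry, Mapping) else None
        where = f"{path} entry #{i + 1}" + (f" ({label})" if label else "")
        if not isinstance(entry, Mapping) or not label:
            raise ParseError(f"{where}: each point needs at least a 'label'")
        if label in seen:
            raise ValidationError(f"{path}: duplicate label {label!r}")
        seen.add(label)
        if "role" not in entry or "energies" not in entry:
            raise ParseError(f"{where}: 'role' and 'energies' are required")
        energies = _energies_from_mapping(entry["energies"], label)
        if factor != 1.0:
            energies = energies.scaled(factor)
        geometry = None
        if entry.get("geometry") is not None:
            rows = entry["geometry"]
            try:
                symbols = [r[0] for r in rows]
                coords = [[float(x) for x in r[1:4]] for r in rows]
            except (TypeError, ValueError, IndexError):
                raise ParseError(f"{where}: geometry rows must be [El, x, y, z]") from None
            geometry = MoleculeGeometry.from_symbols(symbols, coords)
        frequencies = None
        if entry.get("frequencies") is not None:
            frequencies = FrequencySet(
                tuple(float(w) for w in entry["frequencies"]),
                role=entry["role"],
                cleaned=bool(entry.get("frequencies_cleaned", False)),
            )
        try:
            records.append(
                StationaryPointRecord(
                    label=label,
                    role=entry["role"],
                    energies=energies,
                    geometry=geometry,
                    frequencies=frequencies,
                    symmetry_number=int(entry.get("symmetry_number", 1)),
                    net_charge_note=str(entry.get("net_charge_note", "")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from None
    return records


def _read_stationary_points_csv(path, factor: float) -> list[StationaryPointRecord]:
    """Energies-only CSV dialect: ``label, role`` plus energy columns.

    Columns named after QM/MM or COSMO-RS fields fill those; any other
    numeric column is treated as a protocol-tagged single-point energy.
    """
    df = pd.read_csv(path, comment="#")
    for required in ("label", "role"):
        if required not in df.columns:
            raise ParseError(f"{path}: missing required column {required!r}")
    direct = set(_QMMM_FIELDS) | set(_CRS_FIELDS)
    records: list[StationaryPointRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        label = str(row["label"])
        if label in seen:
            raise ValidationError(f"{path}: duplicate label {label!r}")
        seen.add(label)
        kwargs: dict = {}
        single_point: dict[str, float] = {}
        for col in df.columns:
            if col in ("label", "role") or pd.isna(row[col]):
                continue
            if col in direct:
                kwargs[col] = float(row[col]) * factor
            else:
                single_point[col] = float(row[col]) * factor
        try:
            energies = EnergyComponents(single_point=single_point, **kwargs)
            records.append(StationaryPointRecord(label, str(row["role"]), energies))
        except ValidationError as exc:
            raise ValidationError(f"{path} entry {label!r}: {exc}") from None
    return records


def _record_to_mapping(rec: StationaryPointRecord) -> dict:
    energies = {k: v for k, v in asdict(rec.energies).items() if v not in (None, {})}
    out: dict = {"label": rec.label, "role": rec.role, "energies": energies}
    if rec.geometry is not None:
        out["geometry"] = [
            [sym, float(x), float(y), float(z)]
            for sym, (x, y, z) in zip(rec.geometry.symbols, rec.geometry.coords)
        ]
    if rec.frequencies is not None:
        out["frequencies"] = list(rec.frequencies.wavenumbers)
        out["frequencies_cleaned"] = rec.frequencies.cleaned
    if rec.symmetry_number != 1:
        out["symmetry_number"] = rec.symmetry_number
    if rec.net_charge_note:
        out["net_charge_note"] = rec.net_charge_note
    return out


def write_stationary_points(records: Sequence[StationaryPointRecord], path) -> None:
    """Write records to the YAML record schema (kcal/mol, round-trip safe)."""
    doc = {"points": [_record_to_mapping(r) for r in records]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Time courses (CSV)
# ---------------------------------------------------------------------------

def read_time_course(path) -> TimeCourse:
    """Read a time-course CSV (``time_min`` plus ``<species>_uM`` columns)."""
    df = pd.read_csv(path, comment="#")
    if "time_min" not in df.columns:
        raise ParseError(f"{path}: missing required column 'time_min'")
    conc = {}
    for col in df.columns:
        if col.endswith("_uM"):
            conc[col[: -len("_uM")]] = df[col].to_numpy(dtype=float)
    if not conc:
        raise ParseError(f"{path}: no concentration columns ('*_uM') found")
    return TimeCourse(df["time_min"].to_numpy(dtype=float), conc)


def write_time_course(tc: TimeCourse, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        tc.to_frame().to_csv(fh, index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# Profile tables
# ---------------------------------------------------------------------------

def write_profile_table(profiles, path) -> pd.DataFrame:
    """Export profile(s) to a table: one row per stationary point, one column
    per protocol, kcal/mol rounded to 1 decimal.

    *profiles* is either a single profile object (anything exposing ``.points``
    with ``(label, role, g)`` entries) or a mapping ``protocol name → profile``.
    All profiles in a mapping must list the same labels in the same order.
    """
    if hasattr(profiles, "points"):
        profiles = {"G": profiles}
    if not profiles:
        raise ValidationError("no profiles to export")
    columns: dict[str, list[float]] = {}
    labels: list[str] | None = None
    for tag, prof in profiles.items():
        pts = list(prof.points)
        if not pts:
            raise ValidationError(f"profile {tag!r} is empty")
        these = [p.label for p in pts]
        if labels is None:
            labels = these
        elif these != labels:
            raise ValidationError("profiles disagree on stationary-point labels")
        columns[tag] = [round(float(p.g), 1) for p in pts]
    df = pd.DataFrame(columns, index=pd.Index(labels, name="system"))
    df.to_csv(path, float_format="%.1f")
    return df
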