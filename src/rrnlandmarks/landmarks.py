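"""Landmark vocabulary, case data model, configuration registry and file I/O.

The package works on 14 named craniomaxillofacial landmarks spread over three
bones: nine on the mandible (menton Me, gnathion Gn, pogonion Pg, B point B,
infradentale Id, coronoid left/right CorL/CorR, condylar left/right CdL/CdR),
four on the maxilla (ANS, A point, prosthion Pr, PNS) and one on the nasal
bones (nasion Na).  Positions are continuous triples in 0-based pixel space;
per-axis voxel spacing (mm/voxel) converts to anatomical millimetres only at
evaluation time.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Landmark",
    "BoneGroup",
    "VOCABULARY",
    "MANDIBULAR",
    "MAXILLARY",
    "NASAL",
    "LandmarkCase",
    "ConfigurationSpec",
    "CohortTable",
    "builtin_configuration",
    "BUILTIN_CONFIGURATIONS",
    "read_cases",
    "write_cases",
    "pixel_to_mm",
    "resolve_label",
    "load_alias_table",
    "ValidationError",
    "ConfigurationError",
    "FormatError",
    "DataError",
]


class ValidationError(ValueError):
    """Invalid value for a domain object."""


class ConfigurationError(ValueError):
    """Invalid or unknown landmark configuration."""


class FormatError(ValueError):
    """Unparseable input file."""


class DataError(ValueError):
    """Missing or inconsistent landmark data."""


class BoneGroup(enum.Enum):
    MANDIBLE = "mandible"
    MAXILLA = "maxilla"
    NASAL = "nasal"


class Landmark(enum.Enum):
    """The closed 14-member landmark vocabulary."""

    Me = "Me"
    Gn = "Gn"
    Pg = "Pg"
    B = "B"
    Id = "Id"
    CorL = "CorL"
    CorR = "CorR"
    CdL = "CdL"
    CdR = "CdR"
    ANS = "ANS"
    A = "A"
    Pr = "Pr"
    PNS = "PNS"
    Na = "Na"

    @property
    def symbol(self) -> str:
        return self.value

    @property
    def bone_group(self) -> BoneGroup:
        return _BONE_GROUP[self]

    def __repr__(self):
        return f"Landmark.{self.name}"


#: canonical vocabulary order; every ordered structure in the package uses it
VOCABULARY: Tuple[Landmark, ...] = tuple(Landmark)

MANDIBULAR = (Landmark.Me, Landmark.Gn, Landmark.Pg, Landmark.B, Landmark.Id,
              Landmark.CorL, Landmark.CorR, Landmark.CdL, Landmark.CdR)
MAXILLARY = (Landmark.ANS, Landmark.A, Landmark.Pr, Landmark.PNS)
NASAL = (Landmark.Na,)

_BONE_GROUP: Dict[Landmark, BoneGroup] = {}
_BONE_GROUP.update({lm: BoneGroup.MANDIBLE for lm in MANDIBULAR})
_BONE_GROUP.update({lm: BoneGroup.MAXILLA for lm in MAXILLARY})
_BONE_GROUP.update({lm: BoneGroup.NASAL for lm in NASAL})


# ---------------------------------------------------------------------------
# label resolution
# ---------------------------------------------------------------------------

_ALIAS_FILE = Path(__file__).with_name("alias_table.tsv")


def _normalize(label: str) -> str:
    return "".join(ch for ch in label.lower() if ch.isalnum())


def load_alias_table(extra: Optional[Path] = None) -> Dict[str, Landmark]:
    """Load the shipped alias table, optionally merged with a user file.

    The file format is TSV with two columns: alias, canonical symbol.  Lookup
    is case-insensitive and ignores spaces, hyphens and underscores.
    """
    table: Dict[str, Landmark] = {_normalize(lm.symbol): lm for lm in VOCABULARY}
    paths = [_ALIAS_FILE] + ([Path(extra)] if extra else [])
    for path in paths:
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            alias, symbol = line.split("\t")
            table[_normalize(alias)] = Landmark(symbol)
    return table


_DEFAULT_ALIASES: Optional[Dict[str, Landmark]] = None


def resolve_label(label: str, aliases: Optional[Mapping[str, Landmark]] = None
                  ) -> Optional[Landmark]:
    """Map a free-text landmark label onto the vocabulary; None if unknown."""
    global _DEFAULT_ALIASES
    if aliases is None:
        if _DEFAULT_ALIASES is None:
            _DEFAULT_ALIASES = load_alias_table()
        aliases = _DEFAULT_ALIASES
    return aliases.get(_normalize(label))


# ---------------------------------------------------------------------------
# core data types
# ---------------------------------------------------------------------------

@dataclass
class LandmarkCase:
    """One subject's named 3D landmark positions (pixel space) plus spacing."""

    case_id: str
    spacing: np.ndarray
    positions: Dict[Landmark, np.ndarray]
    annotation_source: str = ""
    derived_from: Tuple[str, ...] = ()

    def __post_init__(self):
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,):
            raise ValidationError(f"spacing must be a 3-vector, got {self.spacing!r}")
        if not np.all(self.spacing > 0):
            raise ValidationError(f"spacing must be strictly positive: {self.spacing}")
        clean: Dict[Landmark, np.ndarray] = {}
        for lm, pos in self.positions.items():
            if not isinstance(lm, Landmark):
                lm = Landmark(lm)
            if lm in clean:
                raise ValidationError(f"duplicate landmark {lm.symbol} in case {self.case_id}")
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (3,) or not np.all(np.isfinite(pos)):
                raise ValidationError(
                    f"position for {lm.symbol} in case {self.case_id} must be a finite 3-vector")
            clean[lm] = pos
        self.positions = clean

    @property
    def is_complete(self) -> bool:
        return len(self.positions) == len(VOCABULARY)

    @property
    def missing(self) -> Tuple[Landmark, ...]:
        return tuple(lm for lm in VOCABULARY if lm not in self.positions)

    def position_matrix(self, order: Sequence[Landmark] = VOCABULARY) -> np.ndarray:
        """Positions stacked in `order`; raises DataError on a missing landmark."""
        try:
            return np.stack([self.positions[lm] for lm in order])
        except KeyError as exc:
            raise DataError(f"case {self.case_id} is missing landmark {exc.args[0]}") from exc


@dataclass(frozen=True)
class ConfigurationSpec:
    """A named input/target partition of the landmark vocabulary.

    ``input_set`` (size n) is canonicalized to vocabulary order on
    construction so that relational-unit indexing — and therefore every
    prediction — is independent of the order a user lists the landmarks in.
    """

    name: str
    input_set: Tuple[Landmark, ...]
    target_set: Tuple[Landmark, ...]

    def __post_init__(self):
        inp = tuple(sorted(set(self.input_set), key=VOCABULARY.index))
        tgt = tuple(sorted(set(self.target_set), key=VOCABULARY.index))
        if len(inp) != len(self.input_set) or len(tgt) != len(self.target_set):
            raise ConfigurationError("duplicate landmarks in configuration")
        object.__setattr__(self, "input_set", inp)
        object.__setattr__(self, "target_set", tgt)
        if set(inp) & set(tgt):
            raise ConfigurationError("input and target sets must be disjoint")
        n, m = len(inp), len(tgt)
        if not (1 < n <= 13):
            raise ConfigurationError(f"need 1 < n <= 13 input landmarks, got n={n}")
        if m < 1:
            raise ConfigurationError("need at least one target landmark")
        if Landmark.Me not in inp:
            raise ConfigurationError("Me must be an input landmark (feature reference origin)")
        if sum(1 for lm in inp if lm.bone_group is BoneGroup.MANDIBLE) < 2:
            raise ConfigurationError(
                "need at least two mandibular input landmarks (mandible extent d1)")

    @property
    def n(self) -> int:
        return len(self.input_set)

    @property
    def m(self) -> int:
        return len(self.target_set)

    @property
    def mandibular_inputs(self) -> Tuple[Landmark, ...]:
        return tuple(lm for lm in self.input_set if lm.bone_group is BoneGroup.MANDIBLE)


@dataclass
class CohortTable:
    """A sequence of cases with a provenance tag (real/synthetic/augmented)."""

    cases: list
    provenance: str = "real"

    def __post_init__(self):
        ids = [c.case_id for c in self.cases]
        if len(ids) != len(set(ids)):
            raise ValidationError("case_ids must be unique within a cohort")

    def __len__(self):
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def by_id(self) -> Dict[str, LandmarkCase]:
        return {c.case_id: c for c in self.cases}


# ---------------------------------------------------------------------------
# built-in configurations
# ---------------------------------------------------------------------------

def _cfg(name: str, inputs: Iterable[Landmark]) -> ConfigurationSpec:
    inputs = tuple(inputs)
    targets = tuple(lm for lm in VOCABULARY if lm not in inputs)
    return ConfigurationSpec(name=name, input_set=inputs, target_set=targets)


BUILTIN_CONFIGURATIONS: Dict[str, ConfigurationSpec] = {
    "three-regular": _cfg("three-regular", (Landmark.Me, Landmark.CdL, Landmark.CdR)),
    "three-cross": _cfg("three-cross", (Landmark.Me, Landmark.CdR, Landmark.CorL)),
    "five": _cfg("five", (Landmark.Me, Landmark.CorL, Landmark.CorR,
                          Landmark.CdL, Landmark.CdR)),
    "six": _cfg("six", (Landmark.Me, Landmark.CorL, Landmark.CorR,
                        Landmark.CdL, Landmark.CdR, Landmark.Na)),
    "nine": _cfg("nine", MANDIBULAR),
}


def builtin_configuration(name: str) -> ConfigurationSpec:
    """Return one of the five built-in input/target partitions by name."""
    try:
        return BUILTIN_CONFIGURATIONS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown configuration {name!r}; available: "
            f"{sorted(BUILTIN_CONFIGURATIONS)}") from None


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def pixel_to_mm(position: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Convert pixel-space coordinates to millimetres (componentwise product)."""
    position = np.asarray(position, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    if not np.all(spacing > 0):
        raise ValidationError(f"spacing must be strictly positive: {spacing}")
    return position * spacing


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FCSV_HEADER = (
    "# Markups fiducial file version = 4.11\n"
    "# CoordinateSystem = 0\n"
    "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n"
)


def _write_fcsv_case(case: LandmarkCase, path: Path) -> None:
    lines = [_FCSV_HEADER.rstrip("\n")]
    lines.append("# spacing = %.9g,%.9g,%.9g" % tuple(case.spacing))
    if case.derived_from:
        lines.append("# derived_from = " + ";".join(case.derived_from))
    if case.annotation_source:
        lines.append("# annotation_source = " + case.annotation_source)
    for k, (lm, pos) in enumerate(case.positions.items(), 1):
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{k},{pos[0]:.9f},{pos[1]:.9f},{pos[2]:.9f},"
            f"0,0,0,1,1,1,0,{lm.symbol},,")
    path.write_text("\n".join(lines) + "\n")


def _read_fcsv_case(path: Path, spacing_override, aliases) -> LandmarkCase:
    spacing = None
    derived: Tuple[str, ...] = ()
    source = ""
    positions: Dict[Landmark, np.ndarray] = {}
    skipped = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("spacing"):
                spacing = np.array([float(x) for x in body.split("=")[1].split(",")])
            elif body.startswith("derived_from"):
                derived = tuple(x for x in body.split("=")[1].strip().split(";") if x)
            elif body.startswith("annotation_source"):
                source = body.split("=", 1)[1].strip()
            continue
        parts = line.split(",")
        if len(parts) < 12:
            raise FormatError(f"{path}: malformed FCSV row: {line!r}")
        try:
            xyz = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric coordinates in {line!r}") from exc
        lm = resolve_label(parts[11], aliases)
        if lm is None:
            skipped.append(parts[11])
            continue
        if lm in positions:
            raise ValidationError(f"{path}: duplicate landmark label {parts[11]!r}")
        positions[lm] = xyz
    if spacing_override is not None:
        spacing = np.asarray(spacing_override, dtype=float)
    if spacing is None:
        raise FormatError(
            f"{path}: no '# spacing = sx,sy,sz' comment and no spacing override given")
    case = LandmarkCase(case_id=path.stem, spacing=spacing, positions=positions,
                        annotation_source=source, derived_from=derived)
    if skipped:
        case.annotation_source = (case.annotation_source +
                                  f" [skipped labels: {', '.join(skipped)}]").strip()
    return case


def read_cases(path, format: str, spacing_override=None, aliases=None,
               provenance: str = "real") -> CohortTable:
    """Read a cohort from FCSV (file or directory of files), CSV or JSON.

    Unknown landmark labels are skipped and noted on the case; a duplicate
    label within one case is a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "fcsv":
        files = sorted(path.glob("*.fcsv")) if path.is_dir() else [path]
        if not files:
            raise FormatError(f"no .fcsv files under {path}")
        cases = [_read_fcsv_case(f, spacing_override, aliases) for f in files]
        return CohortTable(cases=cases, provenance=provenance)
    if format == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
        required = {"case_id", "label", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise FormatError(f"CSV {path} must have columns {sorted(required)}")
        cases = []
        for cid, group in df.groupby("case_id", sort=True):
            positions: Dict[Landmark, np.ndarray] = {}
            skipped = []
            for _, row in group.iterrows():
                lm = resolve_label(str(row["label"]), aliases)
                if lm is None:
                    skipped.append(str(row["label"]))
                    continue
                if lm in positions:
                    raise ValidationError(f"case {cid}: duplicate label {row['label']!r}")
                positions[lm] = np.array([row["x"], row["y"], row["z"]], dtype=float)
            if spacing_override is not None:
                spacing = np.asarray(spacing_override, dtype=float)
            elif {"sx", "sy", "sz"}.issubset(group.columns) and not group[["sx", "sy", "sz"]].isna().any().any():
                spacing = group[["sx", "sy", "sz"]].iloc[0].to_numpy(dtype=float)
            else:
                raise FormatError(f"case {cid}: no spacing columns and no override")
            derived = ()
            if "derived_from" in group.columns:
                val = group["derived_from"].iloc[0]
                if isinstance(val, str) and val:
                    derived = tuple(val.split(";"))
            source = ""
            if skipped:
                source = f"[skipped labels: {', '.join(skipped)}]"
            cases.append(LandmarkCase(case_id=str(cid), spacing=spacing,
                                      positions=positions, annotation_source=source,
                                      derived_from=derived))
        return CohortTable(cases=cases, provenance=provenance)
    if format == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"cannot parse JSON {path}: {exc}") from exc
        cases = []
        for rec in payload["cases"]:
            positions = {}
            skipped = []
            for label, xyz in rec["positions"].items():
                lm = resolve_label(label, aliases)
                if lm is None:
                    skipped.append(label)
                    continue
                if lm in positions:
                    raise ValidationError(f"case {rec['case_id']}: duplicate label {label!r}")
                positions[lm] = np.asarray(xyz, dtype=float)
            spacing = (np.asarray(spacing_override, dtype=float)
                       if spacing_override is not None
                       else np.asarray(rec["spacing"], dtype=float))
            source = rec.get("annotation_source", "")
            if skipped:
                source = (source + f" [skipped labels: {', '.join(skipped)}]").strip()
            cases.append(LandmarkCase(
                case_id=rec["case_id"], spacing=spacing, positions=positions,
                annotation_source=source,
                derived_from=tuple(rec.get("derived_from", ()))))
        return CohortTable(cases=cases, provenance=payload.get("provenance", provenance))
    raise FormatError(f"unknown format {format!r}; expected fcsv, csv or json")


def write_cases(cohort: CohortTable, path, format: str) -> None:
    """Write a cohort to FCSV (one file per case in a directory), CSV or JSON."""
    if len(cohort) == 0:
        raise ValidationError("cannot write an empty cohort")
    path = Path(path)
    if format == "fcsv":
        path.mkdir(parents=True, exist_ok=True)
        for case in cohort:
            _write_fcsv_case(case, path / f"{case.case_id}.fcsv")
        return
    if format == "csv":
        rows = []
        for case in cohort:
            for lm, pos in case.positions.items():
                rows.append({
                    "case_id": case.case_id, "label": lm.symbol,
                    "x": pos[0], "y": pos[1], "z": pos[2],
                    "sx": case.spacing[0], "sy": case.spacing[1], "sz": case.spacing[2],
                    "derived_from": ";".join(case.derived_from),
                })
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9f")
        return
    if format == "json":
        payload = {
            "provenance": cohort.provenance,
            "cases": [
                {
                    "case_id": c.case_id,
                    "spacing": [float(s) for s in c.spacing],
                    "positions": {lm.symbol: [float(v) for v in pos]
                                  for lm, pos in c.positions.items()},
                    "annotation_source": c.annotation_source,
                    "derived_from": list(c.derived_from),
                }
                for c in cohort
            ],
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=1))
        return
    raise FormatError(f"unknown format {format!r}; expected fcsv, csv or json")
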