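"""Anatomical character data: concordance matrices, weights, validation, I/O.

The data model is a species x muscle x parameter table of relative-frequency
(RF) concordance scores in [0, 1].  An RF of 1 means the comparison species
shows the reference pattern for that parameter; 0 means the parameter is
absent or fully divergent; fractional values encode partial or polymorphic
concordance.  Four parameters are scored per muscle -- innervation, origin,
insertion and vascularization -- each carrying a pondered weight reflecting
its phylogenetic stability.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ParameterKind",
    "WeightScheme",
    "VariationRecord",
    "ConcordanceVector",
    "CharacterMatrix",
    "InvalidSampleError",
    "relative_frequency",
    "validate_matrix",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_matrix_json",
    "write_matrix_json",
]


class ParameterKind(str, enum.Enum):
    """The four scored anatomical parameters, in canonical display order."""

    INNERVATION = "innervation"
    ORIGIN = "origin"
    INSERTION = "insertion"
    VASCULARIZATION = "vascularization"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical parameter order for display, serialization and random draws.
PARAMETER_ORDER: tuple[ParameterKind, ...] = (
    ParameterKind.INNERVATION,
    ParameterKind.ORIGIN,
    ParameterKind.INSERTION,
    ParameterKind.VASCULARIZATION,
)


class InvalidSampleError(ValueError):
    """Raised for a variation record with no specimens."""


@dataclass(frozen=True)
class WeightScheme:
    """Pondered weights per parameter.

    The default scheme weighs innervation 3, origin 2, insertion 2 and
    vascularization 1 (total 8): the most phylogenetically stable parameter
    carries the largest weight, so a divergence there moves the index most.
    """

    weights: Mapping[ParameterKind, float] = field(
        default_factory=lambda: {
            ParameterKind.INNERVATION: 3.0,
            ParameterKind.ORIGIN: 2.0,
            ParameterKind.INSERTION: 2.0,
            ParameterKind.VASCULARIZATION: 1.0,
        }
    )

    def __post_init__(self) -> None:
        for kind, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"weight for {kind} must be positive, got {w}")

    @property
    def total(self) -> float:
        return float(sum(self.weights.values()))


DEFAULT_WEIGHTS = WeightScheme()


@dataclass(frozen=True)
class VariationRecord:
    """Specimen counts behind an intra-species RF: N specimens, nv variants."""

    n_total: int
    n_variant: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_variant < 0:
            raise ValueError("specimen counts must be non-negative")
        if self.n_variant > self.n_total:
            raise ValueError(
                f"n_variant ({self.n_variant}) exceeds n_total ({self.n_total})"
            )


def relative_frequency(record: VariationRecord) -> float:
    """RF = (N - nv) / N, the fraction of specimens showing the normal pattern.

    Raises
    ------
    InvalidSampleError
        If the record has zero specimens.
    """
    if record.n_total == 0:
        raise InvalidSampleError("relative frequency undefined for N = 0")
    return (record.n_total - record.n_variant) / record.n_total


@dataclass(frozen=True)
class ConcordanceVector:
    """Per-parameter RF concordance for one (species, muscle) cell.

    ``absent_muscle`` marks a muscle scored as nonexistent in the species;
    all four RF values are then 0 by convention, which yields the maximal
    CAI of 1 against an all-concordant reference.
    """

    rf: Mapping[ParameterKind, float]
    absent_muscle: bool = False

    @classmethod
    def from_values(
        cls,
        innervation: float,
        origin: float,
        insertion: float,
        vascularization: float,
        absent_muscle: bool = False,
    ) -> "ConcordanceVector":
        return cls(
            rf={
                ParameterKind.INNERVATION: innervation,
                ParameterKind.ORIGIN: origin,
                ParameterKind.INSERTION: insertion,
                ParameterKind.VASCULARIZATION: vascularization,
            },
            absent_muscle=absent_muscle,
        )

    @classmethod
    def concordant(cls) -> "ConcordanceVector":
        """All-1 vector: the pattern is identical to the reference."""
        return cls.from_values(1.0, 1.0, 1.0, 1.0)

    @classmethod
    def absent(cls) -> "ConcordanceVector":
        """All-0 vector for a muscle considered inexistent."""
        return cls.from_values(0.0, 0.0, 0.0, 0.0, absent_muscle=True)

    def values(self) -> tuple[float, ...]:
        return tuple(self.rf[k] for k in PARAMETER_ORDER)


@dataclass
class CharacterMatrix:
    """A full character matrix: species, muscles with group labels, cells.

    Parameters
    ----------
    species
        Ordered species labels; must include ``reference``.
    reference
        The species every comparison is made against.  Its cells must be
        all-concordant (RF = 1 everywhere it possesses the muscle).
    muscles
        Ordered ``(muscle, group)`` pairs.
    entries
        ``(species, muscle) -> ConcordanceVector`` for every pair.
    cai_overrides
        Optional ``(species, muscle) -> CAI`` values that take precedence
        over the computed index, for cells whose published index is not
        reconstructible from a stated RF decomposition.
    """

    species: list[str]
    reference: str
    muscles: list[tuple[str, str]]
    entries: dict[tuple[str, str], ConcordanceVector]
    cai_overrides: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def muscle_names(self) -> list[str]:
        return [m for m, _ in self.muscles]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for _, g in self.muscles:
            if g not in seen:
                seen.append(g)
        return seen

    def group_of(self, muscle: str) -> str:
        for m, g in self.muscles:
            if m == muscle:
                return g
        raise KeyError(f"unknown muscle: {muscle!r}")

    def muscles_in_group(self, group: str) -> list[str]:
        return [m for m, g in self.muscles if g == group]

    def comparison_species(self) -> list[str]:
        return [s for s in self.species if s != self.reference]

    def subset(
        self,
        species: Iterable[str] | None = None,
        muscles: Iterable[str] | None = None,
        groups: Iterable[str] | None = None,
    ) -> "CharacterMatrix":
        """Restrict to the given species and/or muscles (or whole groups)."""
        keep_sp = list(species) if species is not None else list(self.species)
        if muscles is not None:
            keep_mu = set(muscles)
        elif groups is not None:
            gset = set(groups)
            keep_mu = {m for m, g in self.muscles if g in gset}
        else:
            keep_mu = set(self.muscle_names)
        new_muscles = [(m, g) for m, g in self.muscles if m in keep_mu]
        new_entries = {
            (s, m): v
            for (s, m), v in self.entries.items()
            if s in keep_sp and m in keep_mu
        }
        new_overrides = {
            (s, m): v
            for (s, m), v in self.cai_overrides.items()
            if s in keep_sp and m in keep_mu
        }
        return CharacterMatrix(
            species=keep_sp,
            reference=self.reference,
            muscles=new_muscles,
            entries=new_entries,
            cai_overrides=new_overrides,
        )


def validate_matrix(matrix: CharacterMatrix) -> list[str]:
    """Check every structural invariant; return a description per violation.

    An empty list means the matrix is valid.  Violations name the offending
    (species, muscle, parameter) so they can be fixed in the source table.
    """
    violations: list[str] = []
    if matrix.reference not in matrix.species:
        violations.append(
            f"reference species {matrix.reference!r} not in species list"
        )
    names = matrix.muscle_names
    if len(set(names)) != len(names):
        violations.append("duplicate muscle names in muscle list")
    for sp in matrix.species:
        for muscle in names:
            vec = matrix.entries.get((sp, muscle))
            if vec is None:
                violations.append(
                    f"missing entry for species={sp!r} muscle={muscle!r}"
                )
                continue
            for kind in PARAMETER_ORDER:
                if kind not in vec.rf:
                    violations.append(
                        f"species={sp!r} muscle={muscle!r} "
                        f"parameter={kind.value}: RF missing"
                    )
                    continue
                rf = vec.rf[kind]
                if not 0.0 <= rf <= 1.0:
                    violations.append(
                        f"species={sp!r} muscle={muscle!r} "
                        f"parameter={kind.value}: RF={rf} outside [0, 1]"
                    )
                elif vec.absent_muscle and rf != 0.0:
                    violations.append(
                        f"species={sp!r} muscle={muscle!r} "
                        f"parameter={kind.value}: RF={rf} nonzero for an "
                        "absent muscle"
                    )
                elif sp == matrix.reference and not vec.absent_muscle and rf != 1.0:
                    violations.append(
                        f"species={sp!r} muscle={muscle!r} "
                        f"parameter={kind.value}: reference RF={rf} != 1"
                    )
    for (sp, muscle), value in matrix.cai_overrides.items():
        if not 0.0 <= value <= 1.0:
            violations.append(
                f"species={sp!r} muscle={muscle!r}: CAI override {value} "
                "outside [0, 1]"
            )
    return violations


# ---------------------------------------------------------------------------
# Serialization.  CSV is long form, one row per (species, muscle, parameter);
# JSON mirrors CharacterMatrix field-for-field.  Both round-trip losslessly.
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["species", "muscle", "group", "parameter", "rf", "absent", "cai_override"]


def _matrix_rows(matrix: CharacterMatrix):
    for sp in matrix.species:
        for muscle, group in matrix.muscles:
            vec = matrix.entries[(sp, muscle)]
            override = matrix.cai_overrides.get((sp, muscle))
            for kind in PARAMETER_ORDER:
                yield {
                    "species": sp,
                    "muscle": muscle,
                    "group": group,
                    "parameter": kind.value,
                    "rf": vec.rf[kind],
                    "absent": vec.absent_muscle,
                    "cai_override": override,
                }


def matrix_to_frame(matrix: CharacterMatrix) -> pd.DataFrame:
    """Long-form DataFrame in the CSV dialect's column order."""
    return pd.DataFrame(_matrix_rows(matrix), columns=CSV_COLUMNS)


def frame_to_matrix(frame: pd.DataFrame, reference: str) -> CharacterMatrix:
    missing = set(CSV_COLUMNS) - {"cai_override"} - set(frame.columns)
    if missing:
        raise ValueError(f"character-matrix table missing columns: {sorted(missing)}")
    species = list(dict.fromkeys(frame["species"]))
    muscles: list[tuple[str, str]] = []
    for muscle, group in zip(frame["muscle"], frame["group"]):
        if (muscle, group) not in muscles:
            muscles.append((muscle, group))
    entries: dict[tuple[str, str], ConcordanceVector] = {}
    overrides: dict[tuple[str, str], float] = {}
    for (sp, muscle), cell in frame.groupby(["species", "muscle"], sort=False):
        rf = {
            ParameterKind(row.parameter): float(row.rf)
            for row in cell.itertuples()
        }
        absent = bool(cell["absent"].iloc[0])
        entries[(sp, muscle)] = ConcordanceVector(rf=rf, absent_muscle=absent)
        if "cai_override" in cell.columns:
            ov = cell["cai_override"].iloc[0]
            if pd.notna(ov):
                overrides[(sp, muscle)] = float(ov)
    return CharacterMatrix(
        species=species,
        reference=reference,
        muscles=muscles,
        entries=entries,
        cai_overrides=overrides,
    )


def write_matrix_csv(matrix: CharacterMatrix, path: str | Path) -> None:
    matrix_to_frame(matrix).to_csv(path, index=False)


def read_matrix_csv(path: str | Path, reference: str) -> CharacterMatrix:
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # keep the line number in the message
        raise ValueError(f"malformed character-matrix CSV {path}: {exc}") from exc
    if frame.empty:
        raise ValueError(f"character-matrix CSV {path} contains no data rows")
    return frame_to_matrix(frame, reference=reference)


def matrix_to_dict(matrix: CharacterMatrix) -> dict:
    return {
        "species": matrix.species,
        "reference": matrix.reference,
        "muscles": [{"muscle": m, "group": g} for m, g in matrix.muscles],
        "entries": [
            {
                "species": sp,
                "muscle": muscle,
                "absent": vec.absent_muscle,
                "rf": {k.value: vec.rf[k] for k in PARAMETER_ORDER},
            }
            for (sp, muscle), vec in matrix.entries.items()
        ],
        "cai_overrides": [
            {"species": sp, "muscle": muscle, "cai": value}
            for (sp, muscle), value in matrix.cai_overrides.items()
        ],
    }


def matrix_from_dict(payload: dict) -> CharacterMatrix:
    entries = {
        (e["species"], e["muscle"]): ConcordanceVector(
            rf={ParameterKind(k): float(v) for k, v in e["rf"].items()},
            absent_muscle=bool(e.get("absent", False)),
        )
        for e in payload["entries"]
    }
    overrides = {
        (o["species"], o["muscle"]): float(o["cai"])
        for o in payload.get("cai_overrides", [])
    }
    return CharacterMatrix(
        species=list(payload["species"]),
        reference=payload["reference"],
        muscles=[(m["muscle"], m["group"]) for m in payload["muscles"]],
        entries=entries,
        cai_overrides=overrides,
    )


def write_matrix_json(matrix: CharacterMatrix, path: str | Path) -> None:
    Path(path).write_text(json.dumps(matrix_to_dict(matrix), indent=2))


def read_matrix_json(path: str | Path) -> CharacterMatrix:
    return matrix_from_dict(json.loads(Path(path).read_text()))
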