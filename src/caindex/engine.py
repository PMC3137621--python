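"""The similarity statistic: PAF, CAI, similarity bands, GCAI.

For one muscle in one species, the Pondered Average of Frequencies (PAF) is
the weight-normalized mean of the four per-parameter RF concordance scores:

    PAF = sum_i(w_i * RF_i) / sum_i(w_i)

The Comparative Anatomy Index (CAI) between two species for the same muscle
is the absolute PAF difference, so CAI = 0 means indistinguishable under the
scored parameters and CAI = 1 means maximal divergence (e.g. the muscle is
absent in one species).  Group CAI (GCAI) is the arithmetic mean of the
member muscles' CAIs.  CAI values are classified into similarity bands:
0 exactly is "highly similar", (0, 0.200] "similar", (0.200, 0.650]
"somewhat similar", (0.650, 1] "dissimilar".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .trait_matrix import (
    PARAMETER_ORDER,
    CharacterMatrix,
    ConcordanceVector,
    ParameterKind,
    WeightScheme,
)

__all__ = [
    "SimilarityBand",
    "MuscleSimilarity",
    "GroupSimilarity",
    "AdjustmentSpec",
    "SchemeMismatchError",
    "OverrideConflictError",
    "paf",
    "cai",
    "classify_cai",
    "apply_variability_adjustment",
    "muscle_similarity",
    "group_similarity",
    "pairwise_distance_matrix",
    "round_half_up",
]

#: Tolerance applied at band knots so eighths computed in floating point
#: classify the same way as their exact rational values.
KNOT_TOL = 1e-9


class SchemeMismatchError(ValueError):
    """Parameter sets of a concordance vector and weight scheme disagree."""


class OverrideConflictError(ValueError):
    """A CAI override (defined vs the reference) blocks a non-reference pair."""


class SimilarityBand(enum.IntEnum):
    """Ordered similarity bands; lower value = more similar."""

    HIGHLY_SIMILAR = 0
    SIMILAR = 1
    SOMEWHAT_SIMILAR = 2
    DISSIMILAR = 3

    @property
    def label(self) -> str:
        return {
            SimilarityBand.HIGHLY_SIMILAR: "highly similar",
            SimilarityBand.SIMILAR: "similar",
            SimilarityBand.SOMEWHAT_SIMILAR: "somewhat similar",
            SimilarityBand.DISSIMILAR: "dissimilar",
        }[self]


def round_half_up(value: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def paf(vector: ConcordanceVector, scheme: WeightScheme) -> float:
    """Pondered Average of Frequencies for one (species, muscle) cell.

    The weighted sum is accumulated first and divided once, so that with the
    default integer weights eighths stay exact in binary floating point.
    """
    vec_keys = set(vector.rf)
    scheme_keys = set(scheme.weights)
    if vec_keys != scheme_keys:
        raise SchemeMismatchError(
            f"parameters {sorted(k.value for k in vec_keys ^ scheme_keys)} "
            "not shared between vector and weight scheme"
        )
    num = sum(scheme.weights[k] * vector.rf[k] for k in PARAMETER_ORDER if k in vec_keys)
    return num / scheme.total


def cai(paf_a: float, paf_b: float) -> float:
    """Comparative Anatomy Index: |PAF_a - PAF_b|."""
    for v in (paf_a, paf_b):
        if not -KNOT_TOL <= v <= 1.0 + KNOT_TOL:
            raise ValueError(f"PAF {v} outside [0, 1]")
    return abs(paf_a - paf_b)


def classify_cai(cai_value: float) -> SimilarityBand:
    """Map a CAI value to its similarity band (upper-closed intervals)."""
    if not -KNOT_TOL <= cai_value <= 1.0 + KNOT_TOL:
        raise ValueError(f"CAI {cai_value} outside [0, 1]")
    if abs(cai_value) <= KNOT_TOL:
        return SimilarityBand.HIGHLY_SIMILAR
    if cai_value <= 0.200 + KNOT_TOL:
        return SimilarityBand.SIMILAR
    if cai_value <= 0.650 + KNOT_TOL:
        return SimilarityBand.SOMEWHAT_SIMILAR
    return SimilarityBand.DISSIMILAR


@dataclass(frozen=True)
class AdjustmentSpec:
    """Fractional RF decreases applied to a variable/polymorphic structure.

    A decrease of 0.1 on innervation multiplies that RF by 0.9.  The study
    convention for a highly variable muscle is a 10% decrease on innervation
    and vascularization and 50% on origin and insertion, reflecting where
    the variation concentrates.
    """

    decreases: Mapping[ParameterKind, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kind, d in self.decreases.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"decrease for {kind} must be in [0, 1], got {d}")


def apply_variability_adjustment(
    vector: ConcordanceVector, adj: AdjustmentSpec
) -> ConcordanceVector:
    """Scale each RF_i by (1 - decrease_i); parameters without a decrease pass through."""
    new_rf = {
        kind: rf * (1.0 - adj.decreases.get(kind, 0.0))
        for kind, rf in vector.rf.items()
    }
    return ConcordanceVector(rf=new_rf, absent_muscle=vector.absent_muscle)


@dataclass(frozen=True)
class MuscleSimilarity:
    """CAI result for one muscle between the reference and one comparison."""

    muscle: str
    species_pair: tuple[str, str]
    paf_reference: float
    paf_comparison: float
    cai: float
    band: SimilarityBand
    from_override: bool = False


@dataclass(frozen=True)
class GroupSimilarity:
    """GCAI result for a muscle group between the reference and one comparison."""

    group: str
    species_pair: tuple[str, str]
    member_cais: tuple[tuple[str, float], ...]
    gcai: float
    band: SimilarityBand


def _lookup_vector(matrix: CharacterMatrix, species: str, muscle: str) -> ConcordanceVector:
    if species not in matrix.species:
        raise KeyError(f"unknown species: {species!r}")
    if muscle not in matrix.muscle_names:
        raise KeyError(f"unknown muscle: {muscle!r}")
    return matrix.entries[(species, muscle)]


def muscle_similarity(
    matrix: CharacterMatrix,
    muscle: str,
    comparison: str,
    scheme: WeightScheme | None = None,
) -> MuscleSimilarity:
    """Score one muscle between the matrix's reference and a comparison species.

    If the matrix carries a CAI override for the cell, the published value is
    used verbatim and the result is flagged ``from_override``; the PAF pair
    reported alongside is still computed from the stored RF vectors.
    """
    scheme = scheme or WeightScheme()
    ref_vec = _lookup_vector(matrix, matrix.reference, muscle)
    cmp_vec = _lookup_vector(matrix, comparison, muscle)
    paf_ref = paf(ref_vec, scheme)
    paf_cmp = paf(cmp_vec, scheme)
    override = matrix.cai_overrides.get((comparison, muscle))
    if override is not None:
        value = float(override)
        from_override = True
    else:
        value = cai(paf_ref, paf_cmp)
        from_override = False
    return MuscleSimilarity(
        muscle=muscle,
        species_pair=(matrix.reference, comparison),
        paf_reference=paf_ref,
        paf_comparison=paf_cmp,
        cai=value,
        band=classify_cai(value),
        from_override=from_override,
    )


def group_similarity(
    matrix: CharacterMatrix,
    group: str,
    comparison: str,
    scheme: WeightScheme | None = None,
) -> GroupSimilarity:
    """GCAI: arithmetic mean of member-muscle CAIs, in matrix muscle order."""
    members = matrix.muscles_in_group(group)
    if not members:
        raise ValueError(f"group {group!r} contains no muscles")
    sims = [muscle_similarity(matrix, m, comparison, scheme) for m in members]
    values = [s.cai for s in sims]
    gcai = float(np.mean(values))
    return GroupSimilarity(
        group=group,
        species_pair=(matrix.reference, comparison),
        member_cais=tuple((s.muscle, s.cai) for s in sims),
        gcai=gcai,
        band=classify_cai(gcai),
    )


def pairwise_distance_matrix(
    matrix: CharacterMatrix,
    scheme: WeightScheme | None = None,
    level: str | None = None,
    *,
    ignore_overrides: bool = False,
) -> pd.DataFrame:
    """All-pairs CAI distances over every species in the matrix.

    ``level`` names either a single muscle (distance = |PAF_a - PAF_b|) or a
    group (distance = mean over member muscles of |PAF_a - PAF_b|); ``None``
    averages over every muscle in the matrix.  Because CAI overrides are
    published only relative to the reference species, any override touching
    the selected muscles makes non-reference pairs undefined; this raises
    :class:`OverrideConflictError` unless ``ignore_overrides`` is set, in
    which case distances are recomputed from the stored RF vectors.
    """
    scheme = scheme or WeightScheme()
    if len(matrix.species) < 2:
        raise ValueError("pairwise distances need at least 2 species")
    if level is None:
        members = matrix.muscle_names
    elif level in matrix.muscle_names:
        members = [level]
    elif level in matrix.groups:
        members = matrix.muscles_in_group(level)
    else:
        raise KeyError(f"unknown muscle or group: {level!r}")
    if not ignore_overrides:
        offending = [
            (sp, m) for (sp, m) in matrix.cai_overrides if m in set(members)
        ]
        if offending:
            raise OverrideConflictError(
                "CAI overrides are defined only against the reference and "
                f"block all-pairs distances for cells {offending}; pass "
                "ignore_overrides=True to use the stored RF vectors instead"
            )
    pafs = {
        sp: [paf(matrix.entries[(sp, m)], scheme) for m in members]
        for sp in matrix.species
    }
    n = len(matrix.species)
    out = np.zeros((n, n))
    for i, a in enumerate(matrix.species):
        for j, b in enumerate(matrix.species):
            if i < j:
                d = float(
                    np.mean([abs(x - y) for x, y in zip(pafs[a], pafs[b])])
                )
                out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=matrix.species, columns=matrix.species)
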