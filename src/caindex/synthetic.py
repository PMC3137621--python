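"""Synthetic character matrices with known divergence structure.

The generator emulates the statistical shape of the study data: one
reference species whose traits are all concordant, and comparison species
whose parameters diverge independently.  Per (species, muscle, parameter)
cell, with probability ``flip_probs[parameter]`` the trait diverges: fully
(RF = 0) or, with probability ``partial_prob``, partially (RF drawn
uniformly in the open unit interval).  A non-divergent cell still carries
specimen-level intra-species variation: RF = (N - nv)/N with
nv ~ Binomial(n_specimens, variation_prob), mirroring how fractional RF
arises from real specimen samples.

Because a divergence with RF = 0 on parameter i shifts the PAF by
w_i / sum(w), the mean CAI against the reference has the closed form
sum_i(w_i * q_i) / sum_i(w_i) with q_i the per-parameter expected RF
deficit; :func:`expected_cai` evaluates it, and :func:`recover_flip_probs`
inverts a batch of generated matrices back to flip-probability estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trait_matrix import (
    PARAMETER_ORDER,
    CharacterMatrix,
    ConcordanceVector,
    ParameterKind,
    WeightScheme,
)

__all__ = ["SyntheticSpec", "generate_matrix", "expected_cai", "recover_flip_probs"]


def _default_flip_probs() -> dict[ParameterKind, float]:
    # Less stable parameters diverge more often, inverting the weight order.
    return {
        ParameterKind.INNERVATION: 0.05,
        ParameterKind.ORIGIN: 0.15,
        ParameterKind.INSERTION: 0.15,
        ParameterKind.VASCULARIZATION: 0.30,
    }


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    Defaults mirror the study's scale: three comparison species, forearm-
    sized muscle groups, eight specimens per species, a 10% per-specimen
    variation rate (the human palmaris-longus absence rate), and divergence
    probabilities ordered inversely to the parameters' pondered weights.
    """

    n_species: int = 3
    n_muscles: int = 5
    n_groups: int = 1
    flip_probs: Mapping[ParameterKind, float] = field(default_factory=_default_flip_probs)
    partial_prob: float = 0.2
    n_specimens: int = 8
    variation_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_muscles < 1 or self.n_groups < 1:
            raise ValueError("species, muscle and group counts must be positive")
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be positive")
        probs = [self.partial_prob, self.variation_prob, *self.flip_probs.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")


def generate_matrix(spec: SyntheticSpec) -> CharacterMatrix:
    """Draw one character matrix under ``spec``; deterministic given its seed.

    A single stream seeded once is consumed in fixed order -- species-major,
    muscle-minor, parameters in canonical order, with per-cell draws in the
    sequence (flip?, partial?, value) -- so output is reproducible across
    platforms.
    """
    rng = np.random.default_rng(spec.seed)
    species = ["reference"] + [f"sp{i + 1:02d}" for i in range(spec.n_species)]
    muscles = [
        (f"muscle{i + 1:02d}", f"group{i // spec.n_muscles + 1}")
        for i in range(spec.n_muscles * spec.n_groups)
    ]
    entries: dict[tuple[str, str], ConcordanceVector] = {
        ("reference", m): ConcordanceVector.concordant() for m, _ in muscles
    }
    for sp in species[1:]:
        for muscle, _ in muscles:
            rf: dict[ParameterKind, float] = {}
            for kind in PARAMETER_ORDER:
                if rng.random() < spec.flip_probs.get(kind, 0.0):
                    if rng.random() < spec.partial_prob:
                        u = rng.random()
                        rf[kind] = u if u > 0.0 else 0.5  # open (0, 1)
                    else:
                        rf[kind] = 0.0
                else:
                    nv = rng.binomial(spec.n_specimens, spec.variation_prob)
                    rf[kind] = (spec.n_specimens - nv) / spec.n_specimens
            entries[(sp, muscle)] = ConcordanceVector(rf=rf)
    return CharacterMatrix(
        species=species,
        reference="reference",
        muscles=muscles,
        entries=entries,
    )


def expected_cai(
    flip_probs: Mapping[ParameterKind, float],
    scheme: WeightScheme | None = None,
    variation_prob: float = 0.0,
) -> float:
    """Exact mean CAI versus the reference under the full-flip model.

    With partial divergence off, RF_i is 0 with probability p_i and
    otherwise (1 - variation_prob) in expectation, so the expected PAF
    deficit -- and hence the expected CAI, since every deficit is one-sided
    -- is sum_i(w_i * (1 - (1 - p_i)(1 - v))) / sum_i(w_i).  At v = 0 this
    reduces to sum_i(w_i * p_i) / sum_i(w_i).
    """
    scheme = scheme or WeightScheme()
    num = sum(
        w * (1.0 - (1.0 - flip_probs.get(kind, 0.0)) * (1.0 - variation_prob))
        for kind, w in scheme.weights.items()
    )
    return num / scheme.total


def recover_flip_probs(
    matrices: Sequence[CharacterMatrix],
    scheme: WeightScheme | None = None,
) -> dict[ParameterKind, float]:
    """Estimate per-parameter flip probabilities from generated matrices.

    Valid in the full-flip regime (partial_prob = 0, variation_prob = 0),
    where a divergence leaves RF exactly 0: the estimator is the fraction
    of comparison cells with RF = 0, per parameter, pooled over matrices.
    """
    if not matrices:
        raise ValueError("need at least one matrix to estimate flip probabilities")
    zeros = {kind: 0 for kind in PARAMETER_ORDER}
    total = 0
    for matrix in matrices:
        for sp in matrix.comparison_species():
            for muscle in matrix.muscle_names:
                vec = matrix.entries[(sp, muscle)]
                total += 1
                for kind in PARAMETER_ORDER:
                    if vec.rf[kind] == 0.0:
                        zeros[kind] += 1
    return {kind: zeros[kind] / total for kind in PARAMETER_ORDER}
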