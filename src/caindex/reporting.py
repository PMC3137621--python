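"""Similarity reports and export formats (CSV/JSON report, PHYLIP, newick).

``run_compute`` evaluates every (muscle, comparison species) cell and every
(group, comparison species) aggregate of a character matrix and returns a
tidy report.  ``export_distance_phylip`` writes the all-pairs CAI distance
matrix in PHYLIP square format; ``export_upgma_newick`` clusters such a
matrix by average linkage (UPGMA) and writes a rooted ultrametric newick
tree.  UPGMA is implemented here so that its tie-break is fixed by contract
-- ties merge the lexicographically smallest joined-cluster name first --
which keeps the tree reproducible on any platform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import (
    GroupSimilarity,
    MuscleSimilarity,
    group_similarity,
    muscle_similarity,
    pairwise_distance_matrix,
    round_half_up,
)
from .trait_matrix import CharacterMatrix, WeightScheme

__all__ = [
    "RunConfig",
    "SimilarityReport",
    "run_compute",
    "export_distance_phylip",
    "upgma",
    "export_upgma_newick",
]

log = logging.getLogger("caindex")


@dataclass
class RunConfig:
    """Settings for one report run.

    Exactly one input source: ``input_path`` (CSV/JSON character matrix) or
    ``use_fixture`` (the packaged study matrix).  ``group_by`` selects which
    rows the report carries: per-muscle, per-group, or both ("all").
    """

    input_path: str | Path | None = None
    use_fixture: bool = False
    reference: str | None = None
    scheme: WeightScheme = field(default_factory=WeightScheme)
    group_by: str = "all"  # "muscle" | "group" | "all"
    out_path: str | Path | None = None
    out_format: str = "csv"  # "csv" | "json"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.use_fixture == (self.input_path is not None):
            raise ValueError("exactly one input source: --input or --fixture")
        if self.group_by not in ("muscle", "group", "all"):
            raise ValueError(f"unknown group_by: {self.group_by!r}")


@dataclass(frozen=True)
class SimilarityReport:
    """Per-muscle and per-group similarity rows for one matrix."""

    reference: str
    muscle_rows: tuple[MuscleSimilarity, ...]
    group_rows: tuple[GroupSimilarity, ...]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, muscle rows then group rows; CAIs at 3 decimals."""
        rows = []
        for s in self.muscle_rows:
            rows.append(
                {
                    "level": "muscle",
                    "name": s.muscle,
                    "reference": s.species_pair[0],
                    "comparison": s.species_pair[1],
                    "paf_reference": s.paf_reference,
                    "paf_comparison": s.paf_comparison,
                    "cai": round_half_up(s.cai, 3),
                    "band": s.band.label,
                    "from_override": s.from_override,
                }
            )
        for g in self.group_rows:
            rows.append(
                {
                    "level": "group",
                    "name": g.group,
                    "reference": g.species_pair[0],
                    "comparison": g.species_pair[1],
                    "paf_reference": np.nan,
                    "paf_comparison": np.nan,
                    "cai": round_half_up(g.gcai, 3),
                    "band": g.band.label,
                    "from_override": False,
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        frame = self.to_frame()
        return {
            "reference": self.reference,
            "rows": json.loads(frame.to_json(orient="records")),
        }

    def write(self, path: str | Path, fmt: str = "csv") -> None:
        if fmt == "csv":
            self.to_frame().to_csv(path, index=False)
        elif fmt == "json":
            Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))
        else:
            raise ValueError(f"unknown report format: {fmt!r}")


def _load_config_matrix(config: RunConfig) -> CharacterMatrix:
    from . import fixture, trait_matrix

    if config.use_fixture:
        return fixture.load_fixture()
    path = Path(config.input_path)
    if path.suffix.lower() == ".json":
        return trait_matrix.read_matrix_json(path)
    if config.reference is None:
        raise ValueError("--reference is required for CSV input")
    return trait_matrix.read_matrix_csv(path, reference=config.reference)


def run_compute(config: RunConfig) -> SimilarityReport:
    """Compute the full similarity report for the configured input.

    Every override consumed is logged as a warning so no published-but-
    unreconstructible value enters a report silently.
    """
    matrix = _load_config_matrix(config)
    from .trait_matrix import validate_matrix

    problems = validate_matrix(matrix)
    if problems:
        raise ValueError(
            "invalid character matrix: " + "; ".join(problems[:5])
            + ("" if len(problems) <= 5 else f" (+{len(problems) - 5} more)")
        )
    muscle_rows: list[MuscleSimilarity] = []
    group_rows: list[GroupSimilarity] = []
    if config.group_by in ("muscle", "all"):
        for comparison in matrix.comparison_species():
            for muscle in matrix.muscle_names:
                sim = muscle_similarity(matrix, muscle, comparison, config.scheme)
                if sim.from_override:
                    log.warning(
                        "using published CAI override %.4g for (%s, %s)",
                        sim.cai, comparison, muscle,
                    )
                muscle_rows.append(sim)
    if config.group_by in ("group", "all"):
        for comparison in matrix.comparison_species():
            for group in matrix.groups:
                group_rows.append(
                    group_similarity(matrix, group, comparison, config.scheme)
                )
    return SimilarityReport(
        reference=matrix.reference,
        muscle_rows=tuple(muscle_rows),
        group_rows=tuple(group_rows),
    )


# ---------------------------------------------------------------------------
# PHYLIP square distance matrix
# ---------------------------------------------------------------------------

def format_phylip(distances: pd.DataFrame) -> str:
    """PHYLIP square matrix text: taxon count line, then name + row values.

    Names are truncated/padded to the classic 10-character field; values at
    6 decimals.
    """
    names = list(distances.index)
    lines = [f"{len(names):5d}"]
    for name in names:
        label = f"{name[:10]:<10}"
        row = "  ".join(f"{distances.loc[name, other]:.6f}" for other in names)
        lines.append(f"{label}{row}")
    return "\n".join(lines) + "\n"


def export_distance_phylip(
    matrix: CharacterMatrix,
    out_path: str | Path,
    scheme: WeightScheme | None = None,
    level: str | None = None,
    *,
    ignore_overrides: bool = False,
) -> pd.DataFrame:
    """Write the all-pairs CAI distance matrix in PHYLIP square format."""
    distances = pairwise_distance_matrix(
        matrix, scheme, level, ignore_overrides=ignore_overrides
    )
    Path(out_path).write_text(format_phylip(distances))
    return distances


# ---------------------------------------------------------------------------
# UPGMA (average linkage) -> newick
# ---------------------------------------------------------------------------

@dataclass
class _Cluster:
    name: str  # lexicographically smallest member label, for tie-breaking
    size: int
    height: float
    newick: str


def upgma(distances: pd.DataFrame) -> str:
    """Average-linkage clustering of a symmetric distance matrix to newick.

    Ultrametric: each merge places both children at half the merge distance.
    Ties in the minimum pairwise distance are broken lexicographically by
    the joined-cluster name (the pair whose concatenated sorted names sort
    first merges first), so the output is deterministic.
    """
    values = distances.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValueError("UPGMA requires a symmetric square distance matrix")
    if values.shape[0] < 2:
        raise ValueError("UPGMA requires at least 2 taxa")
    clusters = {
        i: _Cluster(name=str(label), size=1, height=0.0, newick=str(label))
        for i, label in enumerate(distances.index)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): values[i, j]
        for i in clusters
        for j in clusters
        if i < j
    }
    next_id = len(clusters)
    while len(clusters) > 1:
        # minimum distance, ties by sorted pair of cluster names
        best = min(
            dist,
            key=lambda ij: (
                dist[ij],
                tuple(sorted((clusters[ij[0]].name, clusters[ij[1]].name))),
            ),
        )
        i, j = best
        d = dist[best]
        ci, cj = clusters.pop(i), clusters.pop(j)
        a, b = sorted((ci, cj), key=lambda c: c.name)  # children in name order
        height = d / 2.0
        merged = _Cluster(
            name=a.name,
            size=a.size + b.size,
            height=height,
            newick="({}:{:.6f},{}:{:.6f})".format(
                a.newick, height - a.height, b.newick, height - b.height
            ),
        )
        new_dist: dict[tuple[int, int], float] = {}
        for (p, q), v in dist.items():
            if i in (p, q) or j in (p, q):
                continue
            new_dist[(p, q)] = v
        for k in clusters:
            d_ik = dist[tuple(sorted((i, k)))]
            d_jk = dist[tuple(sorted((j, k)))]
            new_dist[tuple(sorted((k, next_id)))] = (
                ci.size * d_ik + cj.size * d_jk
            ) / (ci.size + cj.size)
        clusters[next_id] = merged
        dist = new_dist
        next_id += 1
    (root,) = clusters.values()
    return root.newick + ";"


def export_upgma_newick(distances: pd.DataFrame, out_path: str | Path) -> str:
    """Cluster a distance matrix by UPGMA and write the newick tree."""
    tree = upgma(distances)
    Path(out_path).write_text(tree + "\n")
    return tree
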