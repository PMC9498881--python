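"""Silhouette-based selection of the number of SNP clusters.

Each similarity network is converted to a distance matrix by d = 1 - s.
For a partition, every node i gets a silhouette value

    a(i) = mean distance to its own cluster (excluding itself)
    b(i) = min over other clusters of the mean distance to that cluster
    s(i) = (b(i) - a(i)) / max(a(i), b(i))

with s(i) = 0 for members of singleton clusters.  The multigraph partition
obtained for each cohort is scored against every measure's distance matrix,
the measure x cohort grid of mean silhouettes is averaged, and the smallest
K whose averaged score is within ``tolerance`` of the maximum is selected
(small K preferred, since the aim is a high-level grouping).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cluster import MinMaxCutResults, solve_multigraph, solve_singlegraph
from .networks import MEASURES, SimilarityNetwork

__all__ = [
    "SilhouetteReport",
    "silhouette_values",
    "averaged_silhouette",
    "select_k",
    "sweep_and_select",
    "sweep_and_select_singlegraph",
]


def _child_seed(seed: int, *key: int) -> int:
    """Deterministic per-(K, cohort) seed derived from the run seed."""
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def silhouette_values(network: SimilarityNetwork, assignment) -> np.ndarray:
    """Per-SNP silhouette of a partition under distances 1 - weight."""
    if isinstance(assignment, dict):
        labels = np.array([assignment[s] for s in network.snp_ids], dtype=int)
    else:
        labels = np.asarray(assignment, dtype=int)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    d = 1.0 - network.weights
    n = len(labels)
    sil = np.zeros(n)
    masks = {k: labels == k for k in uniq}
    sizes = {k: int(m.sum()) for k, m in masks.items()}
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            sil[i] = 0.0  # singleton convention
            continue
        a = d[i, masks[own]].sum() / (sizes[own] - 1)  # excludes self: d[i,i]=0
        b = min(d[i, masks[k]].mean() for k in uniq if k != own)
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return sil


def averaged_silhouette(
    assignments: dict[str, object],
    networks: dict[tuple[str, str], SimilarityNetwork],
) -> float:
    """Mean over (measure, cohort) cells of the mean per-SNP silhouette.

    ``assignments`` maps cohort name -> partition (the same multigraph
    partition is reused against every measure's distance matrix);
    ``networks`` maps (measure, cohort) -> similarity network.
    """
    cells = []
    for (measure, cohort), net in sorted(networks.items()):
        if cohort not in assignments:
            raise ValueError(f"missing assignment for cohort {cohort!r}")
        cells.append(float(silhouette_values(net, assignments[cohort]).mean()))
    if not cells:
        raise ValueError("no (measure, cohort) cells provided")
    return float(np.mean(cells))


@dataclass
class SilhouetteReport:
    """Scores of the K sweep and the selected cluster number."""

    per_cell_scores: dict[tuple[str, str, int], float]
    averaged_score: dict[int, float]
    selected_K: int
    tolerance: float
    fits: dict[tuple[str, int], MinMaxCutResults] = field(default_factory=dict, repr=False)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "per_cell_scores": {
                f"{m}|{c}|{k}": v for (m, c, k), v in sorted(self.per_cell_scores.items())
            },
            "averaged_score": {str(k): v for k, v in sorted(self.averaged_score.items())},
            "selected_K": self.selected_K,
            "tolerance": self.tolerance,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")

    def curve_to_csv(self, path: str | Path) -> None:
        """Averaged-silhouette-versus-K curve."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["K", "averaged_silhouette"])
            for k in sorted(self.averaged_score):
                writer.writerow([k, repr(self.averaged_score[k])])


def select_k(averaged: dict[int, float], tolerance: float) -> int:
    best = max(averaged.values())
    return min(k for k, v in averaged.items() if v >= best - tolerance)


def _grid_cohorts(networks: dict[tuple[str, str], SimilarityNetwork]) -> list[str]:
    cohorts = sorted({c for _, c in networks})
    measures = sorted({m for m, _ in networks})
    for m in measures:
        for c in cohorts:
            if (m, c) not in networks:
                raise ValueError(f"missing network for cell (measure={m!r}, cohort={c!r})")
    return cohorts


def sweep_and_select(
    networks: dict[tuple[str, str], SimilarityNetwork],
    k_range: range = range(2, 10),
    tolerance: float = 0.01,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> SilhouetteReport:
    """Sweep K, clustering each cohort's multigraph and averaging silhouettes.

    For every K and cohort, a multigraph min-max cut over that cohort's
    views (one per measure) yields one partition, which is then scored
    against all measures' distance matrices.
    """
    cohorts = _grid_cohorts(networks)
    measures = [m for m in MEASURES if any(mm == m for mm, _ in networks)] or sorted(
        {m for m, _ in networks}
    )
    S = len(next(iter(networks.values())).snp_ids)
    if min(k_range) < 2 or max(k_range) > S - 1:
        raise ValueError(f"k_range must lie within [2, {S - 1}]")

    per_cell: dict[tuple[str, str, int], float] = {}
    averaged: dict[int, float] = {}
    fits: dict[tuple[str, int], MinMaxCutResults] = {}
    for K in k_range:
        assignments = {}
        for ci, cohort in enumerate(cohorts):
            views = [networks[(m, cohort)] for m in measures]
            res = solve_multigraph(
                views, K, seed=_child_seed(seed, K, ci), max_iter=max_iter, tol=tol
            )
            fits[(cohort, K)] = res
            assignments[cohort] = res.labels_
        for (m, cohort), net in networks.items():
            per_cell[(m, cohort, K)] = float(
                silhouette_values(net, assignments[cohort]).mean()
            )
        averaged[K] = float(
            np.mean([per_cell[(m, c, K)] for m in measures for c in cohorts])
        )
    return SilhouetteReport(
        per_cell_scores=per_cell,
        averaged_score=averaged,
        selected_K=select_k(averaged, tolerance),
        tolerance=tolerance,
        fits=fits,
    )


def sweep_and_select_singlegraph(
    networks: dict[tuple[str, str], SimilarityNetwork],
    k_range: range = range(2, 10),
    tolerance: float = 0.01,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> SilhouetteReport:
    """Single-graph comparison mode: each (measure, cohort) network is
    clustered separately and scored against its own distance matrix."""
    cohorts = _grid_cohorts(networks)
    S = len(next(iter(networks.values())).snp_ids)
    if min(k_range) < 2 or max(k_range) > S - 1:
        raise ValueError(f"k_range must lie within [2, {S - 1}]")
    per_cell: dict[tuple[str, str, int], float] = {}
    averaged: dict[int, float] = {}
    for K in k_range:
        for idx, ((m, cohort), net) in enumerate(sorted(networks.items())):
            res = solve_singlegraph(
                net, K, seed=_child_seed(seed, K, idx), max_iter=max_iter, tol=tol
            )
            per_cell[(m, cohort, K)] = float(silhouette_values(net, res.labels_).mean())
        averaged[K] = float(np.mean([v for (_, _, k), v in per_cell.items() if k == K]))
    return SilhouetteReport(
        per_cell_scores=per_cell,
        averaged_score=averaged,
        selected_K=select_k(averaged, tolerance),
        tolerance=tolerance,
    )
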