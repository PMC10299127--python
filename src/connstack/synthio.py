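"""Synthetic cohorts with planted over-/under-connectivity group differences.

Subjects are drawn as zero-mean multivariate Gaussians, i.i.d. across time,
so the population correlation matrix equals the group target exactly.  The
case group's target raises the correlation on ``over_edges`` and lowers it on
``under_edges`` relative to the control baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enhance import WeightedGraph
from .tsio import PhenotypeTable, RoiTimeSeries, write_phenotype, write_timeseries

__all__ = [
    "CohortSpec",
    "simulate_cohort",
    "group_target_matrix",
    "toy_graph_fixture",
    "smoke_spec",
    "write_cohort",
]

_PD_TOL = -1e-8


class CohortSpecError(ValueError):
    """Raised when a cohort specification cannot produce valid targets."""


@dataclass
class CohortSpec:
    """Parameters of a two-group synthetic cohort."""

    n_per_group: int
    n_rois: int
    n_timepoints: int
    over_edges: list[tuple[int, int]] = field(default_factory=list)
    under_edges: list[tuple[int, int]] = field(default_factory=list)
    effect: float = 0.0
    base_corr: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.n_rois < 2 or self.n_timepoints < 2:
            raise CohortSpecError("counts must be positive (n_rois >= 2, T >= 2)")
        if not 0.0 <= self.effect < 1.0:
            raise CohortSpecError(f"effect must be in [0, 1), got {self.effect}")
        if not -1.0 < self.base_corr < 1.0:
            raise CohortSpecError(f"base_corr must be in (-1, 1), got {self.base_corr}")
        over = {self._norm(e) for e in self.over_edges}
        under = {self._norm(e) for e in self.under_edges}
        if over & under:
            raise CohortSpecError(f"over/under edge sets overlap: {sorted(over & under)}")
        for i, j in over | under:
            if i == j:
                raise CohortSpecError(f"self-pair ({i},{i}) is not an edge")
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise CohortSpecError(f"edge ({i},{j}) out of range for {self.n_rois} ROIs")
        self.over_edges = sorted(over)
        self.under_edges = sorted(under)

    @staticmethod
    def _norm(edge: tuple[int, int]) -> tuple[int, int]:
        i, j = int(edge[0]), int(edge[1])
        return (i, j) if i < j else (j, i)


def group_target_matrix(spec: CohortSpec, group: str) -> np.ndarray:
    """Target correlation matrix for "case" or "control"; SPD or rejected."""
    n = spec.n_rois
    R = np.full((n, n), spec.base_corr)
    np.fill_diagonal(R, 1.0)
    if group == "case":
        for i, j in spec.over_edges:
            R[i, j] = R[j, i] = spec.base_corr + spec.effect
        for i, j in spec.under_edges:
            R[i, j] = R[j, i] = spec.base_corr - spec.effect
    elif group != "control":
        raise CohortSpecError(f"unknown group {group!r}")
    min_eig = float(np.linalg.eigvalsh(R).min())
    if min_eig < _PD_TOL:
        raise CohortSpecError(
            f"target correlation matrix for group {group!r} is not positive "
            f"definite (min eigenvalue {min_eig:.3e}); adjust effect/base_corr"
        )
    if min_eig <= 0:  # tiny negative within tolerance: nudge onto the SPD cone
        vals, vecs = np.linalg.eigh(R)
        R = (vecs * np.clip(vals, 1e-10, None)) @ vecs.T
        R = (R + R.T) / 2.0
    return R


def simulate_cohort(spec: CohortSpec) -> list[tuple[RoiTimeSeries, str]]:
    """Draw 2 * n_per_group subjects (controls first), deterministic in seed."""
    targets = {g: group_target_matrix(spec, g) for g in ("control", "case")}
    factors = {}
    for g, R in targets.items():
        vals, vecs = np.linalg.eigh(R)
        factors[g] = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(spec.seed)
    cohort: list[tuple[RoiTimeSeries, str]] = []
    for group in ("control", "case"):
        A = factors[group]
        for k in range(spec.n_per_group):
            z = rng.standard_normal((spec.n_timepoints, spec.n_rois))
            data = z @ A.T
            sid = f"{group}{k:04d}"
            cohort.append((RoiTimeSeries(subject_id=sid, atlas="synthetic", data=data), group))
    return cohort


def toy_graph_fixture() -> WeightedGraph:
    """Fixed 4-vertex weighted graph used to pin down the tree algorithms.

    MST weight 6 on edges {(0,1),(1,2),(0,3)}; MaxST weight 15 on
    {(2,3),(1,3),(0,2)} (verified by exhaustive enumeration in the tests).
    """
    return WeightedGraph(
        n_vertices=4,
        edges=[(0, 1, 1.0), (0, 2, 4.0), (0, 3, 3.0), (1, 2, 2.0), (1, 3, 5.0), (2, 3, 6.0)],
    )


def smoke_spec(seed: int = 0, effect: float = 0.3, n_per_group: int = 100,
               n_rois: int = 30, n_timepoints: int = 150) -> CohortSpec:
    """Desk-scale benchmark cohort: 8 strengthened and 8 weakened edges."""
    over = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11), (12, 13), (14, 15)]
    under = [(16, 17), (18, 19), (20, 21), (22, 23), (24, 25), (26, 27), (28, 29), (0, 2)]
    return CohortSpec(
        n_per_group=n_per_group,
        n_rois=n_rois,
        n_timepoints=n_timepoints,
        over_edges=over,
        under_edges=under,
        effect=effect,
        base_corr=0.2,
        seed=seed,
    )


def write_cohort(cohort: list[tuple[RoiTimeSeries, str]], out_dir: str | Path) -> Path:
    """Write one time-series file per subject plus a phenotype CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels: dict[str, str] = {}
    for ts, label in cohort:
        write_timeseries(ts, out_dir / f"{ts.subject_id}.1D")
        labels[ts.subject_id] = label
    write_phenotype(PhenotypeTable(labels=labels), out_dir / "phenotype.csv")
    return out_dir
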