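"""Between-population diet comparison via Mantel tests.

For two populations, the food taxa present at a mean proportion of at
least 0.1% in *both* are selected; for each population a symmetric matrix
of absolute pairwise differences among its mean proportions is built; the
correlation of the two matrices' upper triangles is tested with a
one-sided (greater) permutation Mantel test, permuting the group labels of
one matrix (rows and columns simultaneously), with the add-one p
correction, so the smallest attainable p with 9999 permutations is 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .profiles import PopulationDietSummary

__all__ = [
    "DifferenceMatrix",
    "MantelResult",
    "shared_groups",
    "difference_matrix",
    "mantel_test",
    "compare_populations",
]


@dataclass(frozen=True)
class DifferenceMatrix:
    """|p_i - p_j| over a population's mean food proportions."""

    group_labels: tuple[str, ...]
    entries: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.group_labels)
        if k < 3:
            raise ValueError("difference matrix needs at least 3 groups")
        e = self.entries
        if e.shape != (k, k):
            raise ValueError(f"entries shape {e.shape} != ({k}, {k})")
        if not np.allclose(e, e.T) or not np.allclose(np.diag(e), 0):
            raise ValueError("entries must be symmetric with zero diagonal")
        if e.min() < -1e-12 or e.max() > 1 + 1e-12:
            raise ValueError("entries must lie in [0, 1]")


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    shared_groups: tuple[str, ...]
    seed: int | None = None


def shared_groups(
    summary_a: PopulationDietSummary,
    summary_b: PopulationDietSummary,
    floor: float = 0.001,
) -> list[str]:
    """Taxa at mean proportion >= floor in both populations (alphabetical).

    Taxa absent from either population are excluded by construction.
    """
    return sorted(
        t
        for t in summary_a.mean_proportion
        if summary_a.mean_proportion[t] >= floor
        and summary_b.mean_proportion.get(t, 0.0) >= floor
    )


def difference_matrix(
    summary: PopulationDietSummary, groups: Sequence[str]
) -> DifferenceMatrix:
    """Pairwise |difference| matrix of the summary's mean proportions."""
    if len(groups) < 3:
        raise ValueError(
            f"comparison undefined: only {len(groups)} shared groups (need >= 3)"
        )
    missing = [g for g in groups if g not in summary.mean_proportion]
    if missing:
        raise ValueError(f"groups not in summary {summary.population_id!r}: {missing}")
    p = np.array([summary.mean_proportion[g] for g in groups])
    return DifferenceMatrix(tuple(groups), np.abs(p[:, None] - p[None, :]))


def mantel_test(
    ma: DifferenceMatrix | np.ndarray,
    mb: DifferenceMatrix | np.ndarray,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (greater) permutation Mantel test of matrix correlation.

    r is the Pearson correlation of the strictly-upper-triangle entries;
    the null distribution comes from uniformly random simultaneous
    row/column permutations of the second matrix;
    p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations).
    """
    labels: tuple[str, ...] = ()
    if isinstance(ma, DifferenceMatrix):
        if isinstance(mb, DifferenceMatrix) and ma.group_labels != mb.group_labels:
            raise ValueError("matrices must share identical group labels")
        labels = ma.group_labels
        ma = ma.entries
    if isinstance(mb, DifferenceMatrix):
        labels = labels or mb.group_labels
        mb = mb.entries
    ma = np.asarray(ma, dtype=float)
    mb = np.asarray(mb, dtype=float)
    if ma.shape != mb.shape or ma.ndim != 2 or ma.shape[0] != ma.shape[1]:
        raise ValueError("matrices must be square and conformable")
    k = ma.shape[0]
    if k < 3:
        raise ValueError("Mantel test needs at least 3 groups")
    iu = np.triu_indices(k, 1)
    va, vb = ma[iu], mb[iu]
    sa, sb = va.std(), vb.std()
    if sa == 0 or sb == 0:
        raise ValueError("upper triangle has zero variance; r undefined")
    va_c = (va - va.mean()) / sa
    r_obs = float(np.dot(va_c, (vb - vb.mean()) / sb) / va.size)

    rng = np.random.default_rng(seed)
    count = 0
    # mean/std of the permuted upper triangle equal those of vb (symmetry),
    # so only the dot product changes under permutation
    vb_mean = vb.mean()
    denom = va.size * sb
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        vp = mb[np.ix_(perm, perm)][iu]
        r_perm = float(np.dot(va_c, vp - vb_mean) / denom)
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return MantelResult(
        r=r_obs, p=p, n_permutations=n_permutations,
        shared_groups=labels, seed=seed,
    )


def compare_populations(
    summary_a: PopulationDietSummary,
    summary_b: PopulationDietSummary,
    floor: float = 0.001,
    n_permutations: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """shared_groups -> difference matrices -> Mantel test."""
    groups = shared_groups(summary_a, summary_b, floor=floor)
    if len(groups) < 3:
        raise ValueError(
            f"cannot compare {summary_a.population_id!r} and "
            f"{summary_b.population_id!r}: only {len(groups)} shared food "
            "groups at the proportion floor (need >= 3)"
        )
    da = difference_matrix(summary_a, groups)
    db = difference_matrix(summary_b, groups)
    return mantel_test(da, db, n_permutations=n_permutations, seed=seed)
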