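"""Group comparison of brain-structure volumes: t-tests and label
randomization.

The permutation test relabels members across the two groups; exact
enumeration over all relabelings replaces random sampling automatically
when the number of distinct relabelings is small enough.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core.pedigree import Pedigree
from .core.variants import VariantRecord
from .core.volumes import VolumeTable

logger = logging.getLogger(__name__)

STUDENT = "student"
WELCH = "welch"

#: Exact enumeration replaces sampling when C(n, n_a) is at most this.
EXACT_ENUMERATION_LIMIT = 200_000


@dataclass
class GroupComparison:
    structure: str
    group_a_ids: tuple[str, ...]
    group_b_ids: tuple[str, ...]
    t_statistic: float | None = None
    p_t: float | None = None
    p_perm: float | None = None
    n_permutations: int = 0
    exact: bool = False
    seed: int | None = None


def _group_values(
    volumes: VolumeTable, structure: str, group_ids: Iterable[str]
) -> np.ndarray:
    vals = volumes.structure_values(structure, group_ids)
    return np.array(list(vals.values()), dtype=float)


def _t_stat(a: np.ndarray, b: np.ndarray, variant: str) -> float:
    res = stats.ttest_ind(a, b, equal_var=(variant == STUDENT))
    return float(res.statistic)


def volume_t_test(
    volumes: VolumeTable,
    group_a_ids: Iterable[str],
    group_b_ids: Iterable[str],
    structure: str,
    variant: str = STUDENT,
) -> GroupComparison:
    """Two-sided two-sample t-test on one structure's volumes."""
    if variant not in (STUDENT, WELCH):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a_ids = tuple(sorted(set(group_a_ids)))
    b_ids = tuple(sorted(set(group_b_ids)))
    if set(a_ids) & set(b_ids):
        raise ValueError("groups must be disjoint")
    a = _group_values(volumes, structure, a_ids)
    b = _group_values(volumes, structure, b_ids)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"each group needs >= 2 members with volumes for {structure}; "
            f"got {len(a)} and {len(b)}"
        )
    res = stats.ttest_ind(a, b, equal_var=(variant == STUDENT))
    return GroupComparison(
        structure=structure,
        group_a_ids=a_ids,
        group_b_ids=b_ids,
        t_statistic=float(res.statistic),
        p_t=float(res.pvalue),
    )


def _perm_t_stats(
    pooled: np.ndarray, n_a: int, assignments: np.ndarray, variant: str
) -> np.ndarray:
    """t statistics for many relabelings; ``assignments`` is (P, n) boolean."""
    n = pooled.size
    n_b = n - n_a
    sums_a = assignments @ pooled
    sq_a = assignments @ (pooled**2)
    tot, tot_sq = pooled.sum(), (pooled**2).sum()
    mean_a = sums_a / n_a
    mean_b = (tot - sums_a) / n_b
    var_a = (sq_a - n_a * mean_a**2) / (n_a - 1)
    var_b = ((tot_sq - sq_a) - n_b * mean_b**2) / (n_b - 1)
    var_a = np.maximum(var_a, 0.0)
    var_b = np.maximum(var_b, 0.0)
    if variant == STUDENT:
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n - 2)
        denom = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    else:
        denom = np.sqrt(var_a / n_a + var_b / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / denom
    return np.where(denom == 0.0, 0.0, t)


def permutation_test(
    volumes: VolumeTable,
    group_a_ids: Iterable[str],
    group_b_ids: Iterable[str],
    structure: str,
    n_permutations: int = 10_000,
    seed: int | None = None,
    variant: str = STUDENT,
) -> GroupComparison:
    """Label-randomization test on the absolute t statistic.

    Sampled p uses the add-one estimator
    ``(1 + #{|t_perm| >= |t_obs|}) / (1 + n_permutations)``; exact
    enumeration (all relabelings, identity included) is used when
    feasible, making the result deterministic.
    """
    comparison = volume_t_test(volumes, group_a_ids, group_b_ids, structure, variant)
    a = _group_values(volumes, structure, comparison.group_a_ids)
    b = _group_values(volumes, structure, comparison.group_b_ids)
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    t_obs = abs(comparison.t_statistic)

    n_exact = comb(n, n_a)
    if n_exact <= EXACT_ENUMERATION_LIMIT:
        assignments = np.zeros((n_exact, n), dtype=float)
        for i, idx in enumerate(combinations(range(n), n_a)):
            assignments[i, list(idx)] = 1.0
        t_perm = _perm_t_stats(pooled, n_a, assignments, variant)
        p_perm = float(np.mean(np.abs(t_perm) >= t_obs - 1e-12))
        comparison.p_perm = p_perm
        comparison.n_permutations = n_exact
        comparison.exact = True
    else:
        rng = np.random.default_rng(seed)
        assignments = np.zeros((n_permutations, n), dtype=float)
        for i in range(n_permutations):
            idx = rng.choice(n, size=n_a, replace=False)
            assignments[i, idx] = 1.0
        t_perm = _perm_t_stats(pooled, n_a, assignments, variant)
        hits = int(np.sum(np.abs(t_perm) >= t_obs - 1e-12))
        comparison.p_perm = (1 + hits) / (1 + n_permutations)
        comparison.n_permutations = n_permutations
        comparison.exact = False
    comparison.seed = seed
    return comparison


def carrier_groups(
    pedigree: Pedigree,
    variant: VariantRecord,
    member_ids: Iterable[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Split members into carriers (genotype >= 1) and non-carriers.

    ``member_ids`` restricts the split (e.g. to members with imaging data).
    Raises if either class is empty.
    """
    ids = list(member_ids) if member_ids is not None else pedigree.member_ids
    carriers = {m for m in ids if (variant.genotypes.get(m) or 0) >= 1}
    noncarriers = set(ids) - carriers
    if not carriers or not noncarriers:
        raise ValueError(
            f"cannot form carrier groups: {len(carriers)} carriers, "
            f"{len(noncarriers)} non-carriers"
        )
    return carriers, noncarriers


def diagnosis_groups(pedigree: Pedigree) -> tuple[set[str], set[str]]:
    """Affected vs unaffected members (unknown status excluded)."""
    return pedigree.affected_ids(), pedigree.unaffected_ids()


def compare_all_structures(
    volumes: VolumeTable,
    group_a_ids: Iterable[str],
    group_b_ids: Iterable[str],
    structures: Sequence[str] | None = None,
    n_permutations: int = 10_000,
    seed: int | None = None,
    variant: str = STUDENT,
    bonferroni: bool = False,
) -> list[GroupComparison]:
    """Per-structure comparisons; optional Bonferroni correction (off by
    default, matching common single-structure reporting)."""
    if structures is None:
        structures = sorted(
            {s for row in volumes.rows.values() for s in row}
        )
    out = []
    for structure in structures:
        cmp_ = permutation_test(
            volumes, group_a_ids, group_b_ids, structure,
            n_permutations=n_permutations, seed=seed, variant=variant,
        )
        if bonferroni:
            m = len(structures)
            cmp_.p_t = min(1.0, cmp_.p_t * m)
            cmp_.p_perm = min(1.0, cmp_.p_perm * m)
        out.append(cmp_)
    return out


def write_comparisons(comparisons: Sequence[GroupComparison], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("structure\tn_a\tn_b\tt\tp_t\tp_perm\tn_permutations\texact\n")
        for c in comparisons:
            fh.write(
                f"{c.structure}\t{len(c.group_a_ids)}\t{len(c.group_b_ids)}\t"
                f"{c.t_statistic:.4f}\t{c.p_t:.5f}\t{c.p_perm:.5f}\t"
                f"{c.n_permutations}\t{int(c.exact)}\n"
            )
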