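"""Independent oracles used by the unit and acceptance suites.

These deliberately avoid the library code paths they check: the pedigree
likelihood is recomputed by exhaustive genotype enumeration, scores by
brute-force term sums, and permutation p-values by direct relabeling.
"""

from __future__ import annotations

import itertools
import math

from famvar.core.pedigree import AFFECTED, UNAFFECTED, Pedigree


def enumeration_lnl(
    pedigree: Pedigree, kind: str, q: float, f_carrier: float, f_noncarrier: float
) -> float:
    """Pedigree log-likelihood by summing over all 3^n genotype vectors."""
    order = pedigree.topological_order()
    idx = {m.member_id: i for i, m in enumerate(order)}
    hw = [(1 - q) ** 2, 2 * q * (1 - q), q**2]

    def trans(gc: int, gf: int, gm: int) -> float:
        pf, pm = gf / 2.0, gm / 2.0
        return [
            (1 - pf) * (1 - pm),
            pf * (1 - pm) + (1 - pf) * pm,
            pf * pm,
        ][gc]

    def pen(g: int) -> float:
        carrier = g >= 1 if kind == "mendelian_AD" else g == 2
        return f_carrier if carrier else f_noncarrier

    total = 0.0
    for gv in itertools.product(range(3), repeat=len(order)):
        p = 1.0
        for m in order:
            g = gv[idx[m.member_id]]
            if m.is_founder:
                p *= hw[g]
            else:
                p *= trans(g, gv[idx[m.father_id]], gv[idx[m.mother_id]])
            f = pen(g)
            if m.affected == AFFECTED:
                p *= f
            elif m.affected == UNAFFECTED:
                p *= 1.0 - f
        total += p
    return math.log(total) if total > 0.0 else -math.inf


def brute_force_dmd(occurrences, n_d: int, n_h: int) -> float:
    """Term-by-term fraction sum, floating point."""
    return sum(o_d / n_d - o_h / n_h for _, o_d, o_h in occurrences)


def enumerated_perm_p(values_a, values_b) -> float:
    """Exact two-sided permutation p of the Student t by direct relabeling."""
    import numpy as np
    from scipy import stats

    pooled = list(values_a) + list(values_b)
    n_a = len(values_a)
    t_obs = abs(stats.ttest_ind(values_a, values_b, equal_var=True).statistic)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        a = [pooled[i] for i in combo]
        b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        if np.isnan(t):
            t = 0.0
        total += 1
        if abs(t) >= t_obs - 1e-12:
            hits += 1
    return hits / total
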