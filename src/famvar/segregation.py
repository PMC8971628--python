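"""Trait segregation analysis and variant-level transmission filters.

The pedigree likelihood treats each member's latent diallelic genotype
(0/1/2 alternate-allele copies) as a node in a Bayesian network: founder
genotypes follow Hardy-Weinberg at allele frequency ``q``, child
genotypes follow Mendelian transmission, and affection status is
Bernoulli given genotype through a two-penetrance map.  The likelihood
is computed exactly by factor elimination (Elston-Stewart peeling
generalised to an arbitrary loop-free pedigree), with a batch dimension
so that whole parameter grids are evaluated in one pass.

Model comparison follows the AIC convention ``AIC = -2 lnL + 2k``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .core.pedigree import AFFECTED, UNAFFECTED, AnalysisGroups, Pedigree, PedigreeError
from .core.variants import VariantRecord

logger = logging.getLogger(__name__)

SPORADIC = "sporadic"
SPORADIC_RESIDUAL = "sporadic_residual"
MENDELIAN_AD = "mendelian_AD"
MENDELIAN_AR = "mendelian_AR"

ALL_MODEL_KINDS = (SPORADIC, SPORADIC_RESIDUAL, MENDELIAN_AD, MENDELIAN_AR)

# T[child, father, mother]: Mendelian transmission for a diallelic locus.
_TRANSMISSION = np.zeros((3, 3, 3))
for _gf in range(3):
    for _gm in range(3):
        _pf, _pm = _gf / 2.0, _gm / 2.0
        _TRANSMISSION[0, _gf, _gm] = (1 - _pf) * (1 - _pm)
        _TRANSMISSION[1, _gf, _gm] = _pf * (1 - _pm) + (1 - _pf) * _pm
        _TRANSMISSION[2, _gf, _gm] = _pf * _pm


@dataclass(frozen=True)
class SegregationModel:
    """A trait model with its free-parameter count ``k``.

    ``params`` holds fitted or fixed values by name:

    * sporadic: ``prevalence`` (k = 1)
    * sporadic_residual: ``prevalence``, ``frailty_prob``, ``frailty_odds``
      (k = 3; shared latent binary frailty per nuclear family)
    * mendelian_AD / mendelian_AR: ``allele_freq``, ``f_carrier``,
      ``f_noncarrier`` (k = 3)
    """

    kind: str
    params: dict[str, float] = field(default_factory=dict)
    k: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ALL_MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass(frozen=True)
class SegregationFit:
    model: SegregationModel
    lnL: float
    converged: bool = True

    @property
    def neg2lnL(self) -> float:
        return -2.0 * self.lnL

    @property
    def aic(self) -> float:
        return self.neg2lnL + 2 * self.model.k


class PeelingEngine:
    """Batched exact likelihood evaluation over latent 3-state genotypes.

    Built once per pedigree; :meth:`evaluate` accepts founder priors of
    shape ``(B, 3)`` and per-member penetrance arrays of shape
    ``(B, n_members, 3)`` and returns ``B`` likelihoods.
    """

    def __init__(self, pedigree: Pedigree):
        if pedigree.has_loop():
            raise PedigreeError(
                "pedigree contains a loop; peeling supports loop-free "
                "pedigrees only"
            )
        self.pedigree = pedigree
        order = pedigree.topological_order()
        self.index = {m.member_id: i for i, m in enumerate(order)}
        self.members = order
        self.founder_idx = [self.index[m.member_id] for m in order if m.is_founder]
        self.triples = [
            (self.index[m.member_id], self.index[m.father_id], self.index[m.mother_id])
            for m in order
            if not m.is_founder
        ]
        self.elim_order = self._elimination_order()

    def _elimination_order(self) -> list[int]:
        # min-degree greedy order on the moral graph
        n = len(self.members)
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for c, f, m in self.triples:
            for a, b in ((c, f), (c, m), (f, m)):
                adj[a].add(b)
                adj[b].add(a)
        order = []
        remaining = set(range(n))
        while remaining:
            v = min(remaining, key=lambda x: (len(adj[x] & remaining), x))
            order.append(v)
            neigh = adj[v] & remaining
            for a in neigh:
                adj[a] |= neigh - {a}
            remaining.remove(v)
        return order

    def evaluate(self, prior: np.ndarray, pen: np.ndarray) -> np.ndarray:
        """Return likelihoods, shape ``(B,)``.

        ``prior``: founder genotype distribution, ``(B, 3)`` (need not be
        normalised for consistency queries).  ``pen``: value of the
        evidence factor per member and genotype, ``(B, n_members, 3)``.
        """
        prior = np.asarray(prior, dtype=float)
        pen = np.asarray(pen, dtype=float)
        B = prior.shape[0]
        factors: list[tuple[tuple[int, ...], np.ndarray]] = []
        for i in self.founder_idx:
            factors.append(((i,), prior * pen[:, i, :]))
        t = _TRANSMISSION[None, :, :, :]
        for c, f, m in self.triples:
            arr = t * pen[:, c, :, None, None]
            factors.append(((c, f, m), arr))

        for v in self.elim_order:
            involved = [fa for fa in factors if v in fa[0]]
            factors = [fa for fa in factors if v not in fa[0]]
            merged_vars, merged = _multiply(involved, B)
            axis = 1 + merged_vars.index(v)
            merged = merged.sum(axis=axis)
            merged_vars = tuple(x for x in merged_vars if x != v)
            factors.append((merged_vars, merged))

        out = np.ones(B)
        for fvars, arr in factors:
            if fvars:  # pragma: no cover - all vars are eliminated
                arr = arr.reshape(B, -1).sum(axis=1)
            out = out * arr.reshape(B)
        return out


def _multiply(
    factors: Sequence[tuple[tuple[int, ...], np.ndarray]], B: int
) -> tuple[tuple[int, ...], np.ndarray]:
    union: list[int] = []
    for fvars, _ in factors:
        for v in fvars:
            if v not in union:
                union.append(v)
    union_t = tuple(union)
    out = None
    for fvars, arr in factors:
        perm = [0] + [1 + fvars.index(v) for v in union_t if v in fvars]
        aligned = np.transpose(arr, perm)
        shape = [B] + [3 if v in fvars else 1 for v in union_t]
        aligned = aligned.reshape(shape)
        out = aligned if out is None else out * aligned
    return union_t, out


def _hw_prior(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)


def _penetrance_map(kind: str, fc: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """Affection probability per genotype, shape ``(B, 3)``."""
    fc = np.asarray(fc, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if kind == MENDELIAN_AD:
        return np.stack([f0, fc, fc], axis=-1)
    if kind == MENDELIAN_AR:
        return np.stack([f0, f0, fc], axis=-1)
    raise ValueError(kind)


def _affection_evidence(
    engine: PeelingEngine, pen_affected: np.ndarray
) -> np.ndarray:
    """Evidence factors P(status | genotype), shape ``(B, n, 3)``."""
    B = pen_affected.shape[0]
    n = len(engine.members)
    pen = np.ones((B, n, 3))
    for i, member in enumerate(engine.members):
        if member.affected == AFFECTED:
            pen[:, i, :] = pen_affected
        elif member.affected == UNAFFECTED:
            pen[:, i, :] = 1.0 - pen_affected
    return pen


def _mendelian_lnl_batch(
    engine: PeelingEngine, kind: str, q: np.ndarray, fc: np.ndarray, f0: np.ndarray
) -> np.ndarray:
    prior = _hw_prior(q)
    pen = _affection_evidence(engine, _penetrance_map(kind, fc, f0))
    lik = engine.evaluate(prior, pen)
    with np.errstate(divide="ignore"):
        return np.log(lik)


def _nuclear_family_partition(pedigree: Pedigree) -> list[list[str]]:
    """Partition members into nuclear-family groups for the frailty model.

    Each member is assigned to exactly one group: non-founders to their
    sibship's family; parents to the family of their (first) union when
    they are not already placed as a child.
    """
    families: dict[tuple[str, str], list[str]] = {}
    placed: set[str] = set()
    for m in pedigree.topological_order():
        if m.is_founder:
            continue
        key = (m.father_id, m.mother_id)
        fam = families.setdefault(key, [])
        for pid in key:
            if pid not in placed:
                fam.append(pid)
                placed.add(pid)
        if m.member_id not in placed:
            fam.append(m.member_id)
            placed.add(m.member_id)
    groups = list(families.values())
    singletons = [
        [m.member_id] for m in pedigree.members if m.member_id not in placed
    ]
    return groups + singletons


def _residual_lnl(
    pedigree: Pedigree,
    prevalence: np.ndarray,
    frailty_prob: np.ndarray,
    frailty_odds: np.ndarray,
) -> np.ndarray:
    """Batched log-likelihood of the shared-frailty sporadic model."""
    p0 = np.asarray(prevalence, dtype=float)
    pi = np.asarray(frailty_prob, dtype=float)
    odds1 = p0 / (1 - p0) * np.asarray(frailty_odds, dtype=float)
    p1 = odds1 / (1 + odds1)
    lnl = np.zeros_like(p0)
    for group in _nuclear_family_partition(pedigree):
        l0 = np.ones_like(p0)
        l1 = np.ones_like(p0)
        for mid in group:
            status = pedigree.member(mid).affected
            if status == AFFECTED:
                l0, l1 = l0 * p0, l1 * p1
            elif status == UNAFFECTED:
                l0, l1 = l0 * (1 - p0), l1 * (1 - p1)
        with np.errstate(divide="ignore"):
            lnl = lnl + np.log((1 - pi) * l0 + pi * l1)
    return lnl


def pedigree_likelihood(pedigree: Pedigree, model: SegregationModel) -> float:
    """Exact log-likelihood of the observed affection statuses.

    Returns ``-inf`` for zero-probability configurations; raises
    :class:`PedigreeError` for loop pedigrees (Mendelian models only).
    """
    if model.kind == SPORADIC:
        p = model.params["prevalence"]
        lnl = 0.0
        for m in pedigree.members:
            if m.affected == AFFECTED:
                lnl += math.log(p) if p > 0 else -math.inf
            elif m.affected == UNAFFECTED:
                lnl += math.log(1 - p) if p < 1 else -math.inf
        return lnl
    if model.kind == SPORADIC_RESIDUAL:
        return float(
            _residual_lnl(
                pedigree,
                np.array([model.params["prevalence"]]),
                np.array([model.params["frailty_prob"]]),
                np.array([model.params["frailty_odds"]]),
            )[0]
        )
    engine = PeelingEngine(pedigree)
    return float(
        _mendelian_lnl_batch(
            engine,
            model.kind,
            np.array([model.params["allele_freq"]]),
            np.array([model.params["f_carrier"]]),
            np.array([model.params["f_noncarrier"]]),
        )[0]
    )


def _fit_sporadic(pedigree: Pedigree) -> SegregationFit:
    statuses = [m.affected for m in pedigree.members if m.affected != "unknown"]
    n_aff = sum(1 for s in statuses if s == AFFECTED)
    n = len(statuses)
    p_hat = n_aff / n if n else 0.5
    model = SegregationModel(SPORADIC, {"prevalence": p_hat}, k=1)
    return SegregationFit(model=model, lnL=pedigree_likelihood(pedigree, model))


def _refine(fun, x0: np.ndarray) -> tuple[np.ndarray, float, bool]:
    res = minimize(fun, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    return res.x, float(res.fun), bool(res.success)


def _fit_sporadic_residual(pedigree: Pedigree) -> SegregationFit:
    p_grid = np.linspace(0.05, 0.95, 19)
    pi_grid = np.linspace(0.05, 0.95, 19)
    r_grid = np.geomspace(1.0, 200.0, 12)
    P, PI, R = np.meshgrid(p_grid, pi_grid, r_grid, indexing="ij")
    lnl = _residual_lnl(pedigree, P.ravel(), PI.ravel(), R.ravel())
    best = int(np.argmax(lnl))
    x0 = np.array([logit(P.ravel()[best]), logit(PI.ravel()[best]),
                   np.log(R.ravel()[best] + 1e-9)])

    def nll(x):
        p0, pi = expit(x[0]), expit(x[1])
        r = math.exp(min(x[2], 20.0))
        return -float(
            _residual_lnl(pedigree, np.array([p0]), np.array([pi]), np.array([r]))[0]
        )

    x, fval, ok = _refine(nll, x0)
    params = {
        "prevalence": float(expit(x[0])),
        "frailty_prob": float(expit(x[1])),
        "frailty_odds": float(math.exp(min(x[2], 20.0))),
    }
    model = SegregationModel(SPORADIC_RESIDUAL, params, k=3)
    return SegregationFit(model=model, lnL=-fval, converged=ok)


def _fit_mendelian(pedigree: Pedigree, kind: str) -> SegregationFit:
    engine = PeelingEngine(pedigree)
    q_grid = np.concatenate([[0.01, 0.03], np.linspace(0.05, 0.95, 19), [0.99]])
    f_grid = np.concatenate([[0.001, 0.01], np.linspace(0.05, 0.95, 19), [0.99, 0.999]])
    Q, FC, F0 = np.meshgrid(q_grid, f_grid, f_grid, indexing="ij")
    lnl = _mendelian_lnl_batch(engine, kind, Q.ravel(), FC.ravel(), F0.ravel())
    best = int(np.argmax(lnl))
    x0 = np.array([logit(Q.ravel()[best]), logit(FC.ravel()[best]),
                   logit(F0.ravel()[best])])

    def nll(x):
        q, fc, f0 = expit(x)
        val = _mendelian_lnl_batch(
            engine, kind, np.array([q]), np.array([fc]), np.array([f0])
        )[0]
        return -float(val) if np.isfinite(val) else 1e12

    x, fval, ok = _refine(nll, x0)
    q, fc, f0 = (float(v) for v in expit(x))
    model = SegregationModel(
        kind, {"allele_freq": q, "f_carrier": fc, "f_noncarrier": f0}, k=3
    )
    lnL = -fval if fval < 1e11 else -math.inf
    return SegregationFit(model=model, lnL=lnL, converged=ok and fval < 1e11)


def fit_models(
    pedigree: Pedigree, model_kinds: Iterable[str] = ALL_MODEL_KINDS
) -> list[SegregationFit]:
    """Fit each requested model by grid search plus local refinement.

    Deterministic (no random restarts).  Fits are returned sorted by AIC
    ascending; non-converged fits are retained and flagged.
    """
    fitters = {
        SPORADIC: _fit_sporadic,
        SPORADIC_RESIDUAL: _fit_sporadic_residual,
        MENDELIAN_AD: lambda p: _fit_mendelian(p, MENDELIAN_AD),
        MENDELIAN_AR: lambda p: _fit_mendelian(p, MENDELIAN_AR),
    }
    fits = []
    for kind in model_kinds:
        if kind not in fitters:
            raise ValueError(f"unknown model kind {kind!r}")
        fit = fitters[kind](pedigree)
        logger.info("fit %s: lnL=%.4f AIC=%.4f", kind, fit.lnL, fit.aic)
        fits.append(fit)
    return sorted(fits, key=lambda f: f.aic)


def best_models(fits: Sequence[SegregationFit], tol: float = 1e-3) -> list[SegregationFit]:
    """Fits whose AIC ties the minimum within ``tol`` (reports near-ties)."""
    lowest = min(f.aic for f in fits)
    return [f for f in fits if f.aic <= lowest + tol]


def _genotype_evidence(
    engine: PeelingEngine, records: Sequence[VariantRecord]
) -> np.ndarray:
    pen = np.ones((len(records), len(engine.members), 3))
    for b, rec in enumerate(records):
        for i, member in enumerate(engine.members):
            g = rec.genotypes.get(member.member_id)
            if g is not None:
                pen[b, i, :] = 0.0
                pen[b, i, g] = 1.0
    return pen


def mendelian_consistency_batch(
    records: Sequence[VariantRecord], pedigree: Pedigree
) -> np.ndarray:
    """Vectorised Mendelian-consistency check over many variants.

    A variant is consistent when some assignment of the missing genotypes
    makes every child receive exactly one allele from each parent.
    """
    if not records:
        return np.zeros(0, dtype=bool)
    engine = PeelingEngine(pedigree)
    prior = np.ones((len(records), 3))  # positivity is all that matters
    lik = engine.evaluate(prior, _genotype_evidence(engine, records))
    return lik > 0.0


def mendelian_consistency(variant: VariantRecord, pedigree: Pedigree) -> bool:
    """True iff the genotypes admit a Mendelian transmission pattern."""
    return bool(mendelian_consistency_batch([variant], pedigree)[0])


def cosegregation_filter(
    variant: VariantRecord,
    groups: AnalysisGroups,
    mode: str | Iterable[str] = ("AD", "AR"),
) -> bool:
    """Genotype-pattern co-segregation test under AD and/or AR coding.

    AD: every affected member carries >= 1 alternate allele and no healthy
    comparator carries any.  AR: every affected is homozygous alternate
    and no healthy comparator is.  Members in ``groups.exempt_ids`` are
    unconstrained.  Missing genotypes count as non-carrying, so a missing
    affected genotype fails the carrier requirement.  Returns True if any
    requested mode passes.
    """
    modes = (mode,) if isinstance(mode, str) else tuple(mode)
    comparators = groups.healthy_comparator_ids - groups.exempt_ids
    for md in modes:
        if md == "AD":
            need, forbid = 1, 1
        elif md == "AR":
            need, forbid = 2, 2
        else:
            raise ValueError(f"unknown co-segregation mode {md!r}")
        gt = variant.genotypes
        if all((gt.get(m) or 0) >= need for m in groups.affected_ids) and not any(
            (gt.get(m) or 0) >= forbid for m in comparators
        ):
            return True
    return False
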