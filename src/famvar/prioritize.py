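"""Four-stage rare-variant prioritization cascade.

Stages: differential extraction (functional class + carrier-fraction
difference between affected members and healthy comparators), genotype
co-segregation under a Mendelian mode, population-rarity filtering, and
deleteriousness-prediction voting.  Survivors are ranked by damaging-vote
count, then case-control odds ratio, then genomic position.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core.pedigree import AnalysisGroups, Pedigree, make_groups
from .core.variants import DAMAGING, PredictorCalls, VariantRecord
from .dmd import _chrom_rank
from .segregation import cosegregation_filter

logger = logging.getLogger(__name__)

STRICT = "strict"
CARRIER_DELTA = "carrier_delta"


@dataclass
class CascadeConfig:
    differential_rule: str = CARRIER_DELTA
    carrier_delta_min: float = 0.5
    max_af: float = 0.05
    min_damaging_votes: int = 1
    keep_splicing: bool = True
    cosegregation_modes: tuple[str, ...] = ("AD", "AR")
    or_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.max_af < 1.0:
            raise ValueError(f"max_af must be in (0, 1), got {self.max_af}")
        if self.min_damaging_votes < 0:
            raise ValueError("min_damaging_votes must be >= 0")
        if self.differential_rule not in (STRICT, CARRIER_DELTA):
            raise ValueError(f"unknown differential rule {self.differential_rule!r}")


@dataclass(frozen=True)
class OddsRatio:
    """An odds ratio, possibly computed after boundary clamping."""

    value: float | None
    boundary: bool = False


@dataclass
class Candidate:
    variant_key: tuple
    gene: str
    damaging_votes: int
    or_exac: float | None
    or_converge: float | None
    eas_all_ratio: float | None
    passed_modes: tuple[str, ...]
    flags: tuple[str, ...] = ()


@dataclass
class CandidateReport:
    stages: list[tuple[str, int, int]]  # (stage, input count, surviving count)
    candidates: list[Candidate]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s, "input": i, "surviving": o} for s, i, o in self.stages
            ],
            "candidates": [
                {
                    "variant": "{}:{}:{}:{}".format(*c.variant_key),
                    "gene": c.gene,
                    "damaging_votes": c.damaging_votes,
                    "or_exac": c.or_exac,
                    "or_converge": c.or_converge,
                    "eas_all_ratio": c.eas_all_ratio,
                    "passed_modes": list(c.passed_modes),
                    "flags": list(c.flags),
                }
                for c in self.candidates
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("rank\tvariant\tgene\tdamaging_votes\tor_exac\t"
                     "or_converge\teas_all_ratio\tpassed_modes\tflags\n")
            for rank, c in enumerate(self.candidates, start=1):
                fmt = lambda v: "." if v is None else f"{v:.4f}"  # noqa: E731
                fh.write(
                    "\t".join(
                        [
                            str(rank),
                            "{}:{}:{}:{}".format(*c.variant_key),
                            c.gene,
                            str(c.damaging_votes),
                            fmt(c.or_exac),
                            fmt(c.or_converge),
                            fmt(c.eas_all_ratio),
                            ",".join(c.passed_modes) or ".",
                            ",".join(c.flags) or ".",
                        ]
                    )
                    + "\n"
                )


_QUALIFYING_EXONIC_FUNC = ("nonsynonymous", "stopgain", "frameshift")


def _functional_pass(rec: VariantRecord, config: CascadeConfig) -> bool:
    if rec.func == "exonic":
        return rec.exonic_func in _QUALIFYING_EXONIC_FUNC
    return config.keep_splicing and rec.func == "splicing"


def differential_variants(
    variants: Iterable[VariantRecord],
    groups: AnalysisGroups,
    config: CascadeConfig | None = None,
) -> list[VariantRecord]:
    """Stage 1: functional class plus carrier-fraction differential.

    In ``carrier_delta`` mode a variant survives when the affected carrier
    fraction exceeds the healthy-comparator carrier fraction by at least
    ``carrier_delta_min``; ``strict`` mode requires all affected to carry
    and no comparator to carry.
    """
    config = config or CascadeConfig()
    comparators = groups.healthy_comparator_ids
    out = []
    for rec in variants:
        if not _functional_pass(rec, config):
            continue
        n_aff = groups.n_affected
        frac_aff = rec.carrier_count(groups.affected_ids) / n_aff
        frac_comp = (
            rec.carrier_count(comparators) / len(comparators) if comparators else 0.0
        )
        if config.differential_rule == STRICT:
            if frac_aff == 1.0 and frac_comp == 0.0:
                out.append(rec)
        elif frac_aff - frac_comp >= config.carrier_delta_min:
            out.append(rec)
    return out


def rarity_filter(
    variants: Iterable[VariantRecord], config: CascadeConfig | None = None
) -> list[VariantRecord]:
    """Stage 3: drop variants with any known reference AF above the cutoff.

    Variants with no known reference frequency are kept (assumed rare) and
    flagged downstream.
    """
    config = config or CascadeConfig()
    out = []
    for rec in variants:
        max_af = rec.freqs.max_reference_af()
        if max_af is None or max_af <= config.max_af:
            out.append(rec)
    return out


def odds_ratio(
    p_case: float | None, p_control: float | None, epsilon: float = 1e-6
) -> OddsRatio:
    """Allele-frequency odds ratio ``p1 (1 - p2) / (p2 (1 - p1))``.

    Frequencies at 0 or 1 are clamped to ``[epsilon, 1 - epsilon]`` and the
    result is flagged as a boundary value.  Unknown inputs give an unknown
    result rather than an error.
    """
    if p_case is None or p_control is None:
        return OddsRatio(value=None)
    boundary = p_case in (0.0, 1.0) or p_control in (0.0, 1.0)
    p1 = min(max(p_case, epsilon), 1 - epsilon)
    p2 = min(max(p_control, epsilon), 1 - epsilon)
    return OddsRatio(value=(p1 * (1 - p2)) / (p2 * (1 - p1)), boundary=boundary)


def enrichment_ratio(af_sub: float | None, af_all: float | None) -> float | None:
    """Subpopulation-to-overall allele-frequency ratio; unknown if af_all = 0."""
    if af_sub is None or af_all is None or af_all == 0.0:
        return None
    return af_sub / af_all


def deleteriousness_votes(calls: PredictorCalls) -> int:
    """Number of predictors calling the variant damaging; unknowns never count."""
    return sum(1 for _, call in calls.calls if call == DAMAGING)


def _rank_key(c: Candidate) -> tuple:
    or_conv = c.or_converge if c.or_converge is not None else float("-inf")
    return (-c.damaging_votes, -or_conv, _chrom_rank(c.variant_key[0]),
            c.variant_key[1])


def run_cascade(
    variants: Sequence[VariantRecord],
    pedigree: Pedigree,
    config: CascadeConfig | None = None,
    groups: AnalysisGroups | None = None,
) -> CandidateReport:
    """Run all four stages and rank the survivors.

    Stage survivor counts are non-increasing by construction and recorded
    in the report.  An empty survivor set yields a valid empty report.
    """
    config = config or CascadeConfig()
    groups = groups or make_groups(pedigree)
    variants = sorted(variants, key=lambda r: (_chrom_rank(r.chrom), r.pos, r.alt))
    stages: list[tuple[str, int, int]] = []

    stage1 = differential_variants(variants, groups, config)
    stages.append(("differential", len(variants), len(stage1)))

    stage2 = [
        rec
        for rec in stage1
        if cosegregation_filter(rec, groups, config.cosegregation_modes)
    ]
    stages.append(("cosegregation", len(stage1), len(stage2)))

    stage3 = rarity_filter(stage2, config)
    stages.append(("rarity", len(stage2), len(stage3)))

    stage4 = [
        rec
        for rec in stage3
        if deleteriousness_votes(rec.predictions) >= config.min_damaging_votes
    ]
    stages.append(("deleteriousness", len(stage3), len(stage4)))

    for name, n_in, n_out in stages:
        logger.info("stage %-15s %d -> %d", name, n_in, n_out)

    candidates = []
    for rec in stage4:
        flags = []
        if rec.freqs.max_reference_af() is None:
            flags.append("no_reference_af")
        orx = odds_ratio(
            rec.freqs.exac_psych_all, rec.freqs.exac_nonpsych_all, config.or_epsilon
        )
        orc = odds_ratio(
            rec.freqs.converge_case, rec.freqs.converge_control, config.or_epsilon
        )
        if orx.boundary or orc.boundary:
            flags.append("boundary_or")
        passed = tuple(
            md
            for md in config.cosegregation_modes
            if cosegregation_filter(rec, groups, md)
        )
        candidates.append(
            Candidate(
                variant_key=rec.key,
                gene=rec.gene,
                damaging_votes=deleteriousness_votes(rec.predictions),
                or_exac=orx.value,
                or_converge=orc.value,
                eas_all_ratio=enrichment_ratio(
                    rec.freqs.exac_eas, rec.freqs.exac_all
                ),
                passed_modes=passed,
                flags=tuple(flags),
            )
        )
    candidates.sort(key=_rank_key)
    return CandidateReport(stages=stages, candidates=candidates)
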