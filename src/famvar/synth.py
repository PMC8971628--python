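"""Synthetic pedigree, genotype, CNV, and volume generation with ground truth.

A single global seed governs all randomness; each stage draws from a
deterministic substream so regenerating any one output is reproducible.
The built-in ``three_gen_17`` template is a three-generation, 17-member
family with five affected members (four second-generation sisters and one
third-generation daughter); a heterozygous driver variant descends from a
first-generation founder whose own genotype is recorded as missing, so
that the observed carrier pattern is exactly the affected members plus —
under incomplete penetrance — unaffected third-generation carriers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .core.cnv import CNVCall, DELETION, DUPLICATION, write_cnv_calls
from .core.pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    Member,
    Pedigree,
    write_pedigree,
)
from .core.variants import (
    DAMAGING,
    DEFAULT_PREDICTORS,
    TOLERATED,
    UNKNOWN,
    PopulationFrequencies,
    PredictorCalls,
    VariantRecord,
    classify_variant,
    write_annotation,
    write_vcf,
)
from .core.volumes import STRUCTURES, VolumeTable, write_volumes

TEMPLATE_THREE_GEN_17 = "three_gen_17"
TEMPLATE_CUSTOM = "custom"

# substream tags keep per-stage randomness independent of the other stages
_STREAM_PEDIGREE = 1
_STREAM_BACKGROUND = 2
_STREAM_DRIVER = 3
_STREAM_VOLUMES = 4
_STREAM_CNV = 5
_STREAM_AFFECTION = 6


@dataclass
class SimulationConfig:
    """All knobs for the generator; identical config + seed => identical output."""

    pedigree_template: str = TEMPLATE_THREE_GEN_17
    custom_members: list[dict] | None = None
    n_background_variants: int = 2000
    fraction_common: float = 0.3
    driver_af: float = 0.01
    driver_penetrance: float = 1.0
    phenocopy_rate: float = 0.0
    driver_model: str = "AD"
    predictor_damaging_probs: float | dict[str, float] = 0.1
    driver_damaging_count: int = 9
    volume_effect: float = 0.0
    volume_group: str = "diagnosis"  # or "carrier"
    volume_noise_cv: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_common", "driver_af", "driver_penetrance",
                     "phenocopy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.driver_damaging_count <= len(DEFAULT_PREDICTORS):
            raise ValueError("driver_damaging_count outside predictor panel size")
        if self.driver_model not in ("AD", "AR"):
            raise ValueError(f"driver_model must be AD or AR, got {self.driver_model}")
        if self.n_background_variants < 0:
            raise ValueError("n_background_variants must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls(**data)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass(frozen=True)
class TruthSet:
    """Ground truth of the planted driver variant."""

    driver_key: tuple[str, int, str, str]
    carrier_ids: frozenset[str]
    masked_ids: frozenset[str]
    model: str


def _template_three_gen_17() -> list[Member]:
    def m(mid, sex, affected, gen, father=None, mother=None):
        return Member(mid, sex, affected, gen, father, mother)

    members = [
        # generation 1: founding couple
        m("G1-M-01", MALE, UNAFFECTED, 1),
        m("G1-F-01", FEMALE, UNAFFECTED, 1),
        # generation 2: four affected sisters, one unaffected brother
        m("G2-F-01", FEMALE, AFFECTED, 2, "G1-M-01", "G1-F-01"),
        m("G2-F-02", FEMALE, AFFECTED, 2, "G1-M-01", "G1-F-01"),
        m("G2-F-03", FEMALE, AFFECTED, 2, "G1-M-01", "G1-F-01"),
        m("G2-F-04", FEMALE, AFFECTED, 2, "G1-M-01", "G1-F-01"),
        m("G2-M-01", MALE, UNAFFECTED, 2, "G1-M-01", "G1-F-01"),
        # spouses marrying in (founders)
        m("G2-M-02", MALE, UNAFFECTED, 1),
        m("G2-M-03", MALE, UNAFFECTED, 1),
        m("G2-M-04", MALE, UNAFFECTED, 1),
        m("G2-M-05", MALE, UNAFFECTED, 1),
        m("G2-F-05", FEMALE, UNAFFECTED, 1),
        # generation 3: one affected daughter, four unaffected children
        m("G3-F-01", FEMALE, UNAFFECTED, 3, "G2-M-02", "G2-F-01"),
        m("G3-F-03", FEMALE, UNAFFECTED, 3, "G2-M-02", "G2-F-01"),
        m("G3-F-02", FEMALE, AFFECTED, 3, "G2-M-03", "G2-F-02"),
        m("G3-M-01", MALE, UNAFFECTED, 3, "G2-M-04", "G2-F-03"),
        m("G3-M-02", MALE, UNAFFECTED, 3, "G2-M-05", "G2-F-04"),
    ]
    return members


#: Members carrying imaging data in the default template: the five affected,
#: the four unaffected third-generation members, and four married-in spouses.
DEFAULT_IMAGING_IDS: tuple[str, ...] = (
    "G2-F-01", "G2-F-02", "G2-F-03", "G2-F-04", "G3-F-02",
    "G3-F-01", "G3-F-03", "G3-M-01", "G3-M-02",
    "G2-M-02", "G2-M-03", "G2-M-04", "G2-M-05",
)

#: Default driver locus and annotation for the planted variant.
DRIVER_CHROM = "chr10"
DRIVER_POS = 49_739_806
DRIVER_REF = "C"
DRIVER_ALT = "T"
DRIVER_GENE = "DRV1"
DRIVER_FREQS = PopulationFrequencies(
    exac_all=0.0015,
    exac_eas=0.0209,
    exac_nonpsych_all=0.0012,
    exac_nonpsych_eas=0.0183,
    exac_psych_all=0.0026,
    g1000_all=0.0042,
    g1000_eas=0.0208,
    converge_case=0.0316,
    converge_control=0.0252,
)


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Build the pedigree for the configured template."""
    if config.pedigree_template == TEMPLATE_THREE_GEN_17:
        return Pedigree(members=_template_three_gen_17(), family_id="FAM1")
    if config.pedigree_template == TEMPLATE_CUSTOM:
        if not config.custom_members or len(config.custom_members) < 3:
            raise ValueError("custom template requires >= 3 members")
        members = [Member(**spec) for spec in config.custom_members]
        return Pedigree(members=members, family_id="FAM1")
    raise ValueError(f"unknown pedigree template {config.pedigree_template!r}")


def gene_drop_matrix(
    pedigree: Pedigree, allele_freqs: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Drop ``V`` independent diallelic loci through the pedigree.

    Founder genotypes are Hardy-Weinberg draws at each locus's allele
    frequency; each child receives one allele from each parent by fair
    Mendelian transmission.  Returns a ``(V, n_members)`` genotype matrix
    and the member-id column order (topological).
    """
    afs = np.asarray(allele_freqs, dtype=float)
    if np.any((afs < 0) | (afs > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    order = pedigree.topological_order()
    index = {m.member_id: i for i, m in enumerate(order)}
    V = afs.shape[0]
    G = np.zeros((V, len(order)), dtype=np.int8)
    for m in order:
        i = index[m.member_id]
        if m.is_founder:
            G[:, i] = rng.binomial(2, afs)
        else:
            gf = G[:, index[m.father_id]]
            gm = G[:, index[m.mother_id]]
            # note: operands must be int; "+" on numpy booleans is logical OR
            paternal = (rng.random(V) < gf / 2.0).astype(np.int8)
            maternal = (rng.random(V) < gm / 2.0).astype(np.int8)
            G[:, i] = paternal + maternal
    return G, [m.member_id for m in order]


def gene_drop(
    pedigree: Pedigree, allele_freq: float, seed: int | None = None
) -> dict[str, int]:
    """Single-locus gene drop; returns member_id -> genotype."""
    rng = np.random.default_rng(seed)
    G, ids = gene_drop_matrix(pedigree, np.array([allele_freq]), rng)
    return {mid: int(g) for mid, g in zip(ids, G[0])}


def _founder_ancestor_of_all_affected(pedigree: Pedigree) -> str:
    affected = pedigree.affected_ids()
    if not affected:
        raise ValueError("pedigree has no affected members to seed a driver")
    ancestors_of: dict[str, set[str]] = {}
    for m in pedigree.topological_order():
        anc = set()
        if not m.is_founder:
            anc |= {m.father_id, m.mother_id}
            anc |= ancestors_of[m.father_id] | ancestors_of[m.mother_id]
        ancestors_of[m.member_id] = anc
    candidates = [
        f.member_id
        for f in pedigree.founders
        if all(
            f.member_id in ancestors_of[a] or f.member_id == a for a in affected
        )
    ]
    if not candidates:
        raise ValueError(
            "no founder is an ancestor of every affected member; cannot plant "
            "a co-segregating driver"
        )
    return min(candidates)


def _transmission_chain(pedigree: Pedigree, transmitter: str) -> set[str]:
    """Members on a parental chain from the transmitter to any affected."""
    chain: set[str] = set()
    for aff in sorted(pedigree.affected_ids()):
        path: list[str] = []
        cur = aff
        while cur != transmitter:
            m = pedigree.member(cur)
            if m.is_founder:
                path = []
                break
            # prefer the parent whose ancestry contains the transmitter
            nxt = None
            for pid in (m.mother_id, m.father_id):
                if pid == transmitter or _has_ancestor(pedigree, pid, transmitter):
                    nxt = pid
                    break
            if nxt is None:
                path = []
                break
            path.append(cur)
            cur = nxt
        chain |= set(path)
    return chain


def _has_ancestor(pedigree: Pedigree, member_id: str, ancestor_id: str) -> bool:
    m = pedigree.member(member_id)
    if m.is_founder:
        return False
    if ancestor_id in (m.father_id, m.mother_id):
        return True
    return _has_ancestor(pedigree, m.father_id, ancestor_id) or _has_ancestor(
        pedigree, m.mother_id, ancestor_id
    )


def _driver_predictions(config: SimulationConfig) -> PredictorCalls:
    calls = {}
    for i, spec in enumerate(DEFAULT_PREDICTORS):
        calls[spec.name] = (
            DAMAGING if i < config.driver_damaging_count else TOLERATED
        )
    return PredictorCalls.from_mapping(calls)


def plant_driver(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple[VariantRecord, TruthSet]:
    """Plant a Mendelian-consistent driver variant with known carriers.

    Under the default AD model the driver descends from a founder ancestor
    of all affected members; that obligate transmitter's genotype (and any
    unaffected, non-exempt intermediate's) is recorded as missing so that
    no observed healthy comparator carries the allele.  Every affected
    member is a heterozygous carrier; with penetrance ``p`` below 1,
    ``round(n_affected / p) - n_affected`` unaffected third-generation
    members with a carrier parent are drawn as additional carriers.
    """
    if config.driver_penetrance <= 0.0:
        raise ValueError("driver_penetrance must be in (0, 1]")
    rng = config.rng(_STREAM_DRIVER)
    affected = pedigree.affected_ids()
    transmitter = _founder_ancestor_of_all_affected(pedigree)
    chain = _transmission_chain(pedigree, transmitter)

    genotypes: dict[str, int | None] = {m: 0 for m in pedigree.member_ids}
    if config.driver_model == "AD":
        carriers = affected | chain | {transmitter}
        for mid in carriers:
            genotypes[mid] = 1
        n_extra = max(
            0, round(len(affected) / config.driver_penetrance) - len(affected)
        )
        eligible = sorted(
            mid
            for mid in pedigree.unaffected_ids()
            if pedigree.member(mid).generation >= 3
            and (
                (genotypes.get(pedigree.member(mid).father_id) or 0) >= 1
                or (genotypes.get(pedigree.member(mid).mother_id) or 0) >= 1
            )
        )
        n_extra = min(n_extra, len(eligible))
        for mid in rng.choice(eligible, size=n_extra, replace=False) if n_extra else []:
            genotypes[str(mid)] = 1
        # hide unaffected, non-exempt obligate carriers (e.g. the founding
        # transmitter) so the observed pattern co-segregates
        masked = {
            mid
            for mid in carriers
            if pedigree.member(mid).affected == UNAFFECTED
            and pedigree.member(mid).generation < 3
        }
        for mid in masked:
            genotypes[mid] = None
    else:  # AR
        for mid in affected:
            genotypes[mid] = 2
            m = pedigree.member(mid)
            if not m.is_founder:
                for pid in (m.father_id, m.mother_id):
                    if (genotypes.get(pid) or 0) < 1:
                        genotypes[pid] = 1
        # a homozygous parent transmits an allele to every child: propagate
        # the obligate minimum down the pedigree
        for m in pedigree.topological_order():
            if m.is_founder:
                continue
            obligate = int((genotypes.get(m.father_id) or 0) == 2) + int(
                (genotypes.get(m.mother_id) or 0) == 2
            )
            if (genotypes.get(m.member_id) or 0) < obligate:
                genotypes[m.member_id] = obligate
        masked = set()

    record = VariantRecord(
        chrom=DRIVER_CHROM,
        pos=DRIVER_POS,
        ref=DRIVER_REF,
        alt=DRIVER_ALT,
        variant_class=classify_variant(DRIVER_REF, DRIVER_ALT),
        gene=DRIVER_GENE,
        func="exonic",
        exonic_func="nonsynonymous",
        genotypes=genotypes,
        freqs=DRIVER_FREQS,
        predictions=_driver_predictions(config),
    )
    observed_carriers = frozenset(
        mid for mid, g in genotypes.items() if (g or 0) >= 1
    )
    truth = TruthSet(
        driver_key=record.key,
        carrier_ids=observed_carriers,
        masked_ids=frozenset(masked),
        model=config.driver_model,
    )
    return record, truth


_BASES = np.array(list("ACGT"))
_CHROMS = [f"chr{i}" for i in range(1, 23)]


def _damaging_prob(config: SimulationConfig, predictor_name: str) -> float:
    if isinstance(config.predictor_damaging_probs, Mapping):
        return float(config.predictor_damaging_probs.get(predictor_name, 0.1))
    return float(config.predictor_damaging_probs)


def simulate_variant_set(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple[list[VariantRecord], TruthSet]:
    """Background variants (gene-dropped) plus the planted driver, sorted."""
    rng = config.rng(_STREAM_BACKGROUND)
    V = config.n_background_variants
    n_common = int(round(V * config.fraction_common))
    afs = np.concatenate([
        rng.uniform(0.06, 0.5, size=n_common),
        rng.uniform(0.001, 0.05, size=V - n_common),
    ])
    rng.shuffle(afs)
    G, member_order = gene_drop_matrix(pedigree, afs, rng)

    chroms = rng.choice(len(_CHROMS), size=V)
    positions = rng.integers(1, 120_000_000, size=V)
    ref_idx = rng.integers(0, 4, size=V)
    alt_idx = (ref_idx + rng.integers(1, 4, size=V)) % 4
    func_draw = rng.random(V)
    exonic_draw = rng.random(V)
    indel_draw = rng.random(V)
    freq_jitter = rng.lognormal(0.0, 0.1, size=(V, 2))
    eas_boost = rng.uniform(1.0, 2.0, size=V)
    pred_names = [p.name for p in DEFAULT_PREDICTORS]
    pred_probs = np.array([_damaging_prob(config, n) for n in pred_names])
    pred_draw = rng.random((V, len(pred_names)))

    seen_keys = {(DRIVER_CHROM, DRIVER_POS, DRIVER_REF, DRIVER_ALT)}
    records: list[VariantRecord] = []
    for v in range(V):
        chrom = _CHROMS[int(chroms[v])]
        pos = int(positions[v])
        ref = str(_BASES[ref_idx[v]])
        alt = str(_BASES[alt_idx[v]])
        is_indel = indel_draw[v] < 0.05
        if is_indel:
            alt = ref + str(_BASES[alt_idx[v]])
        key = (chrom, pos, ref, alt)
        while key in seen_keys:
            pos += 1
            key = (chrom, pos, ref, alt)
        seen_keys.add(key)

        if func_draw[v] < 0.70:
            func = "exonic"
            if is_indel:
                exonic_func = (
                    "frameshift" if exonic_draw[v] < 0.5 else "nonframeshift"
                )
            elif exonic_draw[v] < 0.55:
                exonic_func = "nonsynonymous"
            elif exonic_draw[v] < 0.90:
                exonic_func = "synonymous"
            elif exonic_draw[v] < 0.95:
                exonic_func = "stopgain"
            else:
                exonic_func = "other"
        else:
            func = ("intronic", "UTR", "intergenic", "splicing")[
                int((func_draw[v] - 0.70) / 0.30 * 4) % 4
            ]
            exonic_func = "NA"

        af = float(afs[v])
        all_af = min(1.0, af * float(freq_jitter[v, 0]))
        eas_af = min(1.0, all_af * float(eas_boost[v]))
        g1000 = min(1.0, af * float(freq_jitter[v, 1]))
        freqs = PopulationFrequencies(
            exac_all=round(all_af, 6),
            exac_eas=round(eas_af, 6),
            exac_nonpsych_all=round(all_af, 6),
            exac_nonpsych_eas=round(eas_af, 6),
            exac_psych_all=round(all_af, 6),
            g1000_all=round(g1000, 6),
            g1000_eas=round(min(1.0, g1000 * float(eas_boost[v])), 6),
            converge_case=round(af, 6),
            converge_control=round(af, 6),
        )
        if func == "exonic" and exonic_func in ("nonsynonymous", "stopgain"):
            calls = {
                name: (DAMAGING if pred_draw[v, j] < pred_probs[j] else TOLERATED)
                for j, name in enumerate(pred_names)
            }
            predictions = PredictorCalls.from_mapping(calls)
        else:
            predictions = PredictorCalls.all_unknown()

        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                variant_class=classify_variant(ref, alt),
                gene=f"GENE{v:05d}",
                func=func,
                exonic_func=exonic_func,
                genotypes={
                    mid: int(g) for mid, g in zip(member_order, G[v])
                },
                freqs=freqs,
                predictions=predictions,
            )
        )

    driver, truth = plant_driver(pedigree, config)
    records.append(driver)
    records.sort(key=lambda r: (_chrom_order(r.chrom), r.pos, r.alt))
    return records, truth


def _chrom_order(chrom: str) -> int:
    return int(chrom[3:]) if chrom[3:].isdigit() else 99


#: Baseline structure volumes in mm^3, roughly physiological.
VOLUME_BASELINES: dict[str, float] = {
    "left-thalamus": 7800.0,
    "left-caudate": 3600.0,
    "left-putamen": 4900.0,
    "left-pallidum": 1800.0,
    "left-hippocampus": 3900.0,
    "left-amygdala": 1500.0,
    "left-accumbens-area": 550.0,
    "brain-stem": 21000.0,
    "right-thalamus-proper": 7700.0,
    "right-caudate": 3700.0,
    "right-putamen": 4800.0,
    "right-pallidum": 1750.0,
    "right-hippocampus": 4000.0,
    "right-amygdala": 1550.0,
    "right-accumbens-area": 560.0,
    "cerebellum": 140000.0,
}
assert set(VOLUME_BASELINES) == set(STRUCTURES)


def simulate_volumes(
    pedigree: Pedigree,
    config: SimulationConfig,
    member_ids: Sequence[str] | None = None,
    group_a_ids: Iterable[str] | None = None,
) -> VolumeTable:
    """Gaussian volumes with a standardized group effect ``volume_effect``.

    Members of ``group_a_ids`` (default: the affected members, or the
    driver carriers when ``volume_group == "carrier"``) have their mean
    shifted by ``volume_effect`` noise standard deviations.
    """
    if not np.isfinite(config.volume_effect):
        raise ValueError("volume_effect must be finite")
    rng = config.rng(_STREAM_VOLUMES)
    if member_ids is None:
        if config.pedigree_template == TEMPLATE_THREE_GEN_17:
            member_ids = [
                m for m in DEFAULT_IMAGING_IDS if m in pedigree
            ]
        else:
            member_ids = pedigree.member_ids
    if group_a_ids is None:
        if config.volume_group == "carrier":
            _, truth = plant_driver(pedigree, config)
            group_a_ids = truth.carrier_ids
        else:
            group_a_ids = pedigree.affected_ids()
    group_a = set(group_a_ids)

    rows: dict[str, dict[str, float]] = {}
    for mid in member_ids:
        ind = 1.0 if mid in group_a else 0.0
        row = {}
        for name in STRUCTURES:
            base = VOLUME_BASELINES[name]
            sd = config.volume_noise_cv * base
            vol = base + sd * (config.volume_effect * ind + rng.standard_normal())
            row[name] = max(vol, 0.2 * base)
        rows[mid] = row
    return VolumeTable(rows=rows)


def simulate_cnv_calls(
    pedigree: Pedigree, config: SimulationConfig, n_regions: int = 3
) -> tuple[list[CNVCall], list[CNVCall]]:
    """Two caller-specific CNV call sets with no group-specific regions.

    Every member carries each shared region; the two callers disagree only
    in small boundary jitter.  The resulting consensus set is a null
    fixture for the differential screen.
    """
    rng = config.rng(_STREAM_CNV)
    calls_a: list[CNVCall] = []
    calls_b: list[CNVCall] = []
    for r in range(n_regions):
        chrom = _CHROMS[int(rng.integers(0, len(_CHROMS)))]
        start = int(rng.integers(1_000_000, 100_000_000))
        length = int(rng.integers(50_000, 500_000))
        state = DELETION if rng.random() < 0.5 else DUPLICATION
        for mid in pedigree.member_ids:
            j1, j2 = rng.integers(0, length // 10, size=2)
            calls_a.append(
                CNVCall(chrom, start, start + length - 1, state, "caller_a", mid)
            )
            calls_b.append(
                CNVCall(
                    chrom,
                    start + int(j1),
                    start + length - 1 + int(j2),
                    state,
                    "caller_b",
                    mid,
                )
            )
    return calls_a, calls_b


def simulate_affection(
    pedigree: Pedigree,
    allele_freq: float,
    f_carrier: float,
    f_noncarrier: float,
    model: str = "AD",
    seed: int | None = None,
) -> Pedigree:
    """Resample affection statuses under a major-gene model.

    Gene-drops one causal locus and draws each member's status Bernoulli
    from the genotype-dependent penetrance; used for parameter-recovery
    checks of the segregation fits.
    """
    rng = np.random.default_rng(seed)
    G, ids = gene_drop_matrix(pedigree, np.array([allele_freq]), rng)
    genotypes = dict(zip(ids, G[0]))
    carrier_min = 1 if model == "AD" else 2
    members = []
    for m in pedigree.members:
        p = f_carrier if genotypes[m.member_id] >= carrier_min else f_noncarrier
        status = AFFECTED if rng.random() < p else UNAFFECTED
        members.append(replace(m, affected=status))
    return Pedigree(members=members, family_id=pedigree.family_id)


@dataclass
class FixtureSet:
    """Paths of one written fixture bundle."""

    ped: Path
    vcf: Path
    annotation: Path
    volumes: Path
    cnv_a: Path
    cnv_b: Path
    truth: Path


def write_fixture_set(config: SimulationConfig, out_dir: str | Path) -> FixtureSet:
    """Generate and write the full text fixture bundle for a config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pedigree = simulate_pedigree(config)
    records, truth = simulate_variant_set(pedigree, config)
    volumes = simulate_volumes(pedigree, config)
    cnv_a, cnv_b = simulate_cnv_calls(pedigree, config)

    paths = FixtureSet(
        ped=out / "family.ped",
        vcf=out / "variants.vcf",
        annotation=out / "variants.annotation.tsv",
        volumes=out / "volumes.tsv",
        cnv_a=out / "cnv_caller_a.tsv",
        cnv_b=out / "cnv_caller_b.tsv",
        truth=out / "truth.json",
    )
    write_pedigree(pedigree, paths.ped)
    sample_ids = [m.member_id for m in pedigree.topological_order()]
    write_vcf(records, sample_ids, paths.vcf)
    write_annotation(records, paths.annotation)
    write_volumes(volumes, paths.volumes)
    write_cnv_calls(cnv_a, paths.cnv_a)
    write_cnv_calls(cnv_b, paths.cnv_b)
    paths.truth.write_text(
        json.dumps(
            {
                "driver_key": list(truth.driver_key),
                "carrier_ids": sorted(truth.carrier_ids),
                "masked_ids": sorted(truth.masked_ids),
                "model": truth.model,
            },
            indent=2,
        )
        + "\n"
    )
    return paths
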