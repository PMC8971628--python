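"""Annotated variant records: VCF + annotation-table reading and writing.

A :class:`VariantRecord` joins per-member genotypes (alternate-allele
counts) with functional annotation, population allele frequencies and a
panel of deleteriousness-predictor calls, mirroring the columns of an
ANNOVAR-style multianno table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from cyvcf2 import VCF

from .pedigree import Pedigree, check_sample_ids

logger = logging.getLogger(__name__)

SNV = "SNV"
INDEL = "InDel"

FUNC_CLASSES = ("exonic", "intronic", "UTR", "intergenic", "splicing", "other")
EXONIC_FUNC_CLASSES = (
    "nonsynonymous",
    "synonymous",
    "stopgain",
    "frameshift",
    "nonframeshift",
    "other",
    "NA",
)

DAMAGING = "damaging"
TOLERATED = "tolerated"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class PredictorSpec:
    """One deleteriousness predictor: either categorical or score-based.

    Categorical predictors carry the set of labels counted as damaging;
    score predictors are called damaging when ``score >= threshold``.
    """

    name: str
    column: str
    kind: str = "categorical"  # or "score"
    damaging_labels: tuple[str, ...] = ()
    threshold: float | None = None

    def call(self, value) -> str:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return UNKNOWN
        if self.kind == "categorical":
            label = str(value).strip()
            if label in ("", "."):
                return UNKNOWN
            return DAMAGING if label in self.damaging_labels else TOLERATED
        try:
            score = float(value)
        except (TypeError, ValueError):
            return UNKNOWN
        return DAMAGING if score >= self.threshold else TOLERATED


#: Default 13-slot predictor panel: 12 named algorithms plus a CADD slot.
DEFAULT_PREDICTORS: tuple[PredictorSpec, ...] = (
    PredictorSpec("SIFT", "SIFT_pred", damaging_labels=("D",)),
    PredictorSpec("Polyphen2_HDIV", "Polyphen2_HDIV_pred", damaging_labels=("D", "P")),
    PredictorSpec("Polyphen2_HVAR", "Polyphen2_HVAR_pred", damaging_labels=("D", "P")),
    PredictorSpec("LRT", "LRT_pred", damaging_labels=("D",)),
    PredictorSpec("MutationTaster", "MutationTaster_pred", damaging_labels=("A", "D")),
    PredictorSpec("MutationAssessor", "MutationAssessor_pred", damaging_labels=("H", "M")),
    PredictorSpec("FATHMM", "FATHMM_pred", damaging_labels=("D",)),
    PredictorSpec("PROVEAN", "PROVEAN_pred", damaging_labels=("D",)),
    PredictorSpec("MetaSVM", "MetaSVM_pred", damaging_labels=("D",)),
    PredictorSpec("MetaLR", "MetaLR_pred", damaging_labels=("D",)),
    PredictorSpec("GERP++", "GERP++_RS", kind="score", threshold=2.0),
    PredictorSpec("PhyloP", "phyloP_score", kind="score", threshold=1.6),
    PredictorSpec("CADD", "CADD_phred", kind="score", threshold=15.0),
)

#: Frequency columns of the annotation table, in canonical order.
FREQ_COLUMNS: dict[str, str] = {
    "exac_all": "ExAC_ALL",
    "exac_eas": "ExAC_EAS",
    "exac_nonpsych_all": "ExAC_nonpsych_ALL",
    "exac_nonpsych_eas": "ExAC_nonpsych_EAS",
    "exac_psych_all": "ExAC_psych_ALL",
    "g1000_all": "1000g2015aug_all",
    "g1000_eas": "1000g2015aug_eas",
    "converge_case": "CONVERGE_case",
    "converge_control": "CONVERGE_control",
}


@dataclass(frozen=True)
class PopulationFrequencies:
    """Population allele frequencies; ``None`` marks an unknown value."""

    exac_all: float | None = None
    exac_eas: float | None = None
    exac_nonpsych_all: float | None = None
    exac_nonpsych_eas: float | None = None
    exac_psych_all: float | None = None
    g1000_all: float | None = None
    g1000_eas: float | None = None
    converge_case: float | None = None
    converge_control: float | None = None

    def __post_init__(self) -> None:
        for name in FREQ_COLUMNS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"frequency {name}={v} outside [0, 1]")

    def known(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in FREQ_COLUMNS
            if getattr(self, name) is not None
        }

    def max_reference_af(self) -> float | None:
        """Largest known ExAC / 1000-genomes frequency (rarity filtering).

        Case-control cohort frequencies are deliberately excluded.
        """
        vals = [
            getattr(self, n)
            for n in (
                "exac_all",
                "exac_eas",
                "exac_nonpsych_all",
                "exac_nonpsych_eas",
                "g1000_all",
                "g1000_eas",
            )
            if getattr(self, n) is not None
        ]
        return max(vals) if vals else None


@dataclass(frozen=True)
class PredictorCalls:
    """Ordered damaging/tolerated/unknown calls for the predictor panel."""

    calls: tuple[tuple[str, str], ...] = ()
    raw_scores: tuple[tuple[str, float], ...] = ()

    @classmethod
    def from_mapping(
        cls,
        calls: Mapping[str, str],
        raw_scores: Mapping[str, float] | None = None,
        predictors: Iterable[PredictorSpec] = DEFAULT_PREDICTORS,
    ) -> "PredictorCalls":
        ordered = tuple((p.name, calls.get(p.name, UNKNOWN)) for p in predictors)
        for name, call in ordered:
            if call not in (DAMAGING, TOLERATED, UNKNOWN):
                raise ValueError(f"invalid call {call!r} for predictor {name}")
        scores = tuple(sorted((raw_scores or {}).items()))
        return cls(calls=ordered, raw_scores=scores)

    @classmethod
    def all_unknown(
        cls, predictors: Iterable[PredictorSpec] = DEFAULT_PREDICTORS
    ) -> "PredictorCalls":
        return cls.from_mapping({}, predictors=predictors)

    def as_dict(self) -> dict[str, str]:
        return dict(self.calls)

    def damaging_count(self) -> int:
        return sum(1 for _, c in self.calls if c == DAMAGING)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV/InDel with genotypes and annotation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = SNV
    gene: str = "."
    func: str = "other"
    exonic_func: str = "NA"
    genotypes: Mapping[str, int | None] = field(default_factory=dict)
    freqs: PopulationFrequencies = field(default_factory=PopulationFrequencies)
    predictions: PredictorCalls = field(default_factory=PredictorCalls.all_unknown)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for mid, g in self.genotypes.items():
            if g is not None and g not in (0, 1, 2):
                raise ValueError(f"invalid genotype {g!r} for {mid}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self, member_ids: Iterable[str] | None = None) -> set[str]:
        """Members with >= 1 alternate allele; missing counts as non-carrier."""
        ids = self.genotypes.keys() if member_ids is None else member_ids
        return {m for m in ids if (self.genotypes.get(m) or 0) >= 1}

    def carrier_count(self, member_ids: Iterable[str]) -> int:
        return len(self.carriers(member_ids))

    def with_genotypes(self, genotypes: Mapping[str, int | None]) -> "VariantRecord":
        return replace(self, genotypes=dict(genotypes))


def normalize_chrom(chrom: str, style: str = "chr") -> str:
    """Normalize chromosome naming to a single configured style."""
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{bare}" if style == "chr" else bare


def classify_variant(ref: str, alt: str) -> str:
    return SNV if len(ref) == 1 and len(alt) == 1 else INDEL


def _parse_freq(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text in ("", "."):
        return None
    return float(text)


_FUNC_ALIASES = {
    "exonic": "exonic",
    "intronic": "intronic",
    "splicing": "splicing",
    "intergenic": "intergenic",
    "utr3": "UTR",
    "utr5": "UTR",
    "utr": "UTR",
}

_EXONIC_FUNC_ALIASES = {
    "nonsynonymous snv": "nonsynonymous",
    "nonsynonymous": "nonsynonymous",
    "synonymous snv": "synonymous",
    "synonymous": "synonymous",
    "stopgain": "stopgain",
    "stoploss": "other",
    "frameshift insertion": "frameshift",
    "frameshift deletion": "frameshift",
    "frameshift": "frameshift",
    "nonframeshift insertion": "nonframeshift",
    "nonframeshift deletion": "nonframeshift",
    "nonframeshift": "nonframeshift",
    ".": "NA",
    "": "NA",
}


def _norm_func(value) -> str:
    text = str(value).strip().lower() if value is not None else ""
    if text in ("", ".", "nan"):
        return "other"
    return _FUNC_ALIASES.get(text, "other")


def _norm_exonic_func(value) -> str:
    text = str(value).strip().lower() if value is not None else ""
    if text == "nan":
        text = ""
    return _EXONIC_FUNC_ALIASES.get(text, "other" if text else "NA")


def read_annotation(
    path: str | Path,
    predictors: Iterable[PredictorSpec] = DEFAULT_PREDICTORS,
    chrom_style: str = "chr",
) -> dict[tuple[str, int, str, str], dict]:
    """Read a tab-separated annotation table keyed by (chrom, pos, ref, alt).

    The header row is required.  ``.`` or empty cells mean unknown.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"Chr", "Start", "Ref", "Alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    predictors = tuple(predictors)
    table: dict[tuple[str, int, str, str], dict] = {}
    for row in df.itertuples(index=False, name=None):
        # positional zip: itertuples would mangle names like "Gene.refGene"
        rec = dict(zip(df.columns, row))
        key = (
            normalize_chrom(rec["Chr"], chrom_style),
            int(rec["Start"]),
            rec["Ref"],
            rec["Alt"],
        )
        freqs = PopulationFrequencies(
            **{
                name: _parse_freq(rec.get(col))
                for name, col in FREQ_COLUMNS.items()
            }
        )
        calls = {p.name: p.call(rec.get(p.column)) for p in predictors}
        raw_scores = {}
        for p in predictors:
            if p.kind == "score":
                try:
                    raw_scores[p.name] = float(rec.get(p.column))
                except (TypeError, ValueError):
                    pass
        table[key] = {
            "gene": rec.get("Gene.refGene", ".") or ".",
            "func": _norm_func(rec.get("Func.refGene")),
            "exonic_func": _norm_exonic_func(rec.get("ExonicFunc.refGene")),
            "freqs": freqs,
            "predictions": PredictorCalls.from_mapping(
                calls, raw_scores, predictors=predictors
            ),
        }
    logger.info("read %d annotation rows from %s", len(table), path)
    return table


def read_variants(
    vcf_path: str | Path,
    anno_path: str | Path | None = None,
    pedigree: Pedigree | None = None,
    predictors: Iterable[PredictorSpec] = DEFAULT_PREDICTORS,
    chrom_style: str = "chr",
) -> list[VariantRecord]:
    """Read a VCF (plus optional annotation table) into variant records.

    Multiallelic rows are split into one record per alternate allele, with
    genotypes recoded as counts of that allele.  Records missing from the
    annotation table keep unknown frequencies and predictor calls, with a
    warning.
    """
    predictors = tuple(predictors)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if pedigree is not None:
        check_sample_ids(pedigree, samples)

    anno = (
        read_annotation(anno_path, predictors=predictors, chrom_style=chrom_style)
        if anno_path is not None
        else {}
    )

    records: list[VariantRecord] = []
    n_unannotated = 0
    for v in vcf:
        chrom = normalize_chrom(v.CHROM, chrom_style)
        gts = v.genotypes  # [allele1, allele2, phased] per sample
        for alt_index, alt in enumerate(v.ALT, start=1):
            genotypes: dict[str, int | None] = {}
            for sample, gt in zip(samples, gts):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    genotypes[sample] = None
                else:
                    genotypes[sample] = sum(1 for a in alleles if a == alt_index)
            key = (chrom, v.POS, v.REF, alt)
            extra = anno.get(key)
            if extra is None:
                if anno:
                    n_unannotated += 1
                extra = {
                    "gene": ".",
                    "func": "other",
                    "exonic_func": "NA",
                    "freqs": PopulationFrequencies(),
                    "predictions": PredictorCalls.all_unknown(predictors),
                }
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    variant_class=classify_variant(v.REF, alt),
                    genotypes=genotypes,
                    **extra,
                )
            )
    if n_unannotated:
        warnings.warn(
            f"{n_unannotated} variant(s) had no annotation row; kept with "
            "unknown frequencies and predictor calls",
            stacklevel=2,
        )
    logger.info("read %d variant records from %s", len(records), vcf_path)
    return records


def write_vcf(
    records: list[VariantRecord],
    sample_ids: list[str],
    path: str | Path,
) -> None:
    """Write biallelic records as a minimal VCF 4.2 text file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for r in records:
            if r.chrom not in chroms:
                chroms.append(r.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
        for r in records:
            gts = [gt_strings[r.genotypes.get(s)] for s in sample_ids]
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_annotation(
    records: list[VariantRecord],
    path: str | Path,
    predictors: Iterable[PredictorSpec] = DEFAULT_PREDICTORS,
) -> None:
    """Write the annotation table companion of :func:`write_vcf`."""
    predictors = tuple(predictors)
    columns = (
        ["Chr", "Start", "End", "Ref", "Alt", "Func.refGene", "Gene.refGene",
         "ExonicFunc.refGene"]
        + [FREQ_COLUMNS[name] for name in FREQ_COLUMNS]
        + [p.column for p in predictors]
    )
    rows = []
    call_to_label = {
        "SIFT": {DAMAGING: "D", TOLERATED: "T"},
        "Polyphen2_HDIV": {DAMAGING: "D", TOLERATED: "B"},
        "Polyphen2_HVAR": {DAMAGING: "D", TOLERATED: "B"},
        "LRT": {DAMAGING: "D", TOLERATED: "N"},
        "MutationTaster": {DAMAGING: "D", TOLERATED: "N"},
        "MutationAssessor": {DAMAGING: "H", TOLERATED: "N"},
        "FATHMM": {DAMAGING: "D", TOLERATED: "T"},
        "PROVEAN": {DAMAGING: "D", TOLERATED: "N"},
        "MetaSVM": {DAMAGING: "D", TOLERATED: "T"},
        "MetaLR": {DAMAGING: "D", TOLERATED: "T"},
    }
    for r in records:
        row = {
            "Chr": r.chrom,
            "Start": r.pos,
            "End": r.pos + len(r.ref) - 1,
            "Ref": r.ref,
            "Alt": r.alt,
            "Func.refGene": r.func,
            "Gene.refGene": r.gene,
            "ExonicFunc.refGene": {
                "nonsynonymous": "nonsynonymous SNV",
                "synonymous": "synonymous SNV",
                "NA": ".",
            }.get(r.exonic_func, r.exonic_func),
        }
        for name, col in FREQ_COLUMNS.items():
            v = getattr(r.freqs, name)
            row[col] = "." if v is None else f"{v:.6g}"
        calls = r.predictions.as_dict()
        raw = dict(r.predictions.raw_scores)
        for p in predictors:
            call = calls.get(p.name, UNKNOWN)
            if p.kind == "score":
                score = raw.get(p.name)
                if score is None and call != UNKNOWN:
                    # reconstruct a score consistent with the call
                    score = p.threshold + 1.0 if call == DAMAGING else p.threshold - 1.0
                row[p.column] = "." if score is None else f"{score:.4g}"
            else:
                labels = call_to_label.get(p.name, {DAMAGING: "D", TOLERATED: "T"})
                row[p.column] = labels.get(call, ".")
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
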