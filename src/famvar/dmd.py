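"""Differential mutation density landscapes and the consensus CNV screen.

Each chromosome is tiled with fixed-size windows starting at position 1
(half-open tiling on 1-based coordinates: a variant at an exact window
boundary belongs to the downstream window).  The per-window score sums,
over the distinct variants in the window, the difference between the
affected carrier fraction and the healthy carrier fraction; scores are
accumulated as exact rationals so their granularity (multiples of
``1 / lcm(N_affected, N_healthy)``) is preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core.cnv import CNVCall
from .core.pedigree import AnalysisGroups
from .core.variants import VariantRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 1_000_000
DEFAULT_HOTSPOT_THRESHOLD = 20.0


@dataclass
class WindowTally:
    """Carrier-count tallies for the variants falling in one window."""

    chrom: str
    window_start: int  # 1-based
    window_size: int
    occurrences: list[tuple[tuple, int, int]] = field(default_factory=list)
    # (variant key, carriers among affected, carriers among healthy)

    @property
    def n(self) -> int:
        return len(self.occurrences)

    @property
    def window_end(self) -> int:
        return self.window_start + self.window_size - 1


@dataclass
class DMDLandscape:
    scores: list[tuple[str, int, float]]  # (chrom, window_start, score)
    n_affected: int
    n_healthy: int
    window_size: int = DEFAULT_WINDOW_SIZE


@dataclass
class Hotspot:
    label: str
    chrom: str
    start: int  # 1-based window start of the merged run
    end: int  # 1-based inclusive end
    dmd: float  # peak window score within the run
    genes: set[str] = field(default_factory=set)
    variant_count: int = 0


def window_tally(
    variants: Iterable[VariantRecord],
    groups: AnalysisGroups,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> list[WindowTally]:
    """Bucket variants into fixed windows and count group carriers.

    Occurrence is the number of group members carrying >= 1 alternate
    allele; a missing genotype counts as non-carrier.
    """
    if window_size <= 0:
        raise ValueError(f"window_size must be positive, got {window_size}")
    tallies: dict[tuple[str, int], WindowTally] = {}
    for rec in variants:
        idx = (rec.pos - 1) // window_size
        start = idx * window_size + 1
        tally = tallies.setdefault(
            (rec.chrom, start),
            WindowTally(chrom=rec.chrom, window_start=start, window_size=window_size),
        )
        o_d = rec.carrier_count(groups.affected_ids)
        o_h = rec.carrier_count(groups.healthy_all_ids)
        tally.occurrences.append((rec.key, o_d, o_h))
    out = sorted(tallies.values(), key=lambda t: (_chrom_rank(t.chrom), t.window_start))
    logger.info("tallied %d windows", len(out))
    return out


def _chrom_rank(chrom: str) -> tuple[int, str]:
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    try:
        return (int(bare), "")
    except ValueError:
        return (1000, bare)


def dmd_score(tally: WindowTally, n_affected: int, n_healthy: int) -> float:
    """Sum over window variants of O_d/N_d - O_h/N_h, computed exactly."""
    if n_affected < 1 or n_healthy < 1:
        raise ValueError("group sizes must be >= 1")
    total = Fraction(0)
    for key, o_d, o_h in tally.occurrences:
        if o_d > n_affected or o_h > n_healthy:
            raise ValueError(
                f"occurrence exceeds group size for variant {key}: "
                f"O_d={o_d}/N_d={n_affected}, O_h={o_h}/N_h={n_healthy}"
            )
        total += Fraction(o_d, n_affected) - Fraction(o_h, n_healthy)
    return float(total)


def compute_landscape(
    variants: Iterable[VariantRecord],
    groups: AnalysisGroups,
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> DMDLandscape:
    n_d, n_h = groups.n_affected, groups.n_healthy
    tallies = window_tally(variants, groups, window_size)
    scores = [
        (t.chrom, t.window_start, dmd_score(t, n_d, n_h)) for t in tallies
    ]
    return DMDLandscape(
        scores=scores, n_affected=n_d, n_healthy=n_h, window_size=window_size
    )


def score_granularity(landscape: DMDLandscape) -> int:
    """Every landscape score is an integer multiple of 1/this value."""
    return math.lcm(landscape.n_affected, landscape.n_healthy)


def call_hotspots(
    landscape: DMDLandscape,
    threshold: float = DEFAULT_HOTSPOT_THRESHOLD,
    tallies: Sequence[WindowTally] | None = None,
    gene_map: Mapping[tuple, str] | None = None,
    band_labels: Mapping[tuple[str, int], str] | None = None,
) -> list[Hotspot]:
    """Windows scoring strictly above ``threshold``; adjacent runs merged.

    A merged hotspot reports its peak window score.  ``gene_map`` maps
    variant keys to gene symbols for annotation; ``band_labels`` maps
    (chrom, window_start) to cytoband labels, defaulting to
    ``chrom:window_start``.
    """
    qualifying = [
        (chrom, start, score)
        for chrom, start, score in landscape.scores
        if score > threshold
    ]
    qualifying.sort(key=lambda s: (_chrom_rank(s[0]), s[1]))
    tally_index = {
        (t.chrom, t.window_start): t for t in (tallies or [])
    }

    hotspots: list[Hotspot] = []
    run: list[tuple[str, int, float]] = []

    def flush() -> None:
        if not run:
            return
        chrom = run[0][0]
        start = run[0][1]
        end = run[-1][1] + landscape.window_size - 1
        peak = max(score for _, _, score in run)
        genes: set[str] = set()
        n_var = 0
        for _, wstart, _ in run:
            t = tally_index.get((chrom, wstart))
            if t is None:
                continue
            n_var += t.n
            if gene_map:
                genes |= {
                    gene_map[key] for key, _, _ in t.occurrences if key in gene_map
                }
        label = (band_labels or {}).get((chrom, run[0][1]), f"{chrom}:{run[0][1]}")
        hotspots.append(
            Hotspot(
                label=label,
                chrom=chrom,
                start=start,
                end=end,
                dmd=peak,
                genes=genes,
                variant_count=n_var,
            )
        )

    for chrom, start, score in qualifying:
        if run and (
            chrom != run[-1][0] or start != run[-1][1] + landscape.window_size
        ):
            flush()
            run = []
        run.append((chrom, start, score))
    flush()
    logger.info("called %d hotspot(s) above %s", len(hotspots), threshold)
    return hotspots


def _reciprocal_overlap(a: CNVCall, b: CNVCall) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def consensus_cnv(
    calls_a: Sequence[CNVCall],
    calls_b: Sequence[CNVCall],
    min_reciprocal_overlap: float = 0.5,
) -> list[CNVCall]:
    """Calls from set A confirmed by set B; the intersection is reported.

    Confirmation requires the same member, same copy state, and reciprocal
    overlap >= the threshold.
    """
    if not 0.0 < min_reciprocal_overlap <= 1.0:
        raise ValueError(
            f"overlap threshold must be in (0, 1], got {min_reciprocal_overlap}"
        )
    by_member: dict[tuple[str, str, str], list[CNVCall]] = {}
    for b in calls_b:
        by_member.setdefault((b.member_id, b.chrom, b.copy_state), []).append(b)
    retained: list[CNVCall] = []
    for a in calls_a:
        for b in by_member.get((a.member_id, a.chrom, a.copy_state), []):
            if _reciprocal_overlap(a, b) >= min_reciprocal_overlap:
                retained.append(
                    CNVCall(
                        chrom=a.chrom,
                        start=max(a.start, b.start),
                        end=min(a.end, b.end),
                        copy_state=a.copy_state,
                        caller="consensus",
                        member_id=a.member_id,
                    )
                )
                break
    logger.info("retained %d consensus CNV call(s)", len(retained))
    return retained


def differential_cnv(
    cnvs: Sequence[CNVCall],
    groups: AnalysisGroups,
    min_reciprocal_overlap: float = 0.5,
) -> list[CNVCall]:
    """Consensus CNVs private to one analysis group.

    Calls are clustered across members by copy state and reciprocal
    overlap; a cluster is differential when it is carried by >= 1 affected
    member and no healthy comparator, or vice versa.  Returns the member
    calls of differential clusters.
    """
    clusters: list[list[CNVCall]] = []
    for call in sorted(cnvs, key=lambda c: (_chrom_rank(c.chrom), c.start)):
        for cluster in clusters:
            rep = cluster[0]
            if (
                rep.chrom == call.chrom
                and rep.copy_state == call.copy_state
                and _reciprocal_overlap(rep, call) >= min_reciprocal_overlap
            ):
                cluster.append(call)
                break
        else:
            clusters.append([call])

    out: list[CNVCall] = []
    for cluster in clusters:
        members = {c.member_id for c in cluster}
        in_affected = members & groups.affected_ids
        in_healthy = members & groups.healthy_comparator_ids
        if (in_affected and not in_healthy) or (in_healthy and not in_affected):
            out.extend(cluster)
    logger.info("found %d differential CNV call(s)", len(out))
    return out


def write_landscape(landscape: DMDLandscape, path: str | Path) -> None:
    """Write scores as a BEDGRAPH-style TSV (0-based half-open)."""
    with Path(path).open("w") as fh:
        for chrom, start, score in landscape.scores:
            fh.write(f"{chrom}\t{start - 1}\t{start - 1 + landscape.window_size}\t"
                     f"{score:.6g}\n")


def write_hotspots(hotspots: Sequence[Hotspot], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("label\tchrom\tstart\tend\tdmd\tvariant_count\tgenes\n")
        for h in hotspots:
            genes = ",".join(sorted(h.genes)) if h.genes else "."
            fh.write(
                f"{h.label}\t{h.chrom}\t{h.start - 1}\t{h.end}\t{h.dmd:.6g}\t"
                f"{h.variant_count}\t{genes}\n"
            )
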