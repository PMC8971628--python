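"""Pedigree domain model and 6-column PED file I/O.

Members carry an inferred generation index (founders are generation 1;
a child's generation is one more than the deeper of its parents).
Analysis group construction implements the third-generation exclusion
policy used throughout the variant filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

_SEX_CODES = {"1": MALE, "2": FEMALE}
_SEX_TO_CODE = {MALE: "1", FEMALE: "2"}
_PHENO_CODES = {"1": UNAFFECTED, "2": AFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_PHENO_TO_CODE = {UNAFFECTED: "1", AFFECTED: "2", UNKNOWN: "0"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or malformed PED input."""


@dataclass(frozen=True)
class Member:
    """One pedigree member.

    Founders have both parent ids ``None``; non-founders have both set.
    """

    member_id: str
    sex: str
    affected: str = UNKNOWN
    generation: int = 1
    father_id: str | None = None
    mother_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise PedigreeError(f"invalid sex {self.sex!r} for {self.member_id}")
        if self.affected not in (AFFECTED, UNAFFECTED, UNKNOWN):
            raise PedigreeError(
                f"invalid affection status {self.affected!r} for {self.member_id}"
            )
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"member {self.member_id} must have both parents or neither"
            )
        if self.generation < 1:
            raise PedigreeError(f"generation must be >= 1 for {self.member_id}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A validated family graph.

    Invariants (enforced on construction):

    * every referenced parent is a member with the correct sex,
    * parentage is acyclic,
    * ``generation == 1 + max(parent generations)`` for non-founders.
    """

    members: list[Member]
    family_id: str = "FAM1"

    def __post_init__(self) -> None:
        self._by_id = {m.member_id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            raise PedigreeError("duplicate member ids in pedigree")
        self._validate()

    def _validate(self) -> None:
        dag = nx.DiGraph()
        dag.add_nodes_from(self._by_id)
        for m in self.members:
            if m.is_founder:
                continue
            for pid, want_sex in ((m.father_id, MALE), (m.mother_id, FEMALE)):
                parent = self._by_id.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"member {m.member_id} references unknown parent {pid!r}"
                    )
                if parent.sex != want_sex:
                    raise PedigreeError(
                        f"parent {pid} of {m.member_id} has sex {parent.sex}, "
                        f"expected {want_sex}"
                    )
                dag.add_edge(pid, m.member_id)
        if not nx.is_directed_acyclic_graph(dag):
            raise PedigreeError("cyclic parentage detected")
        for m in self.members:
            if m.is_founder:
                if m.generation != 1:
                    raise PedigreeError(
                        f"founder {m.member_id} must be generation 1, "
                        f"got {m.generation}"
                    )
            else:
                want = 1 + max(
                    self._by_id[m.father_id].generation,
                    self._by_id[m.mother_id].generation,
                )
                if m.generation != want:
                    raise PedigreeError(
                        f"member {m.member_id} has generation {m.generation}, "
                        f"expected {want} from parents"
                    )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._by_id

    def member(self, member_id: str) -> Member:
        return self._by_id[member_id]

    @property
    def member_ids(self) -> list[str]:
        return [m.member_id for m in self.members]

    @property
    def founders(self) -> list[Member]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Member]:
        return [m for m in self.members if not m.is_founder]

    def affected_ids(self) -> set[str]:
        return {m.member_id for m in self.members if m.affected == AFFECTED}

    def unaffected_ids(self) -> set[str]:
        return {m.member_id for m in self.members if m.affected == UNAFFECTED}

    def children_of(self, member_id: str) -> list[Member]:
        return [
            m
            for m in self.members
            if member_id in (m.father_id, m.mother_id)
        ]

    def topological_order(self) -> list[Member]:
        """Members ordered parents-before-children."""
        return sorted(self.members, key=lambda m: (m.generation, m.member_id))

    def has_loop(self) -> bool:
        """True if the marriage graph contains a cycle (e.g. consanguinity).

        Individuals and parental unions form a bipartite graph; any cycle in
        it is a pedigree loop, which the likelihood machinery rejects.
        """
        g = nx.Graph()
        for m in self.members:
            if m.is_founder:
                continue
            union = ("union", m.father_id, m.mother_id)
            g.add_edge(("ind", m.father_id), union)
            g.add_edge(("ind", m.mother_id), union)
            g.add_edge(union, ("ind", m.member_id))
        return len(g) > 0 and bool(nx.cycle_basis(g))


@dataclass
class AnalysisGroups:
    """Member groupings used by the filters and density statistics.

    ``exempt_ids`` holds unaffected third-generation members who are left
    unconstrained by co-segregation filtering and excluded from the
    case-control comparator group (their disease status is considered
    not yet observable).
    """

    affected_ids: set[str]
    healthy_comparator_ids: set[str]
    healthy_all_ids: set[str]
    exempt_ids: set[str] = field(default_factory=set)

    @property
    def n_affected(self) -> int:
        return len(self.affected_ids)

    @property
    def n_healthy(self) -> int:
        return len(self.healthy_all_ids)


def make_groups(pedigree: Pedigree, exempt_generation: int = 3) -> AnalysisGroups:
    """Build analysis groups with the generation-based exemption policy.

    Unaffected members in generations >= ``exempt_generation`` are exempt:
    excluded from the comparator set and unconstrained in co-segregation.
    Members of unknown affection status are excluded from every group.
    """
    affected = pedigree.affected_ids()
    if not affected:
        raise PedigreeError("no affected members: cannot form a case group")
    unaffected = pedigree.unaffected_ids()
    if not unaffected:
        raise PedigreeError("no unaffected members: cannot form a control group")
    exempt = {
        mid
        for mid in unaffected
        if pedigree.member(mid).generation >= exempt_generation
    }
    return AnalysisGroups(
        affected_ids=affected,
        healthy_comparator_ids=unaffected - exempt,
        healthy_all_ids=unaffected,
        exempt_ids=exempt,
    )


def read_pedigree(path: str | Path, family_id: str | None = None) -> Pedigree:
    """Read a 6-column pre-makeped PED file.

    Columns: family, individual, father, mother, sex (1/2), phenotype
    (1 unaffected, 2 affected, 0/-9 unknown).  ``0`` marks a missing
    parent.  Generations are inferred from parentage.  Malformed lines
    raise :class:`PedigreeError` naming the offending line number.
    """
    path = Path(path)
    raw: list[tuple[int, list[str]]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            raw.append((lineno, fields))
    if not raw:
        raise PedigreeError(f"{path}: empty PED file")

    fam_ids = {f[1][0] for f in raw}
    if family_id is None:
        if len(fam_ids) > 1:
            raise PedigreeError(
                f"{path}: multiple family ids {sorted(fam_ids)}; pass family_id"
            )
        family_id = next(iter(fam_ids))
    rows = [(ln, f) for ln, f in raw if f[0] == family_id]

    parsed: dict[str, dict] = {}
    for lineno, f in rows:
        _, iid, fid, mid, sex, pheno = f
        if sex not in _SEX_CODES:
            raise PedigreeError(f"{path}:{lineno}: invalid sex code {sex!r}")
        if pheno not in _PHENO_CODES:
            raise PedigreeError(f"{path}:{lineno}: invalid phenotype code {pheno!r}")
        if (fid == "0") != (mid == "0"):
            raise PedigreeError(
                f"{path}:{lineno}: member {iid} has exactly one parent; "
                "PED requires both or neither"
            )
        parsed[iid] = {
            "lineno": lineno,
            "father": None if fid == "0" else fid,
            "mother": None if mid == "0" else mid,
            "sex": _SEX_CODES[sex],
            "affected": _PHENO_CODES[pheno],
        }

    for iid, rec in parsed.items():
        for pid in (rec["father"], rec["mother"]):
            if pid is not None and pid not in parsed:
                raise PedigreeError(
                    f"{path}:{rec['lineno']}: member {iid} references "
                    f"unknown parent {pid!r}"
                )

    generations = _infer_generations(parsed, path)
    members = [
        Member(
            member_id=iid,
            sex=rec["sex"],
            affected=rec["affected"],
            generation=generations[iid],
            father_id=rec["father"],
            mother_id=rec["mother"],
        )
        for iid, rec in parsed.items()
    ]
    ped = Pedigree(members=members, family_id=family_id)
    logger.info("read %d members from %s (family %s)", len(ped), path, family_id)
    return ped


def _infer_generations(parsed: dict[str, dict], path: Path) -> dict[str, int]:
    generations: dict[str, int] = {}
    pending = dict(parsed)
    while pending:
        progressed = False
        for iid, rec in list(pending.items()):
            if rec["father"] is None:
                generations[iid] = 1
            elif rec["father"] in generations and rec["mother"] in generations:
                generations[iid] = 1 + max(
                    generations[rec["father"]], generations[rec["mother"]]
                )
            else:
                continue
            del pending[iid]
            progressed = True
        if not progressed:
            raise PedigreeError(f"{path}: cyclic parentage involving {sorted(pending)}")
    return generations


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    """Write a 6-column PED file (round-trips with :func:`read_pedigree`)."""
    path = Path(path)
    with path.open("w") as fh:
        for m in pedigree.topological_order():
            fh.write(
                "\t".join(
                    [
                        pedigree.family_id,
                        m.member_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_TO_CODE[m.sex],
                        _PHENO_TO_CODE[m.affected],
                    ]
                )
                + "\n"
            )


def check_sample_ids(pedigree: Pedigree, sample_ids: Iterable[str]) -> None:
    """Raise if ``sample_ids`` are not all pedigree members."""
    offenders = [s for s in sample_ids if s not in pedigree]
    if offenders:
        raise PedigreeError(
            f"sample ids not in pedigree: {', '.join(sorted(offenders))}"
        )
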