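"""Pedigree parsing, validation and queries.

Pedigrees are exchanged in the 6-column PED dialect (family, individual,
father, mother, sex, affection), whitespace delimited, with ``0`` marking a
missing parent.  Columns beyond the sixth are preserved verbatim as free-text
phenotype labels; the literal label ``unsequenced`` additionally marks an
individual as not having exome data (every other individual is assumed
sequenced, matching a design where exome sequencing was performed on the
family members listed in the pedigree file).

Affection coding follows linkage convention: 1 = unaffected, 2 = affected,
0 or -9 = unknown.  Sex: 1 = male, 2 = female, 0 = unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "parse_pedigrees",
    "write_pedigrees",
    "affected_members",
]

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
AFFECTION_CODES = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_AFF_OUT = {"unaffected": "1", "affected": "2", "unknown": "0"}

UNSEQUENCED_LABEL = "unsequenced"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigree input."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affection: str = "unknown"
    sequenced: bool = True
    phenotype_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise PedigreeError("individual_id must be nonempty")
        if self.individual_id in (self.father_id, self.mother_id):
            raise PedigreeError(
                f"individual {self.individual_id!r} cannot be its own parent"
            )
        if self.sex not in _SEX_OUT:
            raise PedigreeError(f"invalid sex {self.sex!r}")
        if self.affection not in _AFF_OUT:
            raise PedigreeError(f"invalid affection {self.affection!r}")


@dataclass
class Pedigree:
    """A single family: members keyed by individual id.

    Parent ids that do not resolve within the family denote unrecorded
    founders; they are kept as ids but no placeholder member is created.
    """

    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members.values())

    def add(self, ind: Individual) -> None:
        if ind.individual_id in self.members:
            raise PedigreeError(
                f"duplicate individual id {ind.individual_id!r} in family "
                f"{self.family_id!r}"
            )
        self.members[ind.individual_id] = ind

    def parents_of(self, individual_id: str) -> tuple[Individual | None, Individual | None]:
        ind = self.members[individual_id]
        father = self.members.get(ind.father_id) if ind.father_id else None
        mother = self.members.get(ind.mother_id) if ind.mother_id else None
        return father, mother

    def founders(self) -> list[Individual]:
        """Members with neither parent recorded in the family."""
        return [
            m
            for m in self.members.values()
            if (m.father_id is None or m.father_id not in self.members)
            and (m.mother_id is None or m.mother_id not in self.members)
        ]

    def validate(self) -> None:
        for ind in self.members.values():
            for pid, expected_sex in ((ind.father_id, "male"), (ind.mother_id, "female")):
                if pid and pid in self.members:
                    parent = self.members[pid]
                    if parent.sex not in ("unknown", expected_sex):
                        raise PedigreeError(
                            f"parent {pid!r} of {ind.individual_id!r} has sex "
                            f"{parent.sex}, expected {expected_sex}"
                        )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative DFS over child -> parent edges
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self.members}
        for start in self.members:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            while stack:
                node, _ = stack[-1]
                if color[node] == WHITE:
                    color[node] = GREY
                parents = [
                    p
                    for p in (self.members[node].father_id, self.members[node].mother_id)
                    if p and p in self.members
                ]
                advanced = False
                for p in parents:
                    if color[p] == GREY:
                        raise PedigreeError(
                            f"ancestry cycle in family {self.family_id!r} involving {p!r}"
                        )
                    if color[p] == WHITE:
                        stack.append((p, 0))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()


def _parse_line(line: str, lineno: int) -> Individual:
    fields = line.split()
    if len(fields) < 6:
        raise PedigreeError(f"line {lineno}: expected >= 6 PED columns, got {len(fields)}")
    fam, iid, fid, mid, sex, aff = fields[:6]
    extra = tuple(fields[6:])
    if sex not in SEX_CODES:
        raise PedigreeError(f"line {lineno}: invalid sex code {sex!r}")
    if aff not in AFFECTION_CODES:
        raise PedigreeError(f"line {lineno}: invalid affection code {aff!r}")
    return Individual(
        individual_id=iid,
        family_id=fam,
        father_id=None if fid == "0" else fid,
        mother_id=None if mid == "0" else mid,
        sex=SEX_CODES[sex],
        affection=AFFECTION_CODES[aff],
        sequenced=UNSEQUENCED_LABEL not in extra,
        phenotype_labels=extra,
    )


def parse_pedigrees(ped_stream: IO[str] | str | Iterable[str]) -> dict[str, Pedigree]:
    """Parse a PED stream into pedigrees keyed by family id.

    Accepts an open text handle, a string of PED text, or an iterable of
    lines.  Blank lines and ``#`` comment lines are skipped.  Raises
    :class:`PedigreeError` (with the offending line number or id) on
    malformed lines, duplicate individual ids within a family, or ancestry
    cycles.
    """
    if isinstance(ped_stream, str):
        lines: Iterable[str] = ped_stream.splitlines()
    else:
        lines = ped_stream
    pedigrees: dict[str, Pedigree] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        ind = _parse_line(line, lineno)
        ped = pedigrees.setdefault(ind.family_id, Pedigree(family_id=ind.family_id))
        ped.add(ind)
    for ped in pedigrees.values():
        ped.validate()
    return pedigrees


def write_pedigrees(pedigrees: Iterable[Pedigree]) -> str:
    """Serialize pedigrees back to PED text (inverse of :func:`parse_pedigrees`)."""
    out: list[str] = []
    for ped in pedigrees:
        for ind in ped.members.values():
            extra = list(ind.phenotype_labels)
            if not ind.sequenced and UNSEQUENCED_LABEL not in extra:
                extra.append(UNSEQUENCED_LABEL)
            out.append(
                "\t".join(
                    [
                        ped.family_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_OUT[ind.sex],
                        _AFF_OUT[ind.affection],
                        *extra,
                    ]
                )
            )
    return "\n".join(out) + ("\n" if out else "")


def affected_members(pedigree: Pedigree, require_sequenced: bool = False) -> list[Individual]:
    """Affected members in deterministic (id-sorted) order.

    With ``require_sequenced`` only members with exome data are returned —
    the set a co-segregation filter actually constrains.
    """
    out = [m for m in pedigree if m.affection == "affected"]
    if require_sequenced:
        out = [m for m in out if m.sequenced]
    return sorted(out, key=lambda m: m.individual_id)
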