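"""Pedigree structure file parsing, validation and family-graph queries.

The pedigree file is plain text, whitespace delimited, one row per
individual, five columns::

    ID  motherID  fatherID  gender  sampleName

``0`` in a parent column means "no parent"; founders have both parent
columns set to ``0`` and every non-founder must list both parents (a
single recorded parent is an error, because full and half siblings would
be indistinguishable).  Gender is ``1``/``M``/``male`` or
``2``/``F``/``female`` (case-insensitive).  ``sampleName`` is the column
name used for this individual in the likelihood file, or ``NA`` when the
individual was not sequenced.  Lines starting with ``#`` are ignored.

Every individual referenced as a parent must have its own row: members
are never auto-created from parent references.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .errors import (
    CyclicAncestryError,
    DanglingReferenceError,
    DuplicateIdError,
    GenderInconsistencyError,
    MissingParentError,
    PedigreeError,
)

NO_PARENT = "0"
NA_SAMPLE = "NA"


class Gender(enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, token: str) -> "Gender":
        t = token.strip().lower()
        if t in ("1", "m", "male"):
            return cls.MALE
        if t in ("2", "f", "female"):
            return cls.FEMALE
        raise PedigreeError(f"unrecognised gender token: {token!r}")


@dataclass(frozen=True)
class Individual:
    """One pedigree row.

    ``mother_id``/``father_id`` are ``None`` for founders and
    ``sample_name`` is ``None`` iff the individual was not sequenced.
    """

    id: str
    mother_id: str | None
    father_id: str | None
    gender: Gender
    sample_name: str | None

    @property
    def is_founder(self) -> bool:
        return self.mother_id is None and self.father_id is None


@dataclass(frozen=True)
class NuclearFamily:
    """A (father, mother) couple and their common children (member positions)."""

    father: int
    mother: int
    children: tuple[int, ...]


@dataclass(frozen=True)
class Relations:
    """Nuclear relations of one member: the neighbours that its genotype
    full conditional depends on (parents, mates and children)."""

    parents: frozenset[int]
    mates: frozenset[int]
    children: frozenset[int]


@dataclass(frozen=True, eq=False)
class Pedigree:
    """Validated family graph; member order is file order."""

    members: tuple[Individual, ...]
    father_index: tuple[int, ...]  # -1 for founders
    mother_index: tuple[int, ...]
    has_loop: bool
    sequenced_index: dict[str, int] = field(repr=False)
    _id_index: dict[str, int] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.members)

    def is_founder(self, i: int) -> bool:
        return self.father_index[i] < 0

    def position_of(self, member_id: str) -> int:
        return self._id_index[member_id]

    @classmethod
    def from_individuals(cls, members: Iterable[Individual]) -> "Pedigree":
        members = tuple(members)
        if not members:
            raise PedigreeError("pedigree has no members")

        index: dict[str, int] = {}
        for i, m in enumerate(members):
            if m.id in index:
                raise DuplicateIdError(f"duplicate member id {m.id!r}")
            index[m.id] = i

        sequenced: dict[str, int] = {}
        for i, m in enumerate(members):
            if m.sample_name is None:
                continue
            if m.sample_name in sequenced:
                raise DuplicateIdError(f"duplicate sample name {m.sample_name!r}")
            sequenced[m.sample_name] = i

        father_index: list[int] = []
        mother_index: list[int] = []
        for m in members:
            if (m.mother_id is None) != (m.father_id is None):
                raise MissingParentError(
                    f"member {m.id!r} lists exactly one parent; pedigrees must be "
                    "complete (both parents or none)"
                )
            if m.is_founder:
                father_index.append(-1)
                mother_index.append(-1)
                continue
            for pid, role, wanted in (
                (m.father_id, "father", Gender.MALE),
                (m.mother_id, "mother", Gender.FEMALE),
            ):
                if pid not in index:
                    raise DanglingReferenceError(
                        f"{role} {pid!r} of member {m.id!r} has no row of its own"
                    )
                if members[index[pid]].gender is not wanted:
                    raise GenderInconsistencyError(
                        f"{role} {pid!r} of member {m.id!r} is not {wanted.value}"
                    )
            father_index.append(index[m.father_id])
            mother_index.append(index[m.mother_id])

        ancestry = nx.DiGraph()
        ancestry.add_nodes_from(range(len(members)))
        for i in range(len(members)):
            if father_index[i] >= 0:
                ancestry.add_edge(father_index[i], i)
                ancestry.add_edge(mother_index[i], i)
        if not nx.is_directed_acyclic_graph(ancestry):
            raise CyclicAncestryError("a member is its own ancestor")

        ped = cls(
            members=members,
            father_index=tuple(father_index),
            mother_index=tuple(mother_index),
            has_loop=False,
            sequenced_index=sequenced,
            _id_index=index,
        )
        object.__setattr__(ped, "has_loop", detect_loops(ped))
        return ped

    def families(self) -> list[NuclearFamily]:
        """Nuclear families in order of first appearance of a child."""
        by_couple: dict[tuple[int, int], list[int]] = {}
        order: list[tuple[int, int]] = []
        for i in range(self.n):
            if self.is_founder(i):
                continue
            key = (self.father_index[i], self.mother_index[i])
            if key not in by_couple:
                by_couple[key] = []
                order.append(key)
            by_couple[key].append(i)
        return [
            NuclearFamily(father=f, mother=m, children=tuple(by_couple[(f, m)]))
            for f, m in order
        ]

    def children_of(self, i: int) -> tuple[int, ...]:
        cache = self.__dict__.get("_children_cache")
        if cache is None:
            cache = [[] for _ in range(self.n)]
            for c in range(self.n):
                if not self.is_founder(c):
                    cache[self.father_index[c]].append(c)
                    cache[self.mother_index[c]].append(c)
            cache = [tuple(cs) for cs in cache]
            object.__setattr__(self, "_children_cache", cache)
        return cache[i]

    def nuclear_relations(self, i: int) -> Relations:
        if not (0 <= i < self.n):
            raise IndexError(i)
        parents: set[int] = set()
        if not self.is_founder(i):
            parents = {self.father_index[i], self.mother_index[i]}
        mates: set[int] = set()
        children = set(self.children_of(i))
        for c in children:
            mate = (
                self.mother_index[c]
                if self.father_index[c] == i
                else self.father_index[c]
            )
            mates.add(mate)
        return Relations(
            parents=frozenset(parents),
            mates=frozenset(mates),
            children=frozenset(children),
        )


def detect_loops(ped: Pedigree) -> bool:
    """True iff the bipartite {individual} ∪ {nuclear family} graph has a cycle.

    This covers consanguineous loops (related mates) and marriage loops
    (e.g. two sibships exchanging spouses); both break anterior/posterior
    peeling, so both route to exact enumeration.
    """
    g = nx.Graph()
    g.add_nodes_from(("i", k) for k in range(ped.n))
    for j, fam in enumerate(ped.families()):
        g.add_node(("f", j))
        g.add_edge(("f", j), ("i", fam.father))
        g.add_edge(("f", j), ("i", fam.mother))
        for c in fam.children:
            g.add_edge(("f", j), ("i", c))
    # a graph is a forest iff |E| = |V| - #components
    return g.number_of_edges() > g.number_of_nodes() - nx.number_connected_components(g)


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse and validate a pedigree structure file."""
    members: list[Individual] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 5:
            raise PedigreeError(
                f"{path}:{lineno}: expected 5 columns "
                f"(ID mID fID gender sampleName), got {len(fields)}"
            )
        mid, fid = fields[1], fields[2]
        members.append(
            Individual(
                id=fields[0],
                mother_id=None if mid == NO_PARENT else mid,
                father_id=None if fid == NO_PARENT else fid,
                gender=Gender.parse(fields[3]),
                sample_name=None if fields[4] == NA_SAMPLE else fields[4],
            )
        )
    return Pedigree.from_individuals(members)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write a pedigree back to the five-column text format."""
    lines = ["# ID mID fID gender sampleName"]
    for m in ped.members:
        lines.append(
            " ".join(
                (
                    m.id,
                    m.mother_id or NO_PARENT,
                    m.father_id or NO_PARENT,
                    "1" if m.gender is Gender.MALE else "2",
                    m.sample_name or NA_SAMPLE,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
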