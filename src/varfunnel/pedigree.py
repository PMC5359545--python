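"""Studbook pedigree engine for an autosomal recessive locus.

Supports obligate-carrier inference (unaffected parents of affected
offspring are necessarily heterozygous), Mendelian consistency checks of
genotype dosage assignments, undirected lineage connectivity, and at-risk
identification: an ungenotyped individual is *at risk* when some
Mendelian-consistent completion of the partially genotyped pedigree assigns
it at least one copy of the variant allele.  "At risk" is a possibility
statement, not a numeric carrier probability.

Founders that are not ancestral to any known carrier or affected individual
are assumed homozygous reference by default — outside lineages are treated
as wild type — which keeps the enumeration over unknown genotypes small and
reflects how studbook populations with a single deleterious founder allele
are managed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .core import PhenotypeStatus, VarFunnelError

__all__ = [
    "Sex",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "EnumerationBoundError",
    "obligate_carriers",
    "mendelian_consistent",
    "at_risk_individuals",
    "connected_component",
]


class PedigreeError(VarFunnelError):
    """Structural problem in a pedigree (cycles, missing members, ...)."""


class EnumerationBoundError(PedigreeError):
    """Too many ungenotyped individuals for exhaustive enumeration."""


class Sex(enum.IntEnum):
    UNKNOWN = 0
    MALE = 1
    FEMALE = 2


@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None = None
    dam: str | None = None
    sex: Sex = Sex.UNKNOWN
    phenotype: PhenotypeStatus = PhenotypeStatus.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """A set of individuals with parent links and partial known genotypes.

    ``known_genotypes`` maps individual id to an alternate-allele dosage in
    {0, 1, 2} at the locus under study.
    """

    def __init__(
        self,
        individuals: Iterable[Individual],
        known_genotypes: Mapping[str, int] | None = None,
    ) -> None:
        self._individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._individuals:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._individuals[ind.id] = ind
        for ind in self._individuals.values():
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in self._individuals:
                    raise PedigreeError(
                        f"parent {parent!r} of {ind.id!r} is not in the pedigree"
                    )
        self._check_acyclic()
        self.known_genotypes: dict[str, int] = {}
        for iid, g in (known_genotypes or {}).items():
            if iid not in self._individuals:
                raise PedigreeError(f"genotyped individual {iid!r} not in pedigree")
            if g not in (0, 1, 2):
                raise PedigreeError(f"genotype of {iid!r} must be 0, 1 or 2; got {g!r}")
            self.known_genotypes[iid] = g

    def _check_acyclic(self) -> None:
        dag = nx.DiGraph()
        dag.add_nodes_from(self._individuals)
        for ind in self._individuals.values():
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    dag.add_edge(parent, ind.id)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise PedigreeError(
                "pedigree contains a cycle (an individual is its own ancestor): "
                + " -> ".join(str(edge[0]) for edge in cycle)
            )
        self._dag = dag

    # -- accessors ---------------------------------------------------------

    def __contains__(self, iid: str) -> bool:
        return iid in self._individuals

    def __len__(self) -> int:
        return len(self._individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self._individuals[iid]

    @property
    def ids(self) -> list[str]:
        return list(self._individuals)

    @property
    def individuals(self) -> list[Individual]:
        return list(self._individuals.values())

    def founders(self) -> list[str]:
        return [i.id for i in self._individuals.values() if i.is_founder]

    def parents_of(self, iid: str) -> list[str]:
        ind = self._individuals[iid]
        return [p for p in (ind.sire, ind.dam) if p is not None]

    def children_of(self, iid: str) -> list[str]:
        return sorted(self._dag.successors(iid))

    def topological_order(self) -> list[str]:
        """Ids with every parent before its children."""
        return list(nx.topological_sort(self._dag))

    def descendants(self, iid: str) -> set[str]:
        return set(nx.descendants(self._dag, iid))

    def undirected_graph(self) -> nx.Graph:
        return self._dag.to_undirected(as_view=False)

    def affected_ids(self) -> list[str]:
        return [
            i.id
            for i in self._individuals.values()
            if i.phenotype is PhenotypeStatus.AFFECTED
        ]


# -- operations ------------------------------------------------------------


def obligate_carriers(pedigree: Pedigree, affected_ids: Iterable[str]) -> set[str]:
    """Unaffected parents of affected individuals.

    Under an autosomal recessive model every parent of an affected offspring
    transmits one variant allele, so unaffected parents are necessarily
    heterozygous carriers.
    """
    out: set[str] = set()
    for aid in affected_ids:
        if aid not in pedigree:
            raise PedigreeError(f"affected individual {aid!r} not in pedigree")
        for parent in pedigree.parents_of(aid):
            if pedigree[parent].phenotype is not PhenotypeStatus.AFFECTED:
                out.add(parent)
    return out


def _child_dosages(p: int, q: int) -> set[int]:
    """Offspring dosages attainable from parental dosages p and q."""
    alleles = {0: (0,), 1: (0, 1), 2: (1,)}
    return {a + b for a in alleles[p] for b in alleles[q]}


def _consistent_with_parents(
    pedigree: Pedigree, iid: str, assignment: Mapping[str, int]
) -> bool:
    ind = pedigree[iid]
    child = assignment[iid]
    sire, dam = ind.sire, ind.dam
    if sire is None and dam is None:
        return True
    alleles = {0: (0,), 1: (0, 1), 2: (1,)}
    sire_alleles = alleles[assignment[sire]] if sire is not None else (0, 1)
    dam_alleles = alleles[assignment[dam]] if dam is not None else (0, 1)
    return child in {a + b for a in sire_alleles for b in dam_alleles}


def mendelian_consistent(pedigree: Pedigree, assignment: Mapping[str, int]) -> bool:
    """True iff a total dosage assignment obeys biallelic Mendelian
    transmission: every non-founder's dosage is attainable by drawing one
    allele from each parent."""
    missing = [iid for iid in pedigree.ids if iid not in assignment]
    if missing:
        raise PedigreeError(
            f"assignment is not total; missing individuals: {sorted(missing)}"
        )
    return all(
        _consistent_with_parents(pedigree, iid, assignment) for iid in pedigree.ids
    )


def connected_component(pedigree: Pedigree, seed_ids: Iterable[str]) -> set[str]:
    """All individuals reachable from the seeds via undirected
    parent--child edges (the seeds' lineage)."""
    graph = pedigree.undirected_graph()
    out: set[str] = set()
    for seed in seed_ids:
        if seed not in pedigree:
            raise PedigreeError(f"seed individual {seed!r} not in pedigree")
        out |= nx.node_connected_component(graph, seed)
    return out


def _fixed_founders(pedigree: Pedigree) -> set[str]:
    """Founders assumed homozygous reference: those with no descendant (and
    not themselves) among known carriers or affected individuals."""
    flagged = {iid for iid, g in pedigree.known_genotypes.items() if g >= 1}
    flagged |= set(pedigree.affected_ids())
    fixed: set[str] = set()
    for founder in pedigree.founders():
        if founder in pedigree.known_genotypes or founder in flagged:
            continue
        if pedigree.descendants(founder) & flagged:
            continue
        fixed.add(founder)
    return fixed


def at_risk_individuals(
    pedigree: Pedigree,
    *,
    assume_outside_founders_homref: bool = True,
    max_unknowns: int = 20,
) -> set[str]:
    """Ungenotyped individuals that could carry the variant allele.

    Returns every individual with unknown genotype for which some
    Mendelian-consistent completion of the pedigree (respecting known
    genotypes and, by default, homozygous-reference founders outside the
    carrier lineage) assigns dosage >= 1.  Found by exhaustive depth-first
    enumeration over the unknowns in topological order, pruning assignments
    inconsistent with already-assigned parents.

    Raises
    ------
    EnumerationBoundError
        If more than ``max_unknowns`` genotypes would need enumerating.
    """
    fixed: dict[str, int] = dict(pedigree.known_genotypes)
    if assume_outside_founders_homref:
        for founder in _fixed_founders(pedigree):
            fixed.setdefault(founder, 0)

    order = pedigree.topological_order()
    unknowns = [iid for iid in order if iid not in fixed]
    if len(unknowns) > max_unknowns:
        raise EnumerationBoundError(
            f"{len(unknowns)} ungenotyped individuals exceed the enumeration "
            f"bound of {max_unknowns}; subdivide the pedigree or raise the bound"
        )

    at_risk: set[str] = set()
    assignment: dict[str, int] = dict(fixed)

    # Individuals whose parents are all assigned before them, in topological
    # order, so a partial assignment can be checked incrementally.  Known
    # individuals are re-checked once both parents are assigned.
    def check(iid: str) -> bool:
        return _consistent_with_parents(pedigree, iid, assignment)

    def assigned_children_ok(iid: str) -> bool:
        # re-validate fixed children whose parents just became assigned
        for child in pedigree.children_of(iid):
            if child in fixed and all(
                p in assignment for p in pedigree.parents_of(child)
            ):
                if not _consistent_with_parents(pedigree, child, assignment):
                    return False
        return True

    # quick sanity: fixed individuals with fully fixed parents must be consistent
    for iid in order:
        if iid in fixed and all(p in fixed for p in pedigree.parents_of(iid)):
            if not _consistent_with_parents(pedigree, iid, fixed):
                raise PedigreeError(
                    f"known genotypes are Mendelian-inconsistent at {iid!r}"
                )

    def recurse(i: int) -> None:
        if at_risk >= set(unknowns):
            return
        if i == len(unknowns):
            for iid in unknowns:
                if assignment[iid] >= 1:
                    at_risk.add(iid)
            return
        iid = unknowns[i]
        for dosage in (0, 1, 2):
            assignment[iid] = dosage
            if check(iid) and assigned_children_ok(iid):
                recurse(i + 1)
        del assignment[iid]

    recurse(0)
    return at_risk
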