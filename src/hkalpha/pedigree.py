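"""Mendelian constraint propagation over a pedigree.

Each individual starts with an ambiguity set of diploid genotypes (from the
reflex caller, or the full genotype space when unsampled).  Iterated
arc-consistency over (father, mother, child) triples prunes a genotype
whenever no compatible genotypes survive for the other two members of some
triple, where a child genotype is compatible iff one allele can come whole
from each parent — the HKαα fusion allele is transmitted as an atom, never
split into its αααanti4.2 and -α3.7 constituents.

The study pedigree is loop-free; on tree-shaped pedigrees arc-consistency
over triples is exact (it matches the brute-force closure).  On hypothetical
loopy pedigrees the surviving sets are an over-approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from hkalpha.calling import Genotype, all_genotypes, genotype_key
from hkalpha.cluster import GENOTYPE_LIBRARY
from hkalpha.cohort import PedigreeGraph


class InconsistentPedigree(ValueError):
    pass


@dataclass
class ResolutionState:
    pedigree: PedigreeGraph
    sets: dict[str, set[Genotype]]
    library: tuple[str, ...] = GENOTYPE_LIBRARY
    at_fixed_point: bool = False
    log: list[str] = field(default_factory=list)

    def copy(self) -> "ResolutionState":
        return ResolutionState(
            self.pedigree,
            {k: set(v) for k, v in self.sets.items()},
            self.library,
            self.at_fixed_point,
            list(self.log),
        )


def full_space(library: tuple[str, ...] = GENOTYPE_LIBRARY) -> set[Genotype]:
    return set(all_genotypes(library))


def child_compatible(child: Genotype, father: Genotype | None, mother: Genotype | None) -> bool:
    """True iff the child can receive one whole allele from each parent.

    A ``None`` parent is unconstrained (unsampled individual outside the
    pedigree table): any allele may come from that side.
    """
    a, b = child
    f = set(father) if father is not None else None
    m = set(mother) if mother is not None else None
    for pat, mat in ((a, b), (b, a)):
        if (f is None or pat in f) and (m is None or mat in m):
            return True
    return False


def _triples(ped: PedigreeGraph):
    for child, (father, mother) in sorted(ped.parent_links.items()):
        yield child, father, mother


def resolve(state: ResolutionState) -> ResolutionState:
    """Iterate triple-wise support pruning to a fixed point (deterministic).

    Raises :class:`InconsistentPedigree` naming the triple whenever a set
    empties.
    """
    state = state.copy()
    sets = state.sets
    for iid in state.pedigree.individuals:
        sets.setdefault(iid, full_space(state.library))

    changed = True
    while changed:
        changed = False
        for child, father, mother in _triples(state.pedigree):
            fset = sets.get(father) if father else None
            mset = sets.get(mother) if mother else None

            def supported_child(g: Genotype) -> bool:
                fs = fset if fset is not None else [None]
                ms = mset if mset is not None else [None]
                return any(child_compatible(g, f, m) for f in fs for m in ms)

            def supported_parent(pg: Genotype, side: str) -> bool:
                other = mset if side == "father" else fset
                others = other if other is not None else [None]
                for cg in sets[child]:
                    for og in others:
                        f, m = (pg, og) if side == "father" else (og, pg)
                        if child_compatible(cg, f, m):
                            return True
                return False

            new_child = {g for g in sets[child] if supported_child(g)}
            if new_child != sets[child]:
                pruned = sorted(set(sets[child]) - new_child)
                state.log.append(f"{child}: pruned {pruned} by parents ({father},{mother})")
                sets[child] = new_child
                changed = True
            if not sets[child]:
                raise InconsistentPedigree(
                    f"no genotype of {child} is consistent with parents "
                    f"({father}, {mother})"
                )
            for side, pid in (("father", father), ("mother", mother)):
                if pid is None:
                    continue
                new_p = {g for g in sets[pid] if supported_parent(g, side)}
                if new_p != sets[pid]:
                    pruned = sorted(set(sets[pid]) - new_p)
                    state.log.append(f"{pid}: pruned {pruned} by triple ({father},{mother},{child})")
                    sets[pid] = new_p
                    changed = True
                if not sets[pid]:
                    raise InconsistentPedigree(
                        f"no genotype of {pid} is consistent with triple "
                        f"({father}, {mother}, {child})"
                    )
    state.at_fixed_point = True
    return state


def brute_force_closure(
    state: ResolutionState,
    max_individuals: int = 8,
    max_alleles: int | None = 7,
) -> dict[str, set[Genotype]]:
    """Exact per-individual projections by joint enumeration (oracle).

    Enumerates, by backtracking over individuals in id order, every joint
    assignment drawn from the current local sets that satisfies every
    child/parents constraint, then projects onto each individual.  Intended
    for verification on small instances only.
    """
    ped = state.pedigree
    ids = sorted(ped.individuals)
    if len(ids) > max_individuals:
        raise ValueError(
            f"brute force refused: {len(ids)} individuals exceeds bound {max_individuals}"
        )
    alleles = {a for s in state.sets.values() for g in s for a in g}
    if max_alleles is not None and len(alleles) > max_alleles:
        raise ValueError(f"brute force refused: {len(alleles)} alleles exceeds bound")

    sets = {iid: sorted(state.sets.get(iid, full_space(state.library))) for iid in ids}
    order = {iid: i for i, iid in enumerate(ids)}
    projections: dict[str, set[Genotype]] = {iid: set() for iid in ids}
    assignment: dict[str, Genotype] = {}

    def consistent_so_far(iid: str) -> bool:
        # check every triple whose members are all assigned so far
        for child, (father, mother) in ped.parent_links.items():
            members = [child] + [p for p in (father, mother) if p is not None]
            if iid not in members:
                continue
            if any(m not in assignment for m in members if m in order):
                continue
            if not child_compatible(
                assignment[child],
                assignment.get(father) if father else None,
                assignment.get(mother) if mother else None,
            ):
                return False
        return True

    def backtrack(k: int) -> None:
        if k == len(ids):
            for iid in ids:
                projections[iid].add(assignment[iid])
            return
        iid = ids[k]
        for g in sets[iid]:
            assignment[iid] = g
            if consistent_so_far(iid):
                backtrack(k + 1)
            del assignment[iid]

    backtrack(0)
    return projections


def resolve_pedigree_calls(
    ped: PedigreeGraph,
    calls: dict[str, set[Genotype]],
    library: tuple[str, ...] = GENOTYPE_LIBRARY,
) -> ResolutionState:
    """Convenience wrapper: build a state from per-individual call sets."""
    sets = {iid: set(calls.get(iid, full_space(library))) for iid in ped.individuals}
    return resolve(ResolutionState(ped, sets, library))


def ambiguity_column(state: ResolutionState) -> dict[str, str]:
    """Semicolon-separated genotype strings (alleles sorted lexically)."""
    return {
        iid: ";".join("/".join(g) for g in sorted(state.sets[iid]))
        for iid in sorted(state.sets)
    }
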