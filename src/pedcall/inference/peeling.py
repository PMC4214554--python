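"""Elston-Stewart peeling: exact genotype marginals on loop-free
pedigrees in time near-linear in pedigree size.

The pedigree is viewed as a tree whose nodes are individuals and nuclear
families (one node per distinct father-mother couple, linked to both
parents and all their common children); on a loop-free pedigree this
graph is a forest.  Peeling is the standard anterior/posterior recursion
expressed as two sweeps of messages over that tree:

* the *anterior* of a member is the message arriving from its parental
  family (the probability of the evidence "above" it); for a founder the
  anterior is the population genotype prior;
* the *posterior* contribution of a mate is the message arriving from
  the spousal family shared with that mate (the evidence "below",
  through that mate and their common children, including the mate's own
  ancestral evidence).

A member's marginal is then proportional to
``anterior x P(D_i|g) x prod over mates of posterior_by_mate``,
which agrees with exhaustive enumeration to floating-point accuracy.
Messages are renormalised as they are formed, which plays the same
numerical-stabilisation role as the log-max shift in the enumeration
engine.  Pedigrees with loops (consanguineous or marriage loops) are a
hard error here; the caller routes them to exact enumeration.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from ..errors import LoopedPedigreeError, NormalizationError
from ..evidence import PosteriorCall, SiteEvidence
from ..pedigree import NuclearFamily, Pedigree

Node = tuple[str, int]  # ("i", member position) or ("f", family index)


@dataclass(frozen=True, eq=False)
class PeelingTables:
    """Anterior vectors (one per member) and per-(member, mate) posterior
    contribution vectors, all genotype-indexed and normalised."""

    anterior: np.ndarray  # (n, 3)
    posterior_by_mate: dict[tuple[int, int], np.ndarray]


def _tree_order(ped: Pedigree):
    """BFS node order and parent pointers of the individual/family tree.

    Each component is rooted at the family adjacent to its lowest-index
    member (that member's parental family if it has one, else its first
    spousal family); isolated members root at themselves.  The order is
    deterministic given member order.
    """
    fams = ped.families()
    adj: dict[Node, list[Node]] = defaultdict(list)
    for j, fam in enumerate(fams):
        for k in {fam.father, fam.mother, *fam.children}:
            adj[("i", k)].append(("f", j))
            adj[("f", j)].append(("i", k))
    for j, fam in enumerate(fams):
        adj[("f", j)].sort()

    parent: dict[Node, Node | None] = {}
    order: list[Node] = []
    seen: set[Node] = set()
    for k in range(ped.n):
        start: Node = ("i", k)
        if start in seen:
            continue
        neighbours = adj[start]
        parental = next(
            (("f", j) for (_, j) in neighbours if k in fams[j].children), None
        )
        root: Node = parental or (neighbours[0] if neighbours else start)
        parent[root] = None
        seen.add(root)
        queue = [root]
        while queue:
            node = queue.pop(0)
            order.append(node)
            for nb in adj[node]:
                if nb in seen:
                    continue
                seen.add(nb)
                parent[nb] = node
                queue.append(nb)
    return order, parent, adj, fams


def peeling_order(ped: Pedigree) -> list[NuclearFamily]:
    """Nuclear families in a valid elimination order (leaf families first)."""
    if ped.has_loop:
        raise LoopedPedigreeError("peeling requires a loop-free pedigree")
    order, _, _, fams = _tree_order(ped)
    return [fams[j] for kind, j in reversed(order) if kind == "f"]


def _normalise(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    return v / s if s > 0 else v


def peel_posteriors(
    ev: SiteEvidence, ped: Pedigree, return_tables: bool = False
):
    """Exact marginals on a loop-free pedigree via two message sweeps."""
    if ped.has_loop:
        raise LoopedPedigreeError(
            "pedigree has a loop; use exact enumeration (method='exact') instead"
        )
    n = ped.n
    tensor = ev.transmission.tensor
    prior = ev.prior.as_array()
    local = ev.likelihoods.copy()
    for i in range(n):
        if ped.is_founder(i):
            local[i] *= prior

    order, parent, adj, fams = _tree_order(ped)
    msg: dict[tuple[Node, Node], np.ndarray] = {}

    def ind_to_fam(k: int, j: int) -> np.ndarray:
        v = local[k].copy()
        for kind, j2 in adj[("i", k)]:
            if j2 != j:
                v = v * msg[(("f", j2), ("i", k))]
        return _normalise(v)

    def fam_to_ind(j: int, k: int) -> np.ndarray:
        fam = fams[j]
        incoming = {
            kk: msg[(("i", kk), ("f", j))]
            for kk in {fam.father, fam.mother, *fam.children}
            if kk != k
        }
        child_factor = np.ones((3, 3))  # over (g_father, g_mother)
        for c in fam.children:
            if c != k:
                child_factor *= tensor @ incoming[c]
        if k == fam.father:
            v = child_factor @ incoming[fam.mother]
        elif k == fam.mother:
            v = child_factor.T @ incoming[fam.father]
        else:
            couple = np.outer(incoming[fam.father], incoming[fam.mother]) * child_factor
            v = np.einsum("fm,fmg->g", couple, tensor)
        return _normalise(v)

    def send(src: Node, dst: Node) -> None:
        if src[0] == "i":
            msg[(src, dst)] = ind_to_fam(src[1], dst[1])
        else:
            msg[(src, dst)] = fam_to_ind(src[1], dst[1])

    for node in reversed(order):  # leaves towards roots
        p = parent[node]
        if p is not None:
            send(node, p)
    for node in order:  # roots towards leaves
        for nb in adj[node]:
            if parent.get(nb) == node:
                send(node, nb)

    post = np.empty((n, 3))
    for k in range(n):
        v = local[k].copy()
        for _, j in adj[("i", k)]:
            v = v * msg[(("f", j), ("i", k))]
        s = v.sum()
        if s <= 0:
            raise NormalizationError(
                "total joint weight is zero (contradictory evidence at m=0)"
            )
        post[k] = v / s
    call = PosteriorCall(post, mode="family")
    if not return_tables:
        return call

    anterior = np.empty((n, 3))
    posterior_by_mate: dict[tuple[int, int], np.ndarray] = {}
    for k in range(n):
        if ped.is_founder(k):
            anterior[k] = prior
        else:
            j = next(j for _, j in adj[("i", k)] if k in fams[j].children)
            anterior[k] = msg[(("f", j), ("i", k))]
        for _, j in adj[("i", k)]:
            fam = fams[j]
            if k == fam.father:
                posterior_by_mate[(k, fam.mother)] = msg[(("f", j), ("i", k))]
            elif k == fam.mother:
                posterior_by_mate[(k, fam.father)] = msg[(("f", j), ("i", k))]
    return call, PeelingTables(anterior=anterior, posterior_by_mate=posterior_by_mate)
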