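"""Multispecies-coalescent pseudo-likelihood on rooted-triple counts.

The likelihood of a species tree given a set of rooted gene trees is the
product over species triples of a multinomial on the three rooted
resolutions, with the concordant probability 1 - (2/3)e^{-tau} where tau is
the internal path length (coalescent units) separating the triple's cherry
from its root in the species tree.  Branch lengths are fitted on a fixed
topology; the objective is concave in the internal lengths, so a single
bounded quasi-Newton run finds the global maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .trees import Tree, TreeError, is_binary, leaf_labels, parse_newick

__all__ = [
    "SpeciesTreeCU",
    "TripleTable",
    "GeneTreeSet",
    "triple_counts",
    "triple_probs",
    "triple_tau",
    "pseudo_loglik",
    "fit_branch_lengths",
    "TAU_MIN",
    "TAU_MAX",
    "PROB_FLOOR",
]

TAU_MIN = 1e-6
TAU_MAX = 10.0
PROB_FLOOR = 1e-300


def triple_probs(tau: float) -> tuple[float, float, float]:
    """Rooted-triple probabilities (concordant, discordant, discordant).

    p_concordant = 1 - (2/3) e^{-tau}; the two discordant resolutions each
    have probability (1/3) e^{-tau}.  The three sum to 1 for any tau >= 0.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    d = math.exp(-tau) / 3.0
    return 1.0 - 2.0 * d, d, d


def _pair_slot(a: str, b: str, triple: tuple[str, str, str]) -> int:
    """Slot index of the resolution pairing {a,b} within a sorted triple.

    Convention for sorted triple (x, y, z): slot 0 = xy|z, 1 = xz|y, 2 = yz|x.
    """
    pair = frozenset((a, b))
    x, y, z = triple
    if pair == frozenset((x, y)):
        return 0
    if pair == frozenset((x, z)):
        return 1
    return 2


@dataclass
class TripleTable:
    """Counts of rooted-triple resolutions across a gene-tree set.

    ``counts[i, j]`` is the number of gene trees resolving sorted triple
    ``triples[i]`` in favor of slot ``j`` (see :func:`_pair_slot` for the
    slot convention).
    """

    species: tuple[str, ...]
    triples: tuple[tuple[str, str, str], ...]
    counts: np.ndarray  # (n_triples, 3) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.triples), 3):
            raise ValueError("counts shape does not match triples")
        if (self.counts < 0).any():
            raise ValueError("negative triple counts")
        self._index = {t: i for i, t in enumerate(self.triples)}

    @classmethod
    def empty(cls, species: Iterable[str]) -> "TripleTable":
        sp = tuple(sorted(set(species)))
        triples = tuple(combinations(sp, 3))
        return cls(sp, triples, np.zeros((len(triples), 3)))

    def get(self, a: str, b: str, c: str) -> tuple[float, float, float]:
        key = tuple(sorted((a, b, c)))
        return tuple(self.counts[self._index[key]])

    def total(self, a: str, b: str, c: str) -> float:
        key = tuple(sorted((a, b, c)))
        return float(self.counts[self._index[key]].sum())


@dataclass
class GeneTreeSet:
    """A list of rooted gene trees with their per-gene taxon occupancy."""

    trees: list[Tree]
    occupancy: list[frozenset[str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for i, t in enumerate(self.trees):
            n_leaves = sum(1 for _ in t.leaf_node_iter())
            if n_leaves < 3:
                continue  # 1- and 2-leaf trees carry no triple information
            if not t.is_rooted or len(t.seed_node.child_nodes()) != 2:
                raise TreeError(
                    f"gene tree {i} is not rooted; root it first "
                    "(e.g. trees.root_by_outgroup)"
                )
        if self.occupancy is None:
            self.occupancy = [leaf_labels(t) for t in self.trees]

    def __len__(self):
        return len(self.trees)

    @property
    def species(self) -> tuple[str, ...]:
        out = set()
        for occ in self.occupancy:
            out |= occ
        return tuple(sorted(out))


def _resolved_triples(tree: Tree):
    """Yield (sorted_triple, slot) for every triple the rooted tree resolves.

    For each internal node v, pairs of leaves whose MRCA is v form a cherry
    against any third leaf outside v's subtree; triples whose three pairwise
    MRCAs coincide (a polytomy at the triple's root) are unresolved and
    skipped.
    """
    all_leaves = sorted(leaf_labels(tree))
    for nd in tree.postorder_internal_node_iter():
        kids = nd.child_nodes()
        child_sets = [sorted(l.taxon.label for l in k.leaf_iter()) for k in kids]
        below = set()
        for cs in child_sets:
            below.update(cs)
        outside = [x for x in all_leaves if x not in below]
        if not outside:
            continue
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                for a in child_sets[i]:
                    for b in child_sets[j]:
                        for c in outside:
                            triple = tuple(sorted((a, b, c)))
                            yield triple, _pair_slot(a, b, triple)


def triple_counts(genes: GeneTreeSet, species: Iterable[str] | None = None) -> TripleTable:
    """Tabulate rooted-triple resolutions across a gene-tree set.

    Each gene tree containing (and resolving) a triple increments exactly one
    of its three counts; genes missing any taxon of the triple, or leaving it
    unresolved at a polytomy, contribute nothing.
    """
    table = TripleTable.empty(species if species is not None else genes.species)
    idx = table._index
    for tree in genes.trees:
        for triple, slot in _resolved_triples(tree):
            i = idx.get(triple)
            if i is None:
                raise TreeError(f"gene tree contains taxa outside the species set: {triple}")
            table.counts[i, slot] += 1
    return table


# ---------------------------------------------------------------------------
# Species tree in coalescent units
# ---------------------------------------------------------------------------

class SpeciesTreeCU:
    """Rooted binary species tree with internal branch lengths in coalescent units.

    Terminal branch lengths carry no information in the one-allele-per-species
    pseudo-likelihood and are ignored.  Internal lengths may be absent (a bare
    topology) until fitted.
    """

    def __init__(self, tree: Tree):
        if not is_binary(tree):
            raise TreeError("species tree must be rooted and binary")
        self.tree = tree
        self.species = tuple(sorted(leaf_labels(tree)))
        self._bit = {s: 1 << i for i, s in enumerate(self.species)}
        self._build_index()

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTreeCU":
        return cls(parse_newick(text))

    def _build_index(self):
        # postorder arrays: for each node, taxon bitmask and parent-edge info
        self._post = list(self.tree.postorder_node_iter())
        self._node_id = {id(nd): i for i, nd in enumerate(self._post)}
        self._mask = []
        for nd in self._post:
            if nd.is_leaf():
                self._mask.append(self._bit[nd.taxon.label])
            else:
                m = 0
                for k in nd.child_nodes():
                    m |= self._mask[self._node_id[id(k)]]
                self._mask.append(m)
        # internal edges: edge above an internal, non-root node
        self._param_nodes = [
            nd for nd in self._post
            if (not nd.is_leaf()) and nd.parent_node is not None
        ]
        self._param_index = {id(nd): i for i, nd in enumerate(self._param_nodes)}
        self.n_internal_edges = len(self._param_nodes)

        # per-triple structure: concordant slot + which internal edges lie on
        # the path from the cherry MRCA to the triple MRCA
        self.triples = tuple(combinations(self.species, 3))
        n_t = len(self.triples)
        A = np.zeros((n_t, self.n_internal_edges))
        slots = np.zeros(n_t, dtype=int)
        for ti, (a, b, c) in enumerate(self.triples):
            pair, path = self._cherry_and_path(a, b, c)
            slots[ti] = _pair_slot(pair[0], pair[1], (a, b, c))
            for nd in path:
                A[ti, self._param_index[id(nd)]] = 1.0
        self._A = A
        self._slots = slots

    def _mrca(self, mask: int):
        for i, nd in enumerate(self._post):
            if self._mask[i] & mask == mask:
                return nd
        raise TreeError("species missing from species tree")

    def _cherry_and_path(self, a: str, b: str, c: str):
        """Species-tree concordant pair of a triple and the internal-edge path
        from the pair's MRCA up to the triple's MRCA."""
        for s in (a, b, c):
            if s not in self._bit:
                raise TreeError(f"species {s!r} missing from species tree")
        m_abc = self._bit[a] | self._bit[b] | self._bit[c]
        top = self._mrca(m_abc)
        for x, y in ((a, b), (a, c), (b, c)):
            nd = self._mrca(self._bit[x] | self._bit[y])
            if nd is not top:
                path = []
                cur = nd
                while cur is not top:
                    path.append(cur)
                    cur = cur.parent_node
                return (x, y), path
        raise TreeError("species tree is not binary at triple "
                        f"{{{a}, {b}, {c}}}")

    # -- branch lengths ----------------------------------------------------

    def internal_lengths(self) -> np.ndarray:
        """Vector of internal branch lengths, in the tree's parameter order."""
        out = np.empty(self.n_internal_edges)
        for i, nd in enumerate(self._param_nodes):
            if nd.edge.length is None:
                raise TreeError("species tree has an internal edge without a length")
            out[i] = float(nd.edge.length)
        if (out < 0).any():
            raise TreeError("negative internal branch length")
        return out

    def with_internal_lengths(self, x: Sequence[float]) -> "SpeciesTreeCU":
        """Copy of this species tree with the given internal branch lengths."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_internal_edges,):
            raise ValueError("wrong number of internal branch lengths")
        clone = SpeciesTreeCU(self.tree.clone(depth=1))
        for i, nd in enumerate(clone._param_nodes):
            nd.edge.length = float(x[i])
        return clone

    def triple_tau(self, a: str, b: str, c: str) -> float:
        """Internal path length (coalescent units) governing a triple."""
        _, path = self._cherry_and_path(a, b, c)
        tau = 0.0
        for nd in path:
            if nd.edge.length is None:
                raise TreeError("species tree has an internal edge without a length")
            tau += float(nd.edge.length)
        return tau

    # -- likelihood machinery ---------------------------------------------

    def _count_vectors(self, counts: TripleTable) -> tuple[np.ndarray, np.ndarray]:
        """Align a TripleTable to this tree's triples: (n_concordant, n_discordant)."""
        extra = set(counts.species) - set(self.species)
        if extra:
            raise TreeError(
                f"counts contain species absent from the species tree: {sorted(extra)}"
            )
        n_con = np.zeros(len(self.triples))
        n_dis = np.zeros(len(self.triples))
        for ti, triple in enumerate(self.triples):
            i = counts._index.get(triple)
            if i is None:
                continue
            row = counts.counts[i]
            n_con[ti] = row[self._slots[ti]]
            n_dis[ti] = row.sum() - n_con[ti]
        return n_con, n_dis


def triple_tau(sp: SpeciesTreeCU, triple: Iterable[str]) -> float:
    a, b, c = tuple(triple)
    return sp.triple_tau(a, b, c)


def _loglik_and_grad(x: np.ndarray, A: np.ndarray, n_con: np.ndarray,
                     n_dis: np.ndarray) -> tuple[float, np.ndarray]:
    tau = A @ x
    e = np.exp(-tau)
    p_con = np.maximum(1.0 - (2.0 / 3.0) * e, PROB_FLOOR)
    p_dis = np.maximum(e / 3.0, PROB_FLOOR)
    ll = float(n_con @ np.log(p_con) + n_dis @ np.log(p_dis))
    # d ll / d tau_t
    g_tau = n_con * ((2.0 / 3.0) * e / p_con) - n_dis
    return ll, A.T @ g_tau


def pseudo_loglik(sp: SpeciesTreeCU, counts: TripleTable) -> float:
    """MSC pseudo-loglikelihood of a species tree given triple counts.

    Sum over triples of the multinomial loglikelihood of the observed
    resolution counts at the triple's tau; triples with zero total count
    contribute 0; probabilities are floored at 1e-300.
    """
    n_con, n_dis = sp._count_vectors(counts)
    ll, _ = _loglik_and_grad(sp.internal_lengths(), sp._A, n_con, n_dis)
    return ll


def _fit_x(sp: SpeciesTreeCU, counts: TripleTable,
           bounds: tuple[float, float] = (TAU_MIN, TAU_MAX)) -> tuple[np.ndarray, float]:
    """Fit internal branch lengths; returns (length vector, loglik).

    Tree-free core of :func:`fit_branch_lengths`, used directly in the
    bootstrap hot loop.
    """
    lo, hi = bounds
    n_con, n_dis = sp._count_vectors(counts)
    k = sp.n_internal_edges
    if k == 0:
        ll, _ = _loglik_and_grad(np.zeros(0), sp._A, n_con, n_dis)
        return np.zeros(0), ll

    # moment-based start: per-triple analytic tau mapped to edges by least
    # squares, clipped to the bounds
    tot = n_con + n_dis
    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = np.where(tot > 0, n_con / np.maximum(tot, 1), 2.0 / 3.0)
    p_hat = np.clip(p_hat, 0.35, 0.999)
    tau_hat = -np.log(3.0 * (1.0 - p_hat) / 2.0)
    x0, *_ = np.linalg.lstsq(sp._A, tau_hat, rcond=None)
    x0 = np.clip(x0, max(lo, 1e-3), hi)

    def neg(x):
        ll, g = _loglik_and_grad(x, sp._A, n_con, n_dis)
        return -ll, -g

    res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                   bounds=[(lo, hi)] * k,
                   options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500})
    x = np.clip(res.x, lo, hi)
    ll, _ = _loglik_and_grad(x, sp._A, n_con, n_dis)
    return x, float(ll)


def fit_branch_lengths(
    topology: SpeciesTreeCU | Tree,
    counts: TripleTable,
    bounds: tuple[float, float] = (TAU_MIN, TAU_MAX),
) -> tuple[SpeciesTreeCU, float]:
    """Maximize the pseudo-loglikelihood over internal branch lengths.

    The objective is concave in the internal lengths (each triple term is
    concave in its tau, and tau is linear in the lengths), so a single
    bounded L-BFGS-B run from a fixed start is globally optimal and the
    result is deterministic.

    Returns the species tree with fitted lengths and the maximized
    pseudo-loglikelihood.
    """
    sp = topology if isinstance(topology, SpeciesTreeCU) else SpeciesTreeCU(topology)
    x, ll = _fit_x(sp, counts, bounds)
    return sp.with_internal_lengths(x), ll
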