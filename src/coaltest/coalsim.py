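"""Censored multispecies-coalescent simulation of rooted gene trees.

One lineage enters at each sampled leaf; within every internal population of
duration tau (coalescent units) the next coalescence among k lineages is
exponential with rate k(k-1)/2 and is applied only if it falls within the
remaining duration; the root population runs until a single lineage remains.

Two outputs share one stochastic core (identical RNG draw sequence):

* :func:`simulate_gene_tree` / :func:`simulate_gene_tree_set` materialize
  rooted newick gene trees (the public contract);
* :func:`simulate_triple_table` accumulates rooted-triple counts directly
  from the merge events, skipping tree construction.  This is the
  parametric-bootstrap fast path: the triple counts are the sufficient
  statistic of the pseudo-likelihood, and at equal seeds the two paths give
  identical tables (tested).

Stream splitting: the set seed is first passed through a SplitMix64-style
mixer and gene i then uses ``random.Random(mix64(seed) ^ i)``.  Per-gene
simulation is therefore order-independent, and nearby set seeds (s, s+1, ...)
still yield statistically independent gene-tree sets — a plain ``seed ^ i``
rule would make consecutive set seeds share almost all of their per-gene
streams.
"""

from __future__ import annotations

import itertools
import math
import random
from typing import Callable, Iterable, Sequence

import numpy as np

from .msc import GeneTreeSet, SpeciesTreeCU, TripleTable
from .trees import TreeError, parse_newick

__all__ = [
    "simulate_gene_tree",
    "simulate_gene_tree_set",
    "simulate_triple_table",
    "mix64",
]


def mix64(seed: int) -> int:
    """SplitMix64 finalizer: spreads nearby integer seeds across 64 bits."""
    z = (seed + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return z ^ (z >> 31)


class _SimIndex:
    """Flattened species tree: postorder populations ready for simulation."""

    def __init__(self, sp: SpeciesTreeCU):
        self.sp = sp
        self.species = sp.species
        post = sp._post
        nid = sp._node_id
        n = len(post)
        self.is_leaf = [nd.is_leaf() for nd in post]
        self.leaf_bit = [0] * n
        self.children = [()] * n
        self.duration = [0.0] * n
        self.base_height = [0.0] * n
        hb = [0.0] * n
        for i, nd in enumerate(post):
            if nd.is_leaf():
                self.leaf_bit[i] = sp._bit[nd.taxon.label]
                hb[i] = 0.0
            else:
                kids = tuple(nid[id(k)] for k in nd.child_nodes())
                self.children[i] = kids
                h = 0.0
                for k, knd in zip(kids, nd.child_nodes()):
                    el = knd.edge.length
                    if el is None:
                        if not knd.is_leaf():
                            raise TreeError(
                                "species tree internal edge lacks a coalescent-unit length"
                            )
                        el = 0.0
                    h = max(h, hb[k] + float(el))
                hb[i] = h
                self.base_height[i] = h
                if nd.parent_node is None:
                    self.duration[i] = math.inf
                else:
                    if nd.edge.length is None:
                        raise TreeError(
                            "species tree internal edge lacks a coalescent-unit length"
                        )
                    self.duration[i] = float(nd.edge.length)
        self.order = list(range(n))  # already postorder
        self.root = n - 1


def _run_core(index: _SimIndex, present_mask: int, rng: random.Random,
              make_leaf: Callable, merge: Callable):
    """Run the censored coalescent; returns the final lineage list.

    ``make_leaf(bit)`` creates a lineage entering at a sampled leaf;
    ``merge(l1, l2, t)`` combines two lineages at coalescent height ``t``.
    The RNG draw sequence depends only on the species tree, the present
    mask and the seed — never on the lineage representation.
    """
    store = [None] * len(index.order)
    is_leaf = index.is_leaf
    durations = index.duration
    bases = index.base_height
    children = index.children
    expovariate = rng.expovariate
    randrange = rng.randrange
    for i in index.order:
        if is_leaf[i]:
            bit = index.leaf_bit[i]
            store[i] = [make_leaf(bit)] if bit & present_mask else []
            continue
        lin = []
        for c in children[i]:
            lin.extend(store[c])
            store[c] = None
        k = len(lin)
        if k >= 2:
            t = bases[i]
            limit = t + durations[i]
            while k >= 2:
                t += expovariate(k * (k - 1) / 2.0)
                if t > limit:
                    break
                a = randrange(k)
                b = randrange(k - 1)
                if b >= a:
                    b += 1
                lin[a] = merge(lin[a], lin[b], t)
                k -= 1
                lin[b] = lin[k]
                lin.pop()
        store[i] = lin
    return store[index.root]


# ---------------------------------------------------------------------------
# Tree-materializing path
# ---------------------------------------------------------------------------

def _present_mask(sp: SpeciesTreeCU, taxa: Iterable[str]) -> int:
    mask = 0
    for t in taxa:
        bit = sp._bit.get(t)
        if bit is None:
            raise TreeError(f"taxon {t!r} is not in the species tree")
        mask |= bit
    if mask == 0:
        raise ValueError("empty taxon set")
    return mask


def _index_of(sp: SpeciesTreeCU) -> _SimIndex:
    idx = getattr(sp, "_sim_index", None)
    if idx is None:
        idx = _SimIndex(sp)
        sp._sim_index = idx
    return idx


def simulate_gene_tree(sp: SpeciesTreeCU, taxa: Iterable[str] | None = None,
                       rng: random.Random | int = 0):
    """Simulate one rooted gene tree for the given taxon subset.

    Node heights (coalescent units) are encoded as branch lengths; the
    topology is what downstream triple counting consumes.  Deterministic
    given the species tree, taxon set and RNG state/seed.
    """
    if isinstance(rng, int):
        rng = random.Random(rng)
    index = _index_of(sp)
    mask = _present_mask(sp, taxa if taxa is not None else sp.species)
    label_of = {bit: s for s, bit in sp._bit.items()}

    def make_leaf(bit):
        return (label_of[bit], 0.0)

    def merge(l1, l2, t):
        f1, h1 = l1
        f2, h2 = l2
        return (f"({f1}:{t - h1:.9g},{f2}:{t - h2:.9g})", t)

    final = _run_core(index, mask, rng, make_leaf, merge)
    frag, _ = final[0]
    tree = parse_newick(frag + ";")
    tree.is_rooted = True
    return tree


def simulate_gene_tree_set(sp: SpeciesTreeCU,
                           occupancy: Sequence[Iterable[str]] | int,
                           seed: int = 0) -> GeneTreeSet:
    """Simulate an independent rooted gene tree per occupancy entry.

    ``occupancy`` is either a list of per-gene taxon subsets or an integer n
    (n complete genes).  Gene i uses ``random.Random(mix64(seed) ^ i)``; the
    whole set is reproducible from the seed and order-independent per gene.
    """
    if isinstance(occupancy, int):
        occupancy = [sp.species] * occupancy
    occ_sets = [frozenset(o) for o in occupancy]
    for i, o in enumerate(occ_sets):
        if not o:
            raise ValueError(f"occupancy entry {i} is empty")
    mixed = mix64(seed)
    trees = [
        simulate_gene_tree(sp, occ_sets[i], random.Random(mixed ^ i))
        for i in range(len(occ_sets))
    ]
    return GeneTreeSet(trees, occ_sets)


# ---------------------------------------------------------------------------
# Direct triple-count path (bootstrap fast path)
# ---------------------------------------------------------------------------

class _TripleCounter:
    """Accumulates rooted-triple counts from merge events via bitmask lookups."""

    _MAX_CACHED_TAXA = 14  # 2^14 precomputed bit lists is still tiny

    def __init__(self, sp: SpeciesTreeCU):
        self.sp = sp
        n_sp = len(sp.species)
        self.bit_index = {1 << i: i for i in range(n_sp)}
        self.row = {t: r for r, t in enumerate(itertools.combinations(range(n_sp), 3))}
        self.counts = np.zeros((len(self.row), 3))
        if n_sp <= self._MAX_CACHED_TAXA:
            self._bits_of = [self._bits(m, self.bit_index) for m in range(1 << n_sp)]
        else:
            self._bits_of = None

    @staticmethod
    def _bits(mask: int, bit_index) -> list[int]:
        out = []
        while mask:
            b = mask & -mask
            out.append(bit_index[b])
            mask ^= b
        return out

    def _indices(self, mask: int) -> list[int]:
        if self._bits_of is not None:
            return self._bits_of[mask]
        return self._bits(mask, self.bit_index)

    def record(self, m1: int, m2: int, present: int) -> None:
        """A merge of lineages m1, m2 resolves ab|c for a in m1, b in m2 and
        every sampled taxon c outside both."""
        avail = present & ~(m1 | m2)
        if not avail:
            return
        counts = self.counts
        row = self.row
        cs = self._indices(avail)
        for a in self._indices(m1):
            for b in self._indices(m2):
                x, y = (a, b) if a < b else (b, a)
                for c in cs:
                    if c > y:
                        counts[row[(x, y, c)], 0] += 1
                    elif c < x:
                        counts[row[(c, x, y)], 2] += 1
                    else:
                        counts[row[(x, c, y)], 1] += 1


def simulate_triple_table(sp: SpeciesTreeCU,
                          occupancy: Sequence[Iterable[str]] | int,
                          seed: int = 0) -> TripleTable:
    """Triple counts of a simulated gene-tree set, without building trees.

    Uses the same stochastic core and per-gene seeding as
    :func:`simulate_gene_tree_set`: at equal arguments,
    ``triple_counts(simulate_gene_tree_set(...))`` gives the identical table.
    """
    if isinstance(occupancy, int):
        occupancy = [sp.species] * occupancy
    index = _index_of(sp)
    counter = _TripleCounter(sp)
    mask_cache: dict = {}
    masks = []
    for o in occupancy:
        key = o if isinstance(o, frozenset) else frozenset(o)
        m = mask_cache.get(key)
        if m is None:
            m = _present_mask(sp, key)
            mask_cache[key] = m
        masks.append(m)
    record = counter.record
    make_leaf = int  # leaf lineage is its bit
    mixed = mix64(seed)

    for i, present in enumerate(masks):
        rng = random.Random(mixed ^ i)

        def merge(m1, m2, t, _present=present):
            record(m1, m2, _present)
            return m1 | m2

        _run_core(index, present, rng, make_leaf, merge)

    triples = tuple(
        tuple(sp.species[j] for j in t)
        for t in sorted(counter.row, key=counter.row.get)
    )
    return TripleTable(sp.species, triples, counter.counts)
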