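"""Coalescent bootstrap likelihood ratio test between competing species trees.

Two rooted species-tree topologies are compared against a fixed set of
rooted gene trees: both get branch lengths fitted by maximum
pseudo-likelihood, the observed statistic is t* = 2(log L1 - log L0), and
its null distribution is approximated by refitting both topologies on
gene-tree sets simulated from the fitted null tree (parametric bootstrap,
occupancy pattern replicated).  p-value = (# of bootstrap t_i >= t*) / n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalsim import simulate_triple_table
from .msc import (
    GeneTreeSet,
    SpeciesTreeCU,
    TripleTable,
    _fit_x,
    fit_branch_lengths,
    triple_counts,
)
from .trees import Tree, TreeError, leaf_labels

__all__ = ["CblrtResult", "cblrt_test", "rank_trees", "sequential_lrt"]


@dataclass
class CblrtResult:
    """Outcome of one coalescent bootstrap LRT."""

    t_star: float
    L0: float
    L1: float
    t_boot: list[float]
    pvalue: float
    n_boot: int
    seed: int
    alpha: float
    reject: bool
    swapped: bool  # True if the inputs were exchanged to enforce L1 >= L0
    null_fitted: SpeciesTreeCU = field(repr=False, default=None)  # type: ignore[assignment]
    alt_fitted: SpeciesTreeCU = field(repr=False, default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        return {
            "t_star": self.t_star,
            "L0": self.L0,
            "L1": self.L1,
            "pvalue": self.pvalue,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "alpha": self.alpha,
            "reject": self.reject,
            "swapped": self.swapped,
            "t_boot": list(self.t_boot),
        }


def _as_species_tree(t) -> SpeciesTreeCU:
    return t if isinstance(t, SpeciesTreeCU) else SpeciesTreeCU(t)


def _boot_seed(seed: int, b: int) -> int:
    """Well-separated, deterministic per-replicate seed."""
    ss = np.random.SeedSequence([int(seed), int(b)])
    return int(ss.generate_state(1, np.uint64)[0])


def cblrt_test(T0: Tree | SpeciesTreeCU, T1: Tree | SpeciesTreeCU,
               genes: GeneTreeSet | TripleTable,
               n_boot: int = 100, seed: int = 0,
               alpha: float = 0.05, swap_roles: bool = True) -> CblrtResult:
    """Coalescent bootstrap LRT of the null tree T0 against T1.

    By default, if T1 fits worse than T0 the roles are swapped (recorded on
    the result) so that the alternative is the higher-likelihood tree and
    t* >= 0; this matches the ranked consecutive-pair usage, where the
    higher-ranked tree is the alternative by construction.  With
    ``swap_roles=False`` the caller's role assignment is kept even when
    L1 < L0 (t* may then be negative) — the appropriate mode when T0 is a
    pre-specified null hypothesis, e.g. in calibration experiments where a
    swap would invert the hypothesis being tested.

    ``genes`` may be a rooted gene-tree set or a precomputed
    :class:`TripleTable`.  The whole result is reproducible from ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    sp0 = _as_species_tree(T0)
    sp1 = _as_species_tree(T1)
    if set(sp0.species) != set(sp1.species):
        raise TreeError("candidate species trees have different leaf sets")

    if isinstance(genes, TripleTable):
        counts = genes
        occupancy = [sp0.species] * _approx_gene_count(genes)
    else:
        counts = triple_counts(genes, sp0.species)
        occupancy = list(genes.occupancy)

    fit0, L0 = fit_branch_lengths(sp0, counts)
    fit1, L1 = fit_branch_lengths(sp1, counts)
    swapped = swap_roles and L1 < L0
    if swapped:
        fit0, fit1 = fit1, fit0
        L0, L1 = L1, L0
    t_star = 2.0 * (L1 - L0)

    occupancy = [o if isinstance(o, frozenset) else frozenset(o) for o in occupancy]
    t_boot = []
    for b in range(n_boot):
        boot_counts = simulate_triple_table(fit0, occupancy, _boot_seed(seed, b))
        _, l0b = _fit_x(fit0, boot_counts)
        _, l1b = _fit_x(fit1, boot_counts)
        t_boot.append(2.0 * (l1b - l0b))

    pvalue = sum(1 for t in t_boot if t >= t_star) / n_boot
    return CblrtResult(
        t_star=t_star, L0=L0, L1=L1, t_boot=t_boot, pvalue=pvalue,
        n_boot=n_boot, seed=seed, alpha=alpha, reject=pvalue <= alpha,
        swapped=swapped, null_fitted=fit0, alt_fitted=fit1,
    )


def _approx_gene_count(counts: TripleTable) -> int:
    """Number of genes implied by a complete-occupancy triple table."""
    if len(counts.triples) == 0:
        raise ValueError("empty triple table")
    return int(round(counts.counts.sum(axis=1).max()))


def rank_trees(candidates, genes: GeneTreeSet | TripleTable,
               names=None) -> list[tuple[str, SpeciesTreeCU, float]]:
    """Fit branch lengths to each candidate and sort ascending by loglikelihood.

    Ties keep input order.  Returns (name, fitted tree, loglik) triples.
    """
    cands = [_as_species_tree(c) for c in candidates]
    if len(cands) < 2:
        raise ValueError("need at least 2 candidate trees")
    base = set(cands[0].species)
    for c in cands[1:]:
        if set(c.species) != base:
            raise TreeError("candidate species trees have different leaf sets")
    if names is None:
        names = [f"tree{i}" for i in range(len(cands))]
    if isinstance(genes, TripleTable):
        counts = genes
    else:
        counts = triple_counts(genes, cands[0].species)
    fitted = []
    for name, c in zip(names, cands):
        sp, ll = fit_branch_lengths(c, counts)
        fitted.append((name, sp, ll))
    return sorted(fitted, key=lambda item: item[2])  # stable: ties keep input order


def sequential_lrt(candidates, genes: GeneTreeSet,
                   n_boot: int = 100, seed: int = 0, alpha: float = 0.05,
                   names=None):
    """Rank candidates by loglikelihood, then LRT each consecutive pair.

    For each adjacent pair the lower-likelihood tree is the null.  The
    reported best tree starts at the lowest-ranked candidate and moves up
    one rank every time a test rejects its null, i.e. it is the last tree
    not rejected in favor of a higher-ranked one.

    Returns (ranked, results, best_name) where ``ranked`` is the output of
    :func:`rank_trees` and ``results`` has one CblrtResult per adjacent pair.
    """
    ranked = rank_trees(candidates, genes, names=names)
    results = []
    best = ranked[0][0]
    for k in range(len(ranked) - 1):
        lo_name, lo_tree, _ = ranked[k]
        hi_name, hi_tree, _ = ranked[k + 1]
        res = cblrt_test(lo_tree, hi_tree, genes,
                         n_boot=n_boot, seed=_boot_seed(seed, 10_000 + k),
                         alpha=alpha)
        results.append(res)
        if res.reject:
            best = hi_name
    return ranked, results, best
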