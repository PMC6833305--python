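"""Alignment summaries, congruence standardization and the long-branch filter.

Covers the per-gene QC used when comparing alignment-processing stages:
parsimony-informative site proportions, GC/base composition, a 2x2 Pearson
chi-square between stages, bootstrap-quantile standardization of tree
distances, average bootstrap support, and the terminal long-branch filter
against a pruned reference tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from scipy.stats import chi2 as chi2_dist

from .trees import (
    Tree,
    internal_supports,
    leaf_labels,
    nrfd,
    prune_to_common_leaves,
    prune_to_taxa,
    terminal_branch_lengths,
)

__all__ = [
    "Alignment",
    "AlignmentSummary",
    "Chi2Result",
    "DistanceStandardization",
    "alignment_summary",
    "informative_chi2",
    "distance_quantile",
    "standardize_distance",
    "mean_bootstrap_support",
    "long_branch_flags",
]

_NUCS = ("A", "C", "G", "T")


@dataclass
class Alignment:
    """Equal-length named nucleotide sequences (gaps '-', missing 'N'/'?')."""

    names: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.seqs):
            raise ValueError("names and sequences differ in number")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        names, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            seqs.append(str(rec.seq))
        if not names:
            raise ValueError(f"no sequences in {path}")
        return cls(names, seqs)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.seqs):
                fh.write(f">{name}\n{seq}\n")

    def _matrix(self) -> np.ndarray:
        return np.array([list(s.encode()) for s in self.seqs], dtype=np.uint8)


@dataclass
class AlignmentSummary:
    prop_informative: float
    gc_content: float
    base_freqs: dict[str, float]
    n_sites: int
    n_seqs: int
    n_informative: int


def alignment_summary(aln: Alignment) -> AlignmentSummary:
    """Proportion of parsimony-informative sites, GC content and base frequencies.

    A site is parsimony-informative iff at least two distinct nucleotide
    states each occur in at least two sequences; gaps and ambiguity codes
    are excluded from state counts.  Composition is over unambiguous
    nucleotides only.
    """
    if aln.n_sites == 0:
        raise ValueError("alignment has no sites")
    mat = aln._matrix()
    nuc_codes = np.array([ord(c) for c in _NUCS], dtype=np.uint8)
    # per-site per-nucleotide counts: (4, n_sites)
    counts = np.stack([(mat == code).sum(axis=0) for code in nuc_codes])
    informative = ((counts >= 2).sum(axis=0) >= 2)
    n_informative = int(informative.sum())

    totals = counts.sum(axis=1).astype(float)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("alignment contains no unambiguous nucleotides")
    freqs = {nuc: totals[i] / grand for i, nuc in enumerate(_NUCS)}
    gc = freqs["G"] + freqs["C"]
    return AlignmentSummary(
        prop_informative=n_informative / aln.n_sites,
        gc_content=gc,
        base_freqs=freqs,
        n_sites=aln.n_sites,
        n_seqs=aln.n_seqs,
        n_informative=n_informative,
    )


@dataclass
class Chi2Result:
    chi2: float
    pvalue: float
    significant: bool
    degenerate: bool
    alpha: float


def informative_chi2(counts_a: tuple[int, int], counts_b: tuple[int, int],
                     alpha: float = 0.05) -> Chi2Result:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Rows are the two alignment stages, columns (informative, non-informative)
    site counts.  A zero row or column margin makes the table degenerate:
    chi2 = 0, pvalue = 1.
    """
    a, b = counts_a
    c, d = counts_b
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return Chi2Result(0.0, 1.0, False, True, alpha)
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    pvalue = float(chi2_dist.sf(stat, df=1))
    return Chi2Result(float(stat), pvalue, pvalue < alpha, False, alpha)


def empirical_quantile(values: Sequence[float], q: float) -> float:
    """Smallest observed value with at least q*100% of the sample <= it."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    xs = sorted(values)
    if not xs:
        raise ValueError("empty sample")
    k = math.ceil(q * len(xs))
    return xs[max(k, 1) - 1]


def distance_quantile(ml: Tree, boots: Sequence[Tree], q: float = 0.99) -> float:
    """Empirical q-quantile of NRFD(ml, b) over bootstrap trees b.

    Each pair is pruned to its shared leaves before the distance; the
    quantile is the order-statistic (ceil rule), no interpolation.
    """
    if len(boots) == 0:
        raise ValueError("empty bootstrap tree list")
    dists = []
    for b in boots:
        p1, p2 = prune_to_common_leaves(ml, b, min_shared=4)
        dists.append(nrfd(p1, p2))
    return empirical_quantile(dists, q)


@dataclass
class DistanceStandardization:
    """A raw tree distance standardized by a bootstrap calibration quantile."""

    distance: float
    quantile: float
    value: float
    significant: bool  # value > 1: outside the bootstrap confidence region


def standardize_distance(distance: float, quantile: float) -> DistanceStandardization:
    """Standardize a distance by a calibration quantile; flag if ratio > 1.

    Convention for quantile 0: any positive distance is significant and the
    standardized value is reported as infinity.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if quantile < 0:
        raise ValueError("quantile must be >= 0")
    if quantile == 0:
        value = math.inf if distance > 0 else 0.0
        return DistanceStandardization(distance, 0.0, value, distance > 0)
    value = distance / quantile
    return DistanceStandardization(distance, quantile, value, value > 1)


def mean_bootstrap_support(tree: Tree) -> float:
    """Arithmetic mean of internal-node support values (root and leaves excluded)."""
    vals = internal_supports(tree, exclude_root=True)
    if not vals:
        raise ValueError("tree has no internal support values")
    return sum(vals) / len(vals)


def long_branch_flags(gene_tree: Tree, reference: Tree,
                      factor: float = 5.0) -> set[str]:
    """Leaves whose terminal branch is >= factor times the reference's.

    The reference is first pruned to the gene tree's leaf set (merged edge
    lengths summed).  Leaves absent from the reference are skipped with a
    warning.  A pruned-reference terminal length of 0 flags the leaf iff its
    gene-tree terminal length is positive.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    gene_leaves = leaf_labels(gene_tree)
    ref_leaves = leaf_labels(reference)
    shared = gene_leaves & ref_leaves
    skipped = sorted(gene_leaves - ref_leaves)
    if skipped:
        warnings.warn(
            f"leaves absent from reference tree, skipped: {', '.join(skipped)}",
            stacklevel=2,
        )
    if len(shared) < 4:
        raise ValueError(f"gene tree and reference share only {len(shared)} leaves")
    ref_pruned = prune_to_taxa(reference, shared)
    gene_len = terminal_branch_lengths(gene_tree)
    ref_len = terminal_branch_lengths(ref_pruned)
    flagged = set()
    for leaf in shared:
        g, r = gene_len[leaf], ref_len[leaf]
        if r == 0:
            if g > 0:
                flagged.add(leaf)
        elif g >= factor * r:
            flagged.add(leaf)
    return flagged
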