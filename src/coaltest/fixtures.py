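"""Synthetic data generators: random species trees and Jukes-Cantor alignments.

Everything here is a pure function of its seed and parameters, so the whole
package is testable offline: species trees feed the coalescent simulator,
and JC alignments feed the alignment QC statistics.
"""

from __future__ import annotations

import random

import numpy as np

from .msc import SpeciesTreeCU
from .qcstats import Alignment
from .trees import Tree, TreeError, parse_newick

__all__ = [
    "random_species_tree",
    "jc_simulate_alignment",
    "stretch_terminal_branch",
    "write_preset",
]


def random_species_tree(n_taxa: int, tau_range: tuple[float, float] = (0.5, 2.0),
                        seed: int = 0, prefix: str = "S") -> SpeciesTreeCU:
    """Random rooted binary species tree with uniform internal branch lengths.

    Built by sequential random joining of subtrees; every internal branch
    length is drawn uniformly from ``tau_range`` (coalescent units).
    Reproducible from the seed.
    """
    if n_taxa < 3:
        raise ValueError(f"need at least 3 taxa, got {n_taxa}")
    lo, hi = tau_range
    if not (0 <= lo <= hi):
        raise ValueError(f"invalid tau_range: {tau_range}")
    rng = random.Random(seed)
    fragments = [f"{prefix}{i + 1}" for i in range(n_taxa)]
    while len(fragments) > 2:
        i = rng.randrange(len(fragments))
        a = fragments.pop(i)
        j = rng.randrange(len(fragments))
        b = fragments.pop(j)
        tau = rng.uniform(lo, hi)
        fragments.append(f"({a},{b}):{tau:.9g}")
    # the root has no parent edge, so the final join carries no length
    newick = f"({fragments[0]},{fragments[1]});"
    return SpeciesTreeCU.from_newick(newick)


_JC_STATES = np.frombuffer(b"ACGT", dtype=np.uint8)


def jc_simulate_alignment(tree: Tree, n_sites: int, seed: int = 0) -> Alignment:
    """Simulate an alignment of i.i.d. sites under the Jukes-Cantor model.

    The root state is uniform over {A,C,G,T}; along an edge of length b each
    site substitutes to each of the three other states with probability
    (1/4)(1 - e^{-4b/3}).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.integers(0, 4, size=n_sites, dtype=np.int8)
    names, seqs = [], []
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        b = nd.edge.length
        if b is None:
            raise TreeError("every edge needs a branch length for JC simulation")
        parent = states[id(nd.parent_node)]
        p_change_any = 0.75 * (1.0 - np.exp(-4.0 * float(b) / 3.0))
        child = parent.copy()
        hit = rng.random(n_sites) < p_change_any
        n_hit = int(hit.sum())
        if n_hit:
            # new state uniform over the 3 non-parental states
            shift = rng.integers(1, 4, size=n_hit, dtype=np.int8)
            child[hit] = (child[hit] + shift) % 4
        states[id(nd)] = child
        if nd.is_leaf():
            names.append(nd.taxon.label)
            seqs.append(_JC_STATES[child].tobytes().decode())
    return Alignment(names, seqs)


def stretch_terminal_branch(tree: Tree, leaf: str, factor: float) -> Tree:
    """Copy of the tree with one leaf's terminal branch multiplied by ``factor``.

    Deterministic helper for exercising the long-branch filter.
    """
    work = tree.clone(depth=1)
    for nd in work.leaf_node_iter():
        if nd.taxon.label == leaf:
            if nd.edge.length is None:
                raise TreeError(f"leaf {leaf!r} has no terminal branch length")
            nd.edge.length = float(nd.edge.length) * factor
            return work
    raise TreeError(f"leaf {leaf!r} not in tree")


def write_preset(preset: str, out_dir, seed: int = 0) -> dict:
    """Write a named fixture bundle (newick + FASTA + occupancy TSV) to a directory.

    Presets: ``smoke`` (tiny 5-taxon set), ``calibration`` (500 complete
    genes on 5 taxa), ``longbranch`` (alignment pair with one stretched
    terminal branch).  Returns a manifest of written paths.
    """
    from pathlib import Path

    from .coalsim import simulate_gene_tree_set
    from .trees import write_newick, write_newick_file

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    if preset == "smoke":
        sp = random_species_tree(5, (0.5, 2.0), seed=seed)
        genes = simulate_gene_tree_set(sp, 20, seed=seed)
        (out / "species.nwk").write_text(write_newick(sp.tree) + "\n")
        write_newick_file(genes.trees, out / "genes.nwk")
        manifest = {"species": out / "species.nwk", "genes": out / "genes.nwk"}
    elif preset == "calibration":
        sp = random_species_tree(5, (1.0, 1.0), seed=seed)
        genes = simulate_gene_tree_set(sp, 500, seed=seed)
        (out / "species.nwk").write_text(write_newick(sp.tree) + "\n")
        write_newick_file(genes.trees, out / "genes.nwk")
        occ = out / "occupancy.tsv"
        with open(occ, "w") as fh:
            fh.write("gene\ttaxa\n")
            for i, o in enumerate(genes.occupancy):
                fh.write(f"{i}\t{','.join(sorted(o))}\n")
        manifest = {"species": out / "species.nwk", "genes": out / "genes.nwk",
                    "occupancy": occ}
    elif preset == "longbranch":
        base = parse_newick("((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05);")
        stretched = stretch_terminal_branch(base, "A", 10.0)
        aln = jc_simulate_alignment(stretched, 500, seed=seed)
        aln.to_fasta(out / "gene.fasta")
        (out / "reference.nwk").write_text(write_newick(base) + "\n")
        (out / "gene.nwk").write_text(write_newick(stretched) + "\n")
        manifest = {"alignment": out / "gene.fasta",
                    "reference": out / "reference.nwk",
                    "gene": out / "gene.nwk"}
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return {k: str(v) for k, v in manifest.items()}
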