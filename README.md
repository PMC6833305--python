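# coaltest

Compare competing species trees against a set of rooted gene trees under the
multispecies coalescent (MSC), and compute the surrounding gene-tree /
alignment congruence statistics:

* **MSC pseudo-likelihood** of a species tree from rooted-triple counts,
  with branch-length optimization (coalescent units) on a fixed topology.
* **Coalescent bootstrap likelihood ratio test (cbLRT)**: `t* = 2(log L1 −
  log L0)` between two candidate species trees, with a parametric-bootstrap
  null simulated from the fitted null tree, plus sequential testing of
  likelihood-ranked candidates.
* **Gene-tree simulation** under the censored multispecies coalescent
  (per-gene taxon occupancy replicated).
* **Robinson–Foulds / normalized RF distances** with pruning to shared taxa,
  and standardization of tree distances by the 99% quantile of ML-vs-bootstrap
  distances.
* **Alignment QC**: parsimony-informative site proportion, GC content and
  base frequencies, 2×2 Pearson χ² between alignment-processing stages,
  average bootstrap support, and a ≥5× terminal long-branch filter against a
  pruned reference tree.
* **Standardized divergence times**: `y* = (y − x)/d` against a reference
  posterior interval half-width, flagging `|y*| > 1`.
* **Synthetic fixtures**: random species trees and Jukes–Cantor alignments,
  so everything is testable offline.

## Library quick start

```python
from coaltest import (SpeciesTreeCU, simulate_gene_tree_set, triple_counts,
                      fit_branch_lengths, cblrt_test, sequential_lrt)

sp = SpeciesTreeCU.from_newick("((((S1,S2):1,S3):1,S4):1,S5);")
genes = simulate_gene_tree_set(sp, 500, seed=42)         # 500 rooted gene trees
counts = triple_counts(genes, sp.species)
fitted, loglik = fit_branch_lengths(sp, counts)

alt = SpeciesTreeCU.from_newick("((((S1,S3):1,S2):1,S4):1,S5);")
result = cblrt_test(alt, sp, genes, n_boot=100, seed=1)  # null=alt, alternative=sp
print(result.t_star, result.pvalue, result.reject)
```

Gene trees handed to `triple_counts` / `cblrt_test` must be rooted; use
`coaltest.trees.root_by_outgroup` for unrooted ML trees.

By default `cblrt_test` swaps the two trees when the alternative fits worse,
so `t* ≥ 0` (the swap is recorded on the result). Pass `swap_roles=False`
when the null hypothesis is fixed a priori, e.g. in size/power simulation
experiments.

## CLI

`coaltest --help` lists all subcommands. The main ones:

```bash
coaltest rfdist   --t1 a.nwk --t2 b.nwk --normalized --prune-to-common
coaltest qc       --aln-dir alignments/ --out qc.tsv
coaltest stddist  --ml ml.nwk --boots boots.nwk --other other.nwk
coaltest lbfilter --genes genetrees/ --reference concat.nwk --factor 5
coaltest loglik   --species sp.nwk --genes genes.nwk
coaltest fitbl    --topology sp.nwk --genes genes.nwk --out fitted.nwk
coaltest simulate --species sp.nwk --n 500 --seed 42 --out genes.nwk
coaltest cblrt    --null t0.nwk --alt t1.nwk --genes genes.nwk --nboot 100 --seed 42
coaltest rank     --candidates concat.nwk,astral.nwk,njst.nwk --genes genes.nwk
coaltest stdtimes --reference ref.tsv --comparison cmp.tsv
coaltest fixtures --preset smoke --out fixtures/ --seed 1
```

Multi-tree files are one newick statement per line (RAxML bootstrap
convention). Tabular output is TSV with a header row.

### Divergence-time tables

`coaltest stdtimes` consumes plain TSVs: the reference has columns
`label, mean, lower, upper` (posterior mean and 95% interval per node), the
comparison has `label, mean`. To build these from two dated trees, run
`coaltest cladelabels --tree chronogram.nwk`, which keys every internal node
by its sorted-leaf-set signature (e.g. `A|B|C`) and reports its age; attach
the interval bounds from your dating program's summary using those labels.

## Reproducibility notes

* Every stochastic routine takes a seed; gene `i` of a simulated set uses
  `random.Random(mix64(seed) ^ i)` (SplitMix64-mixed), so per-gene streams
  are order-independent and nearby set seeds stay independent.
* `fit_branch_lengths` maximizes a concave objective with a deterministic
  start, so fits are bit-reproducible.
* `cblrt_test` results (including the bootstrap statistics) are fully
  reproducible from the seed.
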