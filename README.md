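# phylopart

Partitioned maximum-likelihood supermatrix phylogenomics for nucleotide
data: GTR-family substitution models with discrete-gamma rate variation,
Felsenstein-pruning likelihoods over compressed site patterns, the
codon-position sharing ladder (proportional branch-length scaling factors
through fully separate per-position parameter sets), gene-partitioned
scoring of exhaustively enumerated candidate tree sets, hierarchical
likelihood-ratio model tests, per-partition AICc/BIC, RELL and full
nonparametric bootstraps, Robinson-Foulds congruence diagnostics, and a
forward simulator for heterogeneous multigene datasets with known truth.

## Package layout

| module                  | contents |
|-------------------------|----------|
| `phylopart.models`      | JC/HKY/REV generators, spectral transition probabilities, discrete-gamma categories, average ts/tv ratio R |
| `phylopart.alignment`   | FASTA / relaxed-PHYLIP I/O, site-pattern compression with gene and codon-position labels |
| `phylopart.trees`       | Newick I/O (canonical child ordering), polytomy resolution of backbone constraint trees, normalized RF distance, uniform random topologies, RF null distributions |
| `phylopart.likelihood`  | pruning log-likelihoods (numba-accelerated), fixed-topology optimization (exact per-branch Brent sweeps + bounded L-BFGS-B parameter refinement), per-site log-likelihood vectors |
| `phylopart.search`      | NNI neighborhoods and greedy hill-climbing tree search |
| `phylopart.partitions`  | partition schemes, codon-position sharing policies, joint codon-partitioned fitting, gene-partitioned candidate-set scoring, exact free-parameter accounting, RAxML-style and tabular partition files |
| `phylopart.selection`   | LRTs, per-partition AICc/BIC, RELL bootstrap (tree and bipartition support), nonparametric bootstrap, hierarchical model choice, congruence and parameter-heterogeneity summaries |
| `phylopart.simulate`    | alignment simulation under any model (+gamma, +codon rate multipliers), heterogeneous gene sets with controlled per-gene R / alpha / GC, the default 18-taxon end-to-end fixture |
| `phylopart.pipeline`    | gene-tree and supermatrix analysis drivers |
| `phylopart.cli`         | the `phylopart` command line |

## Command line

```bash
# write a fully-synthetic 18-taxon fixture (genes, supermatrix, partition
# table, backbone with polytomies, enumerated candidate tree set, truth)
phylopart simulate --seed 1 --n-genes 8 --out run/sim

# per-gene ML trees (NNI search under REV+G), hierarchical model tests,
# per-gene R/alpha/GC, congruence summary against a random-tree null
phylopart genetrees --supermatrix run/sim/supermatrix.phy \
    --partitions run/sim/partitions.tsv --seed 2 --out run/genetrees

# exhaustive supermatrix scoring of the candidate set under a model ladder;
# comparison table with per-partition AICc/BIC and LRTs; RELL supports on
# the best tree
phylopart supermatrix --supermatrix run/sim/supermatrix.phy \
    --partitions run/sim/partitions.tsv --backbone run/sim/backbone.nwk \
    --model rev --policy shared --policy rates \
    --mode concat --mode by-gene --seed 3 --out run/supermatrix

# congruence of an arbitrary tree set; markdown report for any run dir
phylopart congruence --trees run/genetrees/gene_trees.nwk --seed 4
phylopart report --run-dir run/supermatrix
```

Every command writes a `manifest.json` recording seeds and inputs; TSV
outputs are deterministic for a fixed seed.

## Conventions

* Nucleotide order A, C, G, T; exchangeability order AC, AG, AT, CG, CT, GT
  with GT as the reference rate.
* Generators are calibrated to one expected substitution per site per unit
  time; branch lengths are expected substitutions per site.
* Discrete gamma uses equal-probability categories with conditional-mean
  rates, renormalized to mean exactly 1 (six categories by default).
* Gaps and N are treated as fully ambiguous characters.
* RF distances are normalized by 2(n-3).
* Partition coordinates in files are 1-based inclusive.
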