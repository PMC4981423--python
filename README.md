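# polynj

Deterministic gene-tree correction guided by genome evolution.

`polynj` takes a gene tree with statistical branch supports, a rooted
binary species tree, and a pairwise distance matrix over the genes. It
contracts weakly supported branches, resolves the resulting polytomies
with a dynamic program that minimizes a weighted duplication+loss
reconciliation cost against the species tree, and chooses among the
cost-optimal resolutions with a Neighbor-Joining criterion on the
distance matrix. The reconciliation machinery (duplication/speciation
annotation, per-branch loss counts, ancestral gene contents, per-branch
event tallies over many families) is exposed as a library.

Degenerate cases reduce to familiar tools: a fully supported binary
input makes it a plain reconciliation tool; a single-species star makes
it classical Neighbor-Joining; a multi-species star makes it Wagner
parsimony on gene counts.

## Layout

| module                  | role |
|-------------------------|------|
| `polynj.treeio`         | Newick + square-PHYLIP I/O, gene-to-species binding |
| `polynj.reconcile`      | LCA reconciliation, events, losses, gene content, tallies |
| `polynj.prepare`        | branch contraction, edge rootings, polytomy extraction |
| `polynj.polytomysolver` | the cost table M(s, k), count-vector backtracking, brute-force oracle |
| `polynj.njresolve`      | NJ-guided resolution of one polytomy under a count vector |
| `polynj.pipeline`       | end-to-end correction + CLI |
| `polynj.simulate`       | birth-death family simulator with recorded ground truth |
| `polynj.compare`        | bipartitions, Robinson-Foulds distance |

## Command line

```sh
polynj -s species.nw -g family.start_tree -d family.dist -o family.tree \
       -n -r best -c nj --slimit 1 --plimit 1 --firstbest --cost 1 0.99999
```

* `-s/-g/-d/-o` — species tree, gene tree, distance matrix, output.
* `-t/--seuil` — support threshold (default 0.95); branches with support
  strictly below it are contracted.
* `-r {best,all,none}` — root search over the edges of the (unrooted)
  contracted tree.
* `--slimit` / `--plimit` — caps on count vectors / retained resolutions
  per polytomy (0 = unlimited); `--firstbest` keeps one output tree.
* `--cost DUP LOSS` — event weights.
* `--map table.tsv` / `--pattern {suffix,strip-digits}` — gene-to-species
  binding (two-column table wins over the naming rule).
* `--keep-losses` — keep artificial loss stubs in the output trees.

Outputs: a multi-tree Newick file (ranked by cost), a TSV report
(`OUTPUT.report.tsv`: rank, rooting, cost, duplications, losses), and a
one-line log on stderr.

## Notes

* The cost table uses the naive O(|S| K²) recurrence; correctness is
  anchored to an exhaustive brute-force oracle over all (2n-3)!!
  resolutions in the test suite. The linear-time construction is out of
  scope.
* The simulator records *observable* ground truth (events whose evidence
  survives pruning of extinct lineages), computed with an independent
  clade-set reconciliation, so reconciling a true tree reproduces the
  recorded counts exactly.
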