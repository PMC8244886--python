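# Methods

## Model

A haplotype network is an undirected graph whose nodes are the distinct
sequence variants (haplotypes) in an aligned sample of `n` individuals and
whose edges are mutational connections. `hapnetdiv` treats the network's
*degree structure* as the carrier of topological information: haplotypes
with the same number of subtending branches (node degree, `nbHc`) form a
*haplotype class* `Hc`, characterized by its branch count `nbHc`, its
number of haplotypes `nhHc` and its number of individuals `niHc`.

With haplotype frequencies `f_h` and class frequencies `f_Hc = niHc/n`:

- `Hd = (1 − Σ f_h²) · n/(n−1)` — probability that two individuals drawn
  without replacement carry different haplotypes.
- `Bd = (1 − Σ f_Hc²) · n/(n−1)` — same construction on classes.
- `HBd = (1 − Σ f_h²)(1 − Σ f_Hc²) · n/(n−1)` — the combined complexity
  metric. The sample-size correction appears **once**: this literal form is
  what reproduces the published model-network values, whereas the plain
  product Hd·Bd would carry the correction twice (e.g. 0.37 instead of 0.35
  on the 21-individual star network). `ReportOptions.both_corrected=True`
  exposes the product for sensitivity analysis.
- `Nd = (1 − Σ nhHc·(nbHc/nH)²) · nH/(nH−1)`; `HNd = Hd·Nd`. The inner
  terms divide branch counts by the number of haplotypes, so they are not
  frequencies; Nd can exceed sensible bounds (any two-haplotype network
  scores exactly 1) and is reported as computed, never clamped. The
  combination rule for HNd is a product by symmetry with HBd; it is an
  assumption, recorded in the report settings, and the pair is included
  only so the older index can be compared against Bd/HBd.
- `π = Σ_{i<j} c_i c_j d_ij / (L · C(n,2))` — mean per-site pairwise
  difference over all individual pairs, with no `n/(n−1)` correction (the
  most common convention; π feeds no other metric here).

Because classes partition haplotypes, `Σ f_Hc² ≥ Σ f_h²`, hence `Bd ≤ Hd`
and `HBd ≤ min(Hd, Bd)` always; the suite asserts these on every fixture
and on random instances.

## Pipeline and numerical choices

1. **Collapse** (`haplotypes.collapse`). Individuals share a haplotype iff
   their sequences match under the ambiguity policy. `strict` (default)
   compares character-for-character; `ignore-ambiguous-sites` first drops
   every column where *any* record carries a gap/N/IUPAC code (complete
   deletion). Strict is the default because it is reproducible without
   cross-record coupling. Sequences are uppercased and `U → T` on read.
   Output is ordered by descending count, ties by first occurrence —
   deterministic for identical inputs.
2. **Distances** (`netbuild.hamming_distances`). A column counts 1 when
   both characters are unambiguous bases and differ; ambiguous/gap columns
   contribute 0 (pairwise deletion). Under the strict policy two *distinct*
   haplotypes can therefore sit at distance 0 (differing only at ambiguous
   sites); this is allowed with a logged warning rather than rejected,
   since refusing would make the documented policy unusable on such data.
3. **Network** (`netbuild.build_msn`). Spanning edges are a Kruskal
   minimum spanning tree with candidate edges examined in
   `(weight, min(u,v), max(u,v))` order — deterministic among equal-cost
   trees. Every non-tree pair whose distance is ≤ the largest weight on its
   tree path + `epsilon` becomes an *alternative* link (`epsilon = 0`,
   the default, admits exactly the equal-cost connections). Alternative
   links are built and counted in node degrees by default, matching how
   minimum-spanning-network displays present them; `--no-alt-links`
   disables both, since whether they should count as subtending branches is
   genuinely open. Edge weights never enter any metric — only degrees do —
   so the choice of step counts affects the network drawing, not the
   scores.
4. **Decomposition and metrics** (`metrics`). Classes are keyed by degree
   and sorted ascending. Degenerate inputs — one haplotype or one
   individual, for which no network exists — raise by default; with
   `lenient=True` they yield an all-zero report flagged `degenerate=True`.

Externally built networks (any construction method) enter through
`netbuild.read_network` as an edge-list TSV plus per-node individual
counts; the same validation (spanning edges form a tree, no self-loops or
duplicate pairs) applies, and all metrics except π are available.

## Synthetic generator

`synth.NetworkSpec` prescribes a haplotype tree plus per-haplotype
individual counts; `realize` expands it into an alignment in which each
tree edge mutates its own unique site(s) of an all-`A` background
(mutations cycle `A→C→G→T`). Pairwise haplotype distances then equal tree
path lengths exactly — additive, homoplasy-free — so the minimum spanning
tree is unique and the pipeline provably recovers the prescribed degree
sequence. The generator is deterministic given a spec; individual ids are
`h<haplotype>_<replicate>` and each individual is assigned its own
population label, as in the published model panels.

The shipped fixtures are the model conditions the metrics were introduced
on: 21-individual networks (a 5-branch star with class breakdown 1:15,
5:6; a 6-haplotype network with classes 1:15, 2:3, 4:3 and haplotype
counts {6,3,3,3,3,3}; an all-unique 21-haplotype panel) and a
48-individual maximally even two-class chain. Where a published panel does
not print its exact haplotype-count split, no fixture claims it; property
checks cover those shapes instead.

What the generator does **not** emulate: realistic mutation models,
homoplasy, recombination, reticulation beyond equal-cost ties, missing
data, or coalescent genealogies. Passing tests therefore demonstrate the
correctness of collapsing, network construction and the metric algebra —
not robustness to alignment error or to violations of tree-likeness in
real data, where different construction methods may yield different
degrees and hence different Bd.

## Known limitations

- Two published model-table entries are internally inconsistent: their
  printed combined-metric values disagree (by one unit in the second
  decimal) with the literal formula applied to their own printed class
  structure. The implementation reports full precision and the test suite
  asserts only internally consistent values, substituting structural
  property checks (pair-enumeration identity, coarsening inequalities,
  class-count/evenness/sample-size monotonicity, pipeline round-trips,
  exhaustive MST agreement) for those entries.
- Bd compares degree *classes* only; it is blind to which degrees they are
  and to branch lengths, by design.
- Problem sizes in the test suite (≤ 60 individuals for enumeration
  oracles, ≤ 7 haplotypes for exhaustive spanning-tree search, ≤ 15 for
  round-trips) were chosen so the oracles stay exact and exhaustive; the
  metrics themselves are closed-form and scale to arbitrarily large
  networks.
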