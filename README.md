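# hapnetdiv

Quantitative comparison of haplotype-network complexity for phylogeography
and population genetics.

Haplotype networks are the standard way to display relationships among the
sequence variants sampled from a population, but most studies only quantify
their genetic component — haplotype diversity — and describe topology
qualitatively. `hapnetdiv` computes a family of indices that also quantify
topology, so networks from different populations, species or markers can be
compared with single numbers:

- **Hd** — haplotype diversity (Nei): the probability that two individuals
  sampled without replacement carry different haplotypes,
  `Hd = (1 − Σ f_h²) · n/(n−1)`, where `f_h` is the frequency of haplotype
  *h* among the `n` individuals.
- **Bd** — branch diversity: haplotypes are grouped into *haplotype
  classes* by their number of subtending branches (node degree), and the
  same construction is applied to class frequencies
  `f_Hc = niHc/n`: `Bd = (1 − Σ f_Hc²) · n/(n−1)` — the probability that
  two individuals fall in different classes.
- **HBd** — haplotype network branch diversity, the combined complexity
  metric: `HBd = (1 − Σ f_h²)(1 − Σ f_Hc²) · n/(n−1)` (a single sample-size
  correction).
- **Nd / HNd** — the earlier adjusted-degree-distribution index
  `Nd = (1 − Σ nhHc·(nbHc/nH)²) · nH/(nH−1)` and its combination with Hd,
  included for comparison; unlike Bd they are not probabilities.
- **π** — nucleotide diversity (mean per-site pairwise difference), for
  reference.

The package also provides the machinery around the metrics: haplotype
collapsing from aligned FASTA, deterministic minimum-spanning-network
construction with equal-cost alternative links, ingestion of externally
built networks (the metrics are construction-method-agnostic), and a
synthetic generator that realizes any prescribed network topology as a
sequence alignment.

## Worked example

```python
from hapnetdiv import compute_report, panel_fixtures, realize

aln = realize(panel_fixtures()["fig1B"])   # 21 individuals, 6 haplotypes
report = compute_report(aln, dataset="fig1B")
print(report.n, report.nH, report.nHc)                    # 21 6 3
print(round(report.Hd, 2), round(report.Bd, 2), round(report.Nd, 2))
# 0.86 0.47 0.4
```

This network has a 4-branch hub, a 2-branch internal haplotype and four
1-branch tips; its three classes hold 15, 3 and 3 of the 21 individuals.
Two random individuals differ in haplotype with probability 0.86 and fall
in different degree classes with probability 0.47. Running
`python examples/model_networks.py` prints all shipped model networks:

```
dataset            n  nH  nHc     Hd     Bd    HBd     Nd
fig1A             21   6    2   0.86   0.43   0.35   0.20
fig1B             21   6    3   0.86   0.47   0.38   0.40
unique21_chain    21  21    2   1.00   0.18   0.17   0.86
s1B_even2class    48   4    2   0.77   0.51   0.38   0.50
```

Note how `fig1A` and `fig1B` share Hd (identical haplotype frequencies) yet
differ in Bd and HBd: topology alone separates them. The other examples
score a user-supplied edge list (`examples/custom_network.py`) and sweep
the structural properties of Bd (`examples/bd_properties.py`).

The same pipeline is available from the shell:

```bash
hapnetdiv simulate fig1B --out-prefix /tmp/fig1B
hapnetdiv compute --fasta /tmp/fig1B.fasta --format json
hapnetdiv compute --edges net.tsv --counts counts.tsv   # precomputed network
```

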