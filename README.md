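# metaweight

Weighted enzyme graphs for large-scale comparative analysis of prokaryotic
metabolism.

Pairwise comparison of metabolic networks does not scale to thousands of
sequenced genomes.  `metaweight` instead integrates many genomes into one
**super-metabolic graph** — a node for every enzyme (complete EC number),
an edge wherever two enzymes' reactions share a metabolite — and summarises
a set of genomes as **node weights** on that fixed topology.  Comparing two
deep lineages (e.g. *Archaea* vs *Eubacteria*) then reduces to comparing
weight vectors and compressing weighted graphs, which is cheap at any number
of genomes.

## Model

For a set *G* of genomes sampled from one domain, with *f(g, v) = 1* when
genome *g* contains enzyme *v*, three weight kinds are defined per enzyme:

- **taxonomic** — w_t(v) = (1/|G|) Σ_g f(g, v), the presence fraction,
  in [0, 1]; high means the enzyme is ubiquitous in the domain;
- **isoenzymatic** — the mean number of distinct protein forms of *v* per
  genome *containing* it, in [1, ∞) when present (0 when absent); high
  means enzymatic redundancy;
- **sequence-similarity** — pick one representative protein of *v* per
  containing genome, locally align all pairs (BLOSUM62, affine gaps), and
  average the identity fractions, in [0, 1]; high means sequence
  conservation.

Genomes are sampled **uniformly across evolutionary space**: species are
first clustered on 16S rRNA similarity, and each sampled dataset draws at
most one genome per cluster (k = 15 genomes per dataset, 100 replicate
datasets per domain by default), so over-sequenced clades cannot dominate.

Analyses on top of the weights:

- Spearman rank correlations within and between domains, with one-tailed
  **permutation tests** that shuffle weights over the fixed topology;
- classification of enzymes as **specific** to a domain (mean weight
  > t_high = 0.667 in one domain, < 1 − t_high in the other) or
  **ubiquitous** (> t_high in both), plus per-pathway ratios of such
  enzymes;
- greedy **node-weighted graph compression**: merge similar nodes into
  supernodes and delete edges, scoring every candidate operation by
  (distance increment)/(size decrease), where the distance to the
  decompressed graph charges removed nodes their weight and every retained
  node pair the weight-scaled change in edge weight.  Compressing both
  domains to the same ratio cr = (supernodes + superedges)/(|V| + |E|) and
  intersecting the retained enzyme sets probes the conserved metabolic core.

## Worked example

`examples/03_compress_conserved_core.py` plants a shared high-occurrence
core (a quarter of 120 enzymes at presence probability 0.95 in both
domains, the rest uniform background), estimates taxonomic weights from 30
stratified 15-genome datasets per domain, and sweeps the compression:

```
   cr  mean weight (A)  shared-part mean  distance bound
 0.80            0.486             0.490           16.07
 0.60            0.548             0.562           37.06
 0.40            0.577             0.591           67.58
 0.20            0.625             0.655           97.58
 0.10            0.656             0.685          116.46
```

Reading the table: as the compression ratio shrinks, low-weight periphery
is removed first, so the mean taxonomic weight of surviving enzymes rises
(0.49 → 0.66); the enzymes surviving in *both* domains' compressed graphs
are more ubiquitous still (0.49 → 0.69) — the signature of a conserved
core shared by the two lineages.  The distance bound is the accumulated
compression error (sum of per-operation increments).

The other examples build the three weight kinds on a small universe
(`01`), run the domain comparison and enzyme classification (`02`), and
drive the full file-based pipeline with its byte-stable manifest (`04`).
A thin CLI mirrors the pipeline stages:

```bash
metaweight simulate --seed 1 --out data/
metaweight sample --k 15 --replicates 100 --seed 1 \
    --clusters data/clusters.tsv --out datasets.tsv
metaweight run --config run.yaml --out report/
```

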