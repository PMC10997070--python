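# plastmark

Comparative plastome analysis and plastid phylogenetic-marker
screening.

Plant systematists routinely sequence complete chloroplast genomes
(plastomes, ~150 kb circular molecules with a quadripartite
LSC–IRb–SSC–IRa architecture) for a genus, then ask which *subset* of
regions carries enough signal to stand in for the whole plastome in
phylogenetic work. `plastmark` implements that workflow end to end as
a tested, reusable library:

- **Structure** — quadripartite partitioning from the longest pair of
  disjoint inverted-repeat copies, IR-junction reports (nearest gene
  and offset per junction), microsatellite (SSR) scanning with
  MISA-style unit-size thresholds (10/5/4/3/3/3 for mono- through
  hexanucleotides), and dispersed-repeat detection by exact-seed +
  Hamming extension (≥ 30 bp, ≤ 3 mismatches).
- **Diversity** — nucleotide diversity π = 2/(n(n−1)) Σ_{i<j} d_ij
  under complete deletion, sliding windows (600 bp / 200 bp step by
  default), mVISTA-style percent-identity profiles, per-region π
  ranking.
- **Codon usage** — codon counts and RSCU under the bacterial/plastid
  genetic code (table 11), start-codon summaries.
- **Phylogenetics** — JC/K2P closed-form and HKY/GTR numeric
  distances, neighbor joining, Felsenstein-pruning likelihoods with
  discrete-gamma rates, NJ + NNI hill-climbing maximum-likelihood
  search (GTR+Γ), bootstrap support, AIC model choice, mean-path-length
  ultrametricization.
- **Informativeness** — empirical-Bayes per-site substitution rates on
  a fixed ultrametric tree and Townsend-style phylogenetic
  informativeness ρ(λ, T) = 16 λ e^(−4λT) profiled per region.
- **Marker screening** — every non-empty combination of candidate
  regions (10 candidates → 1,023 subsets) gets a tree and a congruence
  score against the whole-plastome reference: classic Robinson–Foulds
  similarity and generalized-RF clustering-information similarity
  (mutual information between splits under an optimal matching).
- **Synthetic data** — a seeded generator that evolves annotated
  quadripartite plastomes along a known tree with region-specific rate
  multipliers and planted SSRs, emitting truth tables so every stage
  is testable without downloads.

## Worked example

Run the full pipeline on the default synthetic preset (20 plastome-like
genomes, ~27 kb each, quadripartite, AT-rich):

```python
from plastmark.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(out_dir="demo", seed=7))
```

The run (about half a minute) prints/stores, among other things:

```
genome: 27420 bp, GC 0.3762
segment mean pi: {'LSC': 0.0252, 'SSC': 0.0312, 'IRa': 0.0069, 'IRb': 0.0068}
codons: 5900 RSCU(ATG)= 1.0
tree lnl: -48968.8 GTR+G4 alpha 0.55
screen: best ['s01-s02', 's02-s03'] cis 1.0 of 1023 subsets
```

Reading this: each genome is 27,420 bp at 37.6% GC; windowed
nucleotide diversity is lowest inside the inverted repeats (π ≈ 0.007)
and highest in the small single-copy region (π ≈ 0.031) — the
hallmark rate contrast of real plastome panels; methionine's single
codon sits at RSCU = 1 by construction; the whole-concatenation tree
was fit under GTR+Γ (α ≈ 0.55); and of the 1,023 candidate-region
combinations screened, a two-spacer concatenation already matches the
whole-plastome tree perfectly (clustering-information similarity 1.0)
on this easy synthetic panel. Per-stage TSV/newick/JSON artifacts land
in `demo/`.

The same stages are exposed on the command line:

```sh
plastmark simulate --out sim --seed 1
plastmark structure --genbank sim/genomes --out struct
plastmark diversity --alignment whole.fasta --window 600 --step 200 --out pi.tsv
plastmark tree --alignment concat.fasta --bootstrap 100 --seed 1 --out tree.nwk
plastmark screen --regions sim/alignments --candidates cands.json \
    --reference tree.nwk --metric cis --seed 1 --out ranking.tsv
plastmark run --out full_run --seed 1
```

Real annotated plastomes are consumed as GenBank flat files
(`plastmark.io.read_genbank`); `scripts/fetch_accessions.py` documents
how to download the published 20-genome *Iris* panel from NCBI when
network access is available.

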