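# Methods

This note records the models, conventions and design decisions behind
`plastmark`, in the spirit of the methods documentation that mature
simulation and inference packages ship.

## Coordinates and formats

All internal coordinates are 0-based, half-open; the GenBank reader
converts from the 1-based inclusive convention at the boundary and
rejects features that wrap the sequence origin (rotate the record
first — silent mis-extraction is worse than a hard error). Ambiguity
codes other than N are mapped to N on input, with the replacement
count logged. Intergenic spacers are named `leftGene-rightGene` in
genome order. GenBank and FASTA parsing is delegated to Biopython,
newick parsing to dendropy; validation and coordinate bookkeeping are
added on top.

## Quadripartite partitioning

The two inverted-repeat copies are located as the longest pair of
disjoint, maximal, exact reverse-complement repeats of at least
`min_ir_len` (default 1000 bp), with the sequence treated circularly
via doubling. Seeding uses 64-mers with a stride of
`min_ir_len − 63`, which still guarantees a hit inside any qualifying
repeat. The longer single-copy arc is labelled LSC; IRb is the copy
that follows the LSC in deposited orientation, matching conventional
plastome figures. More than one distinct top-length candidate pair is
an ambiguity error listing the candidates. Junction reports give, per
junction, the nearest gene and the gap in bp; a gene containing the
junction is reported with the negative within-gene offset from its
nearer edge.

## Repeat scanners

SSRs are maximal perfect tandem tracts of primitive 1–6 bp motifs,
found by run-length analysis of the periodicity mask
`s[i] == s[i+u]`; a motif that is a power of a shorter motif is
reported at the shorter unit only, and the reported interval covers
full units. Minimum unit counts are 10/5/4/3/3/3 for unit sizes 1–6.
Two SSRs separated by at most `compound_gap` bases (default 100, the
common MISA default; not stated by the upstream protocol) are flagged
compound. The scan runs on the full genome including both IR copies,
so IR-resident SSRs are counted twice — the behaviour of submitting a
complete sequence to an SSR web service.

Dispersed repeats (forward and palindromic; reverse and complement
kinds behind a flag) are maximal ungapped pairs with length ≥ 30 and
Hamming mismatches ≤ 3, found by exact k-mer seeding with
`k = (min_len − max_mismatch) // (max_mismatch + 1)`; this k (6 at the
defaults) is the largest seed that pigeonhole-guarantees completeness
— note that ceil(min_len/(max_mismatch+1)) would not be complete for
windows at exactly the minimum length. Around each seed, all maximal
windows under the mismatch budget are enumerated via the flanking
mismatch positions; self-overlapping pairs are excluded and output is
deduplicated. The scanner is validated against a full O(n²)
per-diagonal oracle.

## Nucleotide diversity

π is the average pairwise per-site difference fraction; the deletion
policy is complete (listwise) deletion of columns with any gap or N,
matching the sliding-window convention of the standard desktop tool;
pairwise deletion is available behind a flag. Sliding windows are laid
out at alignment-column offsets 0, step, 2·step, … with full
containment only (the trailing partial window is dropped; end handling
is not documented upstream, so the simpler convention was chosen).
Percent-identity profiles are in ungapped reference coordinates; a gap
in the compared row counts as a mismatch.

## Substitution models and tree inference

Models are reversible 4-state (JC, K2P, HKY, GTR) with optional
discrete-gamma rate heterogeneity (4 equal-probability categories with
conditional-mean rates by default). Rate matrices are scaled to one
expected substitution per unit branch length. Likelihoods use
Felsenstein pruning over compressed site patterns; gaps and N are
missing data, and all-missing columns are dropped. Partials are not
rescaled, which is safe well beyond the package's intended scale
(tens of taxa at plastome-level divergence).

The ML search replaces heavy SPR machinery with a desk-scale
equivalent: a neighbor-joining start on JC distances, per-edge Brent
branch-length optimization (messages are refreshed before each 1-D
problem, so lnL is monotone by construction), model-parameter fitting
(empirical frequencies; kappa or GTR exchangeabilities and gamma shape
by bounded optimization), and first-improvement NNI sweeps in a fixed
edge enumeration until no move gains more than the tolerance. The
search is deterministic; the seed only drives bootstrap resampling
(and nothing else). Bootstrap replicates are inferred in fast mode
(NJ on JC distances) and split frequencies are mapped onto the best
tree. Model choice minimizes AIC = 2k − 2 lnL with k counting model
parameters (frequencies included; branch lengths are shared by all
candidates and cancel from the argmin).

Ultrametricization uses the mean-path-length rule — each node's age is
its mean root-to-tip distance, clamped so parents are older than
children — instead of penalized-likelihood rate smoothing. Its only
downstream consumer is PI profiling, which depends on relative node
depths, not on rate-smoothing detail.

## Site rates and phylogenetic informativeness

Per-site rates are empirical-Bayes posterior means over the fitted
discrete-gamma categories, rescaled to mean one. This estimator is
deliberately stable at desk scale, but it *shrinks* contrasts: a
planted 5× between-region rate ratio is recovered as roughly 2.5–3×
(ordering preserved) because single-column likelihoods are weak and
the prior caps the range. Region rankings — the quantity PI profiling
consumes — are unaffected, and the tests assert exactly that.

Informativeness uses the four-state per-site form
ρ(λ, T) = 16 λ e^(−4λT) (peak at λ = 1/(4T)); the constant affects
absolute scale only, so rankings, not absolute PI values, are the
supported output. The default ranking epoch is the crown age of the
ultrametric tree; net PI (regional sum) is the default ranking
statistic, with per-site PI also reported.

## Marker-combination screening

All non-empty subsets of the candidate regions (capped at 20
candidates) are screened; fast mode infers each subset's tree by
neighbor joining on JC distances assembled from cached per-region
pairwise difference counts — exact for gap-free concatenations and
sufficient for ranking — with an option to re-infer the top subsets by
full NNI ML. Two congruence scores are always reported: 1 − normalized
Robinson–Foulds distance (normalized by the total split count), and
clustering-information similarity, where each split contributes its
two-block entropy, shared information is a maximum-weight matching of
pairwise mutual information between splits (`linear_sum_assignment`),
and the score is 2·shared/(H(T1)+H(T2)). Star trees score 0 by
convention. Ties rank by fewer regions, then shorter concatenation,
then subset name.

## Synthetic data

The generator evolves each named region independently along one tree
(states sampled through exact transition-probability matrices, sites
i.i.d. given a discrete-gamma category when the model carries a shape
parameter), then assembles genomes as LSC ⧺ IRb ⧺ SSC ⧺ revcomp(IRb).
Branch lengths are in expected substitutions/site at multiplier 1 and
multipliers scale branches uniformly per region. Indels are not
simulated — alignments are the simulated matrices, since alignment is
out of scope. Two determinism-preserving touch-ups keep the planted
truth exactly recoverable: the four bases flanking the IR junctions
are adjusted so the IR pair is exactly maximal, and the bases flanking
each planted SSR tract break its periodicity.

The default "iris-like" preset is a desk-scale stand-in for a
genus-level plastome panel: 20 taxa, 29 regions over a ~27 kb genome
(instead of ~150 kb), base composition ~38% GC, overall mean pairwise
divergence 0.02, IR regions at 0.35× the base rate and SSC spacers at
~2×, which reproduces the canonical windowed-π contrast (IR ≈ 0.007,
SSC ≈ 0.031) without copying any measured profile. What passing tests
on this preset do *not* show: robustness to alignment error, indels,
gene-order rearrangements, IR expansion/contraction differences among
taxa, or rate variation that violates the per-region multiplier model.

The marker-screen preset fixes one representative 20-taxon phylogeny
(a Yule draw whose internodes mix easy and hard splits) and varies
only sequence evolution across seeds, as in a real study where the
true phylogeny is fixed. Its calibration places the screen in the
graded regime of real plastome work: three 1 kb regions at 2.5× carry
most of the signal (0.3–0.8 expected substitutions on the hardest
internodes each — individually insufficient), five at 0.15× are
nearly uninformative, and within-region rates are homogeneous because
between-region heterogeneity is the object of study and within-region
gamma heterogeneity would make the fast-mode JC distances
statistically inconsistent (more data converging to a slightly wrong
tree). In this regime no single region matches the reference tree
perfectly while high-signal combinations come close, so the ranking
discriminates combinations rather than collapsing into ties.

## Pipeline

Stages run in order: data (simulate or load) → structure → diversity →
codon usage → whole-concatenation tree → ultrametricization →
site-rates/PI → candidate selection → combination screen → report.
One global seed derives per-stage seeds by stage-name hashing, so
stages are individually reproducible; the tree stage (the dominant
cost) caches its artifacts and is reloaded when the config fingerprint
is unchanged. The default tree mode is fast (NJ topology with fitted
GTR+Γ branch lengths and shape); full NNI search is a config switch.
Real mode consumes a directory of GenBank records plus per-region
alignment FASTAs; duplicate gene names (IR-duplicated genes) are
deduplicated before codon counting, consistent with per-species codon
totals that count unique genes once.

## Known limitations

- No partitioned models; concatenations are fit under a single model.
- NNI-only topology search can miss optima that SPR would find on
  larger or noisier data sets; at the package's scale the search
  reliably reaches trees at least as good as the true topology.
- The clustering-information similarity uses optimal split matching;
  for very large trees the O(n³) assignment would dominate, but at
  ≤ 20 candidates and ≤ ~50 taxa it is negligible.
- Real-data checks against the published accession panel require a
  network fetch (`scripts/fetch_accessions.py`) and are not runnable
  offline.
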