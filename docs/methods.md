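# Methods

## Problem and model

The package classifies rare single-nucleotide missense variants as
disease-related (positive) or neutral (negative). The model is a
500-tree random forest over a fixed-order feature matrix of
8 conservation features, 17 population allele frequencies and a
k-dimensional PPI-network embedding per variant (8 + 17 + k columns).
The reported score is the vote fraction — the share of trees whose hard
prediction is the positive class — which makes a one-tree forest emit
{0, 1} scores and defines a deterministic tie rule: a score exactly at
the 0.5 threshold classifies as disease-related.

Key assumptions:

* variants are independent rows; no linkage or haplotype structure;
* gene-level network information is a valid variant-level feature — all
  variants of one gene share an embedding block;
* curation precedes modelling: only variants with a *known* overall
  allele frequency below the rarity threshold (default 1%) enter the
  matrix, so the AF block never contains a missing overall AF.

## Dataset curation

`filter_rare` keeps records with AF present and `< af_threshold`
(default 0.01); a record with unknown overall AF cannot be certified
rare and is removed in the same pass (a single well-defined survivor
set rather than two sequential filters). `deduplicate_by_priority`
resolves cross-database duplicates by source rank, default
clinvar > varibench > cosmic = varisnp; equal-rank duplicates with
conflicting labels are a hard error listing the offending keys, because
silently choosing either label would bias the benchmark. A raw
multi-source table may carry the same variant key under two sources
before dedup, so set-level uniqueness is enforced on
(chrom, pos, ref, alt, source); dedup output is unique on the key
alone. An optional exclusion-key list supports benchmark constructions
that must drop variants seen by other tools' training sets.

## Feature blocks

The exact identities of the 8 conservation columns and 17 AF columns
are annotation-pipeline-dependent; both are configurable named schemas
whose *counts* are fixed. Defaults: GERP++ RS, phastCons
(vertebrate/mammalian), phyloP (vertebrate/mammalian/primate), a
conserved-element score and a binary transcription-conserved-element
flag; AF overall/male/female plus afr, sas, amr, eas, nfe, fin, asj,
oth and six additional gnomAD-v2-style strata (popmax, raw, controls,
non_cancer, non_neuro, non_topmed). AF cells outside [0, 1] are
annotation errors and are masked missing with a warning.

Missing cells are imputed column-wise. Default strategy is the
per-column median (deterministic, robust to the heavy right skew of
rare-variant AFs); mean and k-nearest-neighbour (nan-Euclidean,
`impute.knn_k` default 5) are available. Observed cells are never
modified; a column with no observed value is an error rather than a
guess.

## PPI embedding

STRING-style scored edges (0–1000) are binarized at
`ppi.score_threshold` (default 700, the conventional high-confidence
cutoff); self-edges are dropped and duplicate pairs merged keeping the
maximum score. Walks are second-order: from current node v reached
from t, a neighbour x has unnormalized weight 1/p if x = t, 1 if x is
adjacent to t, 1/q otherwise. Choices where the transition law is
silent:

* **First step** (no previous node): uniform over neighbours — the
  convention of the biased-walk embedding literature.
* **Dead ends**: the walk truncates; an isolated start node yields a
  length-1 walk.
* **Sampling**: inverse-CDF on the unnormalized weights (the contract
  is the distribution, not the sampler; tests compare the sampler
  against the closed-form law by Monte Carlo and χ²).
* **Reproducibility**: each (start node, repeat) pair draws from an RNG
  derived from (seed, node rank, repeat), so corpora are byte-identical
  regardless of loop scheduling.

Defaults p = 1, q = 1, walk length 80, 10 walks per node, k = 64,
window 5, 5 epochs, 5 negative samples — the customary settings of the
walk-embedding literature; all are config keys.

The skip-gram-with-negative-sampling trainer is implemented in numpy:
fixed-window (center, context) pairs, negatives from the unigram
distribution raised to 3/4, mini-batch SGD (batch 8192) with a linearly
decaying learning rate (initial 0.5) and single-threaded deterministic
updates. Because PPI vocabularies are small, a batch contains many
repeats of the same node; per-row gradients are therefore *averaged*
within a batch, which keeps the effective step size O(lr) and the
optimisation stable where naive summed scatter-updates diverge. The
windowed-context formulation is used (training on start-node pairs
only is a narrower reading of the same construction; windowed contexts
are the standard choice). Nodes absent from the corpus, genes without
a protein mapping and proteins outside the network all fall back to
the zero vector (with a logged warning) so feature rows stay aligned
with the variant set.

## Cross-validation and metrics

Folds are a random near-equal partition, stratified by label by
default (plain random splitting is available; stratification only
prevents degenerate single-class folds on small data and does not
otherwise change the procedure). Per fold: train on the other nine
groups, score the held-out group, compute accuracy, precision, recall,
F1 and AUROC; the final report is the arithmetic mean of the ten
per-fold values. Because per-fold AUROC on ~200 records is noisy, the
pooled out-of-fold AUROC (all records, each scored by the model that
did not see it) is reported alongside; both are labelled.

AUROC is the Mann–Whitney rank statistic with tie-halving — the
probability that a random positive outscores a random negative —
equivalent to trapezoidal ROC integration; curve points are exported
separately for plotting. Zero-denominator metrics are reported as 0
with an explicit `undefined` flag. Feature importance defaults to mean
decrease in impurity (the forest's native measure), with permutation
importance as an alternative; the top-20 report includes a roll-up of
how many conservation / AF / embedding features it contains.

## Synthetic generator

The generator emulates the three signals the classifier exploits, with
defaults chosen once as a realistic rare-variant benchmark:

* **Network**: 160 genes in a 4-community stochastic block model,
  within-community edge probability 0.30, between 0.02. True edges get
  STRING scores ≥ 700 and an equal number of decoy non-edges score
  below 700, so thresholded reconstruction recovers exactly the
  planted adjacency.
* **Variants**: 2000, disease fraction 0.5. Overall AF is Beta(0.5,
  1000) for the disease class (mean ≈ 5·10⁻⁴) and Beta(1.5, 300) for
  neutral (mean ≈ 5·10⁻³) — both classes are predominantly rare, the
  disease class an order of magnitude rarer; population strata are the
  overall AF perturbed by lognormal noise (σ = 0.3), clipped to [0, 1].
* **Conservation**: each continuous feature is shifted up by 0.8
  standard deviations in the disease class; the element flag fires at
  0.2 (neutral) vs 0.52 (disease).
* **Community association**: the first ⌈4/2⌉ = 2 communities are
  disease-enriched; a disease variant's gene lies there with
  probability 0.8 vs the 0.5 base rate for neutral variants.
* **Missingness**: 5% of annotation cells (never the overall AF) are
  masked.

The null configuration equalises the AF shapes, zeroes the
conservation shift and sets the community association to the base
rate, so no block carries label information. What the generator does
*not* emulate: real genome coordinates and transcripts, LD, calling
artefacts, per-population AF correlation structure, database-specific
label noise, or scale-free PPI degree distributions. Passing tests
therefore demonstrate that the pipeline recovers the *kinds* of signal
the method assumes and stays calibrated under the null — not that it
attains any particular accuracy on real curated benchmarks.

## Verification strategy and problem sizes

* Evaluation formulas are checked exhaustively against exact rational
  arithmetic for all confusion-count vectors with total ≤ 20, against
  brute-force tallies and an O(n²) pairwise AUROC oracle on random
  data, and for internal consistency against published
  precision/recall/F1 triples (agreement within ±0.002, the rounding
  of three-decimal inputs).
* The walk sampler is validated on a fixed 6-node graph with
  p = 0.5, q = 2 (all three distance branches exercised): 10⁵ draws per
  (previous, current) state, max deviation < 0.01 per neighbour and χ²
  goodness-of-fit at α = 0.01.
* Embedding quality is checked on a 60-node 2-block SBM (p_in = 0.3,
  p_out = 0.02) across 3 seeds: mean within-block cosine similarity
  must exceed between-block by ≥ 0.1 (observed ≈ 0.5–0.6).
* End-to-end recovery uses the default 2000-variant fixture (pooled CV
  AUROC ≥ 0.9; observed ≈ 0.96). Calibration averages the pooled CV
  AUROC over 5 null-fixture seeds and requires it in [0.45, 0.55]
  (the mean over seeds is the stable statistic at this sample size,
  where a single seed's AUROC has a standard error of ~0.02);
  observed ≈ 0.49.

These sizes (60–160-node graphs, 2000 variants, 500 trees) keep the
full suite and the acceptance script to a few minutes on one CPU while
leaving each check comfortably clear of its threshold.

## Known limitations

* The skip-gram trainer is tuned for the small vocabularies of
  gene-level PPI networks (10²–10⁴ nodes); for very large graphs an
  asynchronous implementation would be faster, though the averaging
  update remains correct.
* The conservation and AF schema defaults name plausible ANNOVAR/dbNSFP
  and gnomAD v2 columns but any 8/17-column configuration is accepted;
  column identity is the caller's responsibility.
* Vote-fraction scores are not calibrated probabilities.
* The VCF adapter reads gene/label/AF from INFO keys; it does not do
  transcript-level annotation or liftover.
* Multi-gene (overlapping-gene) variants must be pre-assigned a single
  gene symbol; the package does not arbitrate overlaps.
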