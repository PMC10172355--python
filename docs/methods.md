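# Methods

## Quantization model

Neural gas is an online vector quantizer: prototypes have no lattice
topology, and every prototype moves toward each presented sample with a
strength that decays exponentially in its *distance rank*. We use the
classical formulation with exponential annealing of both the step size and
the neighbourhood range:

    eps(t)    = eps0 * (eps_f / eps0)^(t / t_max)
    lambda(t) = lam0 * (lam_f / lam0)^(t / t_max),   t_max = epochs * n_samples.

Published settings fix epochs = 1000, eps0 = 0.5 and lam0 = 4.5; the final
values are not published, so we adopt the original neural-gas practice of
eps_f = 0.005 and lam_f = 0.01 and expose both in `NGConfig`. Results are
insensitive to these at the scales used here: by the end of training
exp(−k/λ) is ≈ 0 for every non-winning unit, so the endgame is
winner-take-all refinement.

Other numerical choices, all declared rather than inferred (the original
MATLAB toolbox invocation is not recoverable):

* **Distance**: Euclidean throughout.
* **Epoch**: one seeded shuffled pass over the samples; the presentation
  counter t advances per sample.
* **Initialization**: n_units distinct samples drawn without replacement
  (keeps prototypes inside the data range and avoids dead units). With
  eps ≤ 1 and this initialization, every prototype coordinate provably stays
  within the per-feature [min, max] of the data (each update is a convex
  combination), which the tests assert.
* **Ties**: equal distances are ranked by lowest unit index (stable sort);
  the same rule breaks assignment ties.
* **Empty units** keep occupancy 0 and are reported, never re-seeded: the
  trained codebook is a fixed object.
* **Determinism**: a single `numpy.random.Generator` seeded from
  `NGConfig.seed` drives initialization and shuffling; identical
  seed + config + data give bit-identical codebooks and assignments.

The λ → 0 limit of the update is exactly online k-means, which gives an
independent correctness oracle: with λ pinned at 1e-6 the trained codebook
must match an online k-means run with the identical presentation order to
1e-6, and assignment must match brute-force nearest-centroid search.

## Preprocessing

Fixed order: organelle removal → rare-OTU filter → rarefaction → rank
aggregation.

* **Organelle removal** drops OTUs with any rank equal (case-insensitively)
  to "chloroplast" or "mitochondria".
* **Rare-OTU filter**: the conventional prevalence/abundance rule — keep an
  OTU iff its count reaches `min_count` (default 10) in at least
  `min_samples` (default 3) samples. The verbal rule "seen less than ten
  times in at least three samples" is ambiguous; this reading is the
  standard phyloseq-style filter, is monotone in both thresholds, and is
  idempotent and commutes with organelle removal (tested).
* **Rarefaction**: exact multivariate hypergeometric subsampling
  (`numpy.random.Generator.multivariate_hypergeometric`) to depth 39,680
  (default) with seed 150517 (default). Samples shallower than the depth are
  dropped with a warning; one generator is consumed over samples in sorted-ID
  order so results are platform-reproducible. Every output column sums
  exactly to the depth and no count exceeds its input.
* **Aggregation** sums counts within each taxon at the requested rank and
  divides by the sample total; unlabeled OTUs pool into
  `unclassified_<rank>`. Rows sum to 1 by construction.
* **NG input** is the community block only — covariates never enter the
  training space; they are used solely to describe units afterwards. Raw
  proportions are the default (features are commensurate); per-feature
  z-scoring is opt-in, with constant features mapped to zero and flagged.

## Unit profiles and diversity

Occupancy is members / assigned samples. Covariate summaries
(mean, SD, min, max, n) exclude missing values pairwise. SD is the sample
standard deviation (ddof = 1), reported as 0 for single-member units.
Occupancy percentages round half-even; note that printed percentages in the
source material are consistent with the 90-sample design as denominator even
where unit membership sums to 89, so `occupancy_percent` accepts an explicit
total.

Shannon H′ uses natural logarithms (the vegan convention); Pielou
J′ = H′/ln S is undefined (missing) for S ≤ 1. Per-unit evenness is the mean
of per-sample J′ values, not J′ of the mean composition — the natural
reading, and numerically consistent (to 3 decimals) with the published
bacterial per-unit averages via H̄/ln S̄. Rarefaction curves use Hurlbert's
exact expectation E[S_d] = Σᵢ (1 − C(N−Nᵢ, d)/C(N, d)), computed in log-gamma
space; it is monotone, concave, and verified against Monte-Carlo
subsampling.

## Synthetic generator

The generator emulates the study conditions, not the study data:

* **Design**: 3 stations with depth levels {ST101: 0, 35 m; CJ007: 0, 30,
  50 m; CJ009: 0, 30, 50, 75, 100 m, DCM} × 12 months; n_samples (default
  90) cells drawn from that grid. The DCM level is the label "DCM" with a
  50 m numeric stand-in.
* **Library sizes**: log-normal parameterized to arithmetic mean 134,328 and
  SD 38,181, truncated by resampling to [58,138, 291,926].
* **Community**: K = 4 planted phylum clusters (24 phyla, two archaeal).
  Centroid k = 0.55·base + 0.45·signature, where the base is a
  Proteobacteria-dominated marine composition and each cluster's signature
  puts 0.5 on each of two cluster-specific phyla — giving pairwise L1
  separation 0.9. Per sample, phylum proportions ~ Dirichlet(α·centroid)
  with total concentration α = 60 (moderate phylum-level overdispersion, a
  realistic within-condition spread); fixed log-normal weights (σ = 1) split
  each phylum over its OTUs; counts are multinomial at the library size.
  ~10% of OTUs are archaeal (Crenarchaeota, Thermoplasmatota).
* **Covariates**: Gaussian around base levels chosen from central-Adriatic
  ranges (e.g. Temp 16 °C ± 1, Sal 38.2 ± 0.15, NO₃ 1 µmol/L ± 0.2, Chl a
  0.2 µg/L ± 0.05), with cluster-specific mean shifts on Temp, Sal, NO₃,
  NH₄ and Chl a. Cluster labels are independent of station/month/depth by
  construction. DIN = NO₃+NO₂+NH₄ always.
* **CARD-FISH block**: 9 cluster centers (percent of DAPI) echoing the
  study's narrative states (a SAR11-44% state, a balanced "stand-by" state,
  Gammaproteobacteria- and Bacteroidetes-dominated states, ...); per-sample
  values are logistic-normal around the centers (logit-scale SD 0.25),
  with the SAR11 probe clipped to never exceed the Alphaproteobacteria
  probe that contains it. Several of these centers deliberately overlap
  (e.g. the three SAR11-rich states), so a 9-unit quantizer recovers them
  only partially (ARI ≈ 0.6) — the phylum-mode recovery test, with its
  enforced L1 ≥ 0.8 separation, is the calibrated benchmark.

What the generator does **not** emulate: sequencing error and chimeras,
spatial/seasonal autocorrelation of covariates, depth-dependent community
gradients, compositional coupling between the CARD-FISH and OTU blocks, or
missing covariate patterns. Passing recovery tests therefore demonstrate
algorithmic correctness under the stated separation, not expected accuracy
on field data.

## Recovery scoring

`recovery_experiment` runs simulate → preprocess (defaults, rarefaction
depth 39,680) → train → assign, then scores: adjusted Rand index between
BMU and planted labels (undefined for K = 1), and a codebook error defined
as the mean Euclidean distance between codebook rows and planted centroids
under the Hungarian (minimum-cost) matching. At the default study scale
(90 samples, α = 60) this error is ≈ 0.02 and the median ARI over seeds
is 1.0.

## Problem sizes

Tests and the acceptance script use the study-scale defaults throughout
(90 samples, 900 OTUs, 1000 epochs); the oracle-agreement checks use
100–1,000 random vectors and 10,000 Monte-Carlo replicates, and pipeline
contract tests use a 40-sample, 300-OTU configuration with 120 epochs since
they exercise plumbing, not recovery power.

## Known limitations

* The quantizer is O(epochs × samples × units × features) in pure NumPy; it
  is comfortable at study scale but not tuned for thousands of samples.
* Rarefaction discards data; it is kept because the downstream diversity
  summaries are defined on the rarefied table. Unrarefied diversity is
  available behind an explicit choice (pass the unrarefied table).
* The per-unit covariate summaries are descriptive; no association tests
  are performed.
* The pipeline makes no assumption about the sample count (the source study
  reports 90 collected and 89 analysed samples; both pass through
  unchanged).
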