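# Methods

## Scope and data model

The framework evaluates *datasets*, not generator internals: a candidate
"model" is anything that yields synthetic patient-by-feature matrices with
the real cohort's schema, whether a built-in sampler or files produced by an
external GAN. This matches the threat model of every privacy metric here —
the adversary holds synthetic data but never the generator.

A cohort is a complete rectangular matrix. Binary columns encode
presence/absence of medical concepts (diagnosis phecodes, procedure
categories, medication ingredients) and demographic indicators (binary
gender, one-hot race); continuous columns are vitals/labs min-max mapped to
[0, 1] with the original bounds retained in the schema so normalization is
invertible to within 1e-9. Missing values are rejected rather than imputed:
every metric below assumes complete matrices, and silent imputation would
contaminate both the utility distances and the attack simulations. Record
order carries no identity — a synthetic record is never linked to a real
record by position.

The real cohort is split 70:30 into training and evaluation parts with a
seeded permutation (`floor(0.7·N)` training records). The split is
unstratified by default; a stratified option exists because with rare
outcomes (~4 % positive) small evaluation sets can otherwise end up with
very few positives.

## Generation phase

Each model is run five times per synthesis paradigm and the three replicate
datasets with the lowest dimension-wise score are retained
(`n_candidates=5`, `n_keep=3`). The filter uses the marginal-fidelity score
because it is the cheapest face-value usability check; it deliberately drops
runs that failed to capture first-moment statistics before the expensive
metrics run.

Two synthesis paradigms are supported. *Combined* hands the generator all
features including the outcome. *Separated* runs the generator once per
outcome stratum at exactly the real stratum size and concatenates, so the
synthetic outcome distribution equals the real one by construction; an empty
stratum is an error since nothing can be learned from it.

## Utility metrics

- **Dimension-wise score** `1000·(Σ_binary |Δprevalence| + Σ_cont ŵ_f)/D`,
  where ŵ_f is the 1-D Wasserstein distance of feature f divided by the
  maximum of that feature's distances across all candidate datasets under
  assessment (0 when all are 0). Max-normalization rather than min-max:
  min-max would force the best candidate to 0 regardless of its actual
  distance and distort the ratios between the others. The ×1000 factor only
  keeps the averages legible. APD and AWD are also exposed separately.
- **Correlation distance** — mean absolute cell-wise difference between the
  two Pearson matrices, ×10⁶. Entries involving a constant column (e.g. a
  rare code absent from one dataset) are defined as 0 off-diagonal with the
  diagonal kept at 1, keeping the matrices comparable instead of erroring.
- **Latent deviation** — real and synthetic records are stacked (sizes must
  match), projected by PCA onto the smallest dimension count explaining
  ≥ 80 % of variance, and clustered with k-means. The statistic is
  `log(1/K Σ (nᵢᴿ/nᵢ − ½)²)` with the natural log. Perfect mixing (every
  cluster exactly half real) gives −∞, which is accepted as the best
  possible value and ranks first rather than erroring. k defaults to the
  elbow heuristic: k-means for k = 1..10 with 10 seeded restarts, choosing
  the k (2..9) that maximizes the second difference of the within-cluster
  sum of squares, smallest k on ties; k is overridable since the elbow is a
  heuristic and a user may prefer a fixed inspection granularity.
- **Knowledge violation** — from the real data, for each gender the three
  most prevalent concepts carried by that gender only; the score is the
  mean, over those codes, of the fraction of synthetic carriers whose
  gender is the impossible one (0 when a code has no synthetic carriers).
  The fraction-of-carriers reading (rather than an odds ratio) keeps the
  value in [0, 1] and matches the interpretation "over half the synthetic
  carriers of a prostate code are female".
- **Concept abundance** — per record, the count of distinct positive
  concepts; histogram over M = 20 equal-width bins spanning [0, number of
  concepts] (last bin right-closed, zero counts fall in bin 1); distance
  `Σ|h_r − h_s|/(2N)`, requiring equal record counts so the bound of 1 is
  exact.
- **TSTR / TRTS AUROC** — LightGBM gradient-boosted trees behind a
  pluggable learner interface (`deterministic=True`, single thread, seeded,
  100 trees by default), with a percentile bootstrap 95 % CI over test
  records (1000 resamples by default; resamples that lose one outcome class
  are skipped). TSTR and TRTS are separate ranking lists.
- **Feature agreement** — features ranked by mean |SHAP| attribution of the
  trained model (LightGBM's exact TreeSHAP via `pred_contrib`). M is the
  smallest k such that retraining on the real top-k features reaches ≥ 90 %
  of the full real model's evaluation AUROC, found by linear scan; if the
  full model is no better than chance, M defaults to 1. The score is
  |top-M(real) ∩ top-M(synthetic)|/M.

## Privacy metrics

- **Attribute inference** — for each real target, the k = 1 nearest
  synthetic records by Euclidean distance on the adversary's known
  attributes; unknown binary attributes predicted by majority vote (ties to
  positive), continuous by the neighbour mean. Binary attributes score F1
  with presence as the positive class (0 when no target is positive);
  continuous score the fraction of predictions within the closeness
  threshold 0.1 on the normalized scale. The final risk is the
  entropy-weighted sum over inferred attributes (Bernoulli entropy for
  binary, 20-bin discretized entropy for continuous, weights summing to 1).
  If every inferable attribute is constant the weights fall back to uniform
  so degenerate fixtures still score their raw F1.
- **Membership inference** — a target is claimed to be a training member
  when at least one synthetic record lies strictly within Euclidean
  distance 2 over all attributes; risk is the F1 with members positive.
  Targets are all training and all evaluation records, weighted equally.
- **Meaningful identity disclosure** — for each real record s: f_s real
  records and F_s population records sharing its exact quasi-identifier
  values, I_s whether a synthetic record matches them exactly (first such
  record, by index, is the matched pair), and R_s whether the adversary
  would learn something: a binary sensitive attribute qualifies when some
  synthetic record matches some real record on it and the record's value
  has real share below 0.5; a continuous attribute qualifies when
  `p_s·|X_s − Y_t| < 1.48·MAD` with p_s the real share of the record's
  cluster under univariate 3-cluster k-means and MAD floored at 1e-9 when
  zero. R_s = 1 iff at least ⌈L %·|sensitive|⌉ attributes qualify (L = 1 by
  default). The risk is the larger of the population- and sample-normalized
  sums of `(1/f_s or 1/F_s)·(1+λ_s)/2·I_s·R_s`. λ_s models adversary error
  as `(1−e₁)(1−e₂)` with e₁, e₂ drawn from triangular distributions
  (default (0, 0.1, 0.2) each); the triples are required configuration, not
  hidden constants, and a deterministic override exists for testing. With
  λ = 1, population = real data and a verbatim synthetic copy, the measure
  reduces to the classic marketer risk, bounded by 1. Exact-value QID
  matching only; generalization-hierarchy search is out of scope.
- **NNAA risk** — `AA_ES − AA_TS`, where AA between two equal-size point
  sets is ½[P(nearest-cross distance > nearest-within distance) + the
  symmetric term], self-distances excluding the point itself. Training and
  synthetic data are repeatedly subsampled to the evaluation size (5 seeded
  repeats by default) and the risk averaged. Raw values lie in [−1, 1];
  small negatives are reported as computed, not clipped, and flagged only
  through the risk categorizer, which clamps into [0, 1] before
  categorizing.

Risk categories cut [0, 1] into equal thirds: low below 1/3, median below
2/3, high otherwise.

Sensitivity presets mirror the usual attack variants (k = 10 neighbours,
membership threshold 5, L = 0.1 %) as configuration, not separate code
paths.

## Ranking

Per metric, datasets are ranked best-first with tie-averaged ranks (tied
datasets share the mean of the positions they occupy, so the rank sum is
always n(n+1)/2). A model's rank-derived score is the mean rank of its
replicates; the final score is the weighted sum over the twelve ranking
lists, lowest first, ties broken lexicographically by model id — exact
values are surfaced so a near-tie from floating-point rounding is visible
rather than silently ordered.

Weight profiles have 11 slots — seven utility, with TSTR and TRTS sharing a
single model-performance slot half-and-half, and four privacy. This is the
reading under which all three built-in use-case profiles sum to 1 while the
assessment still produces twelve ranking lists. Built-ins: *education*
(dimension-wise 0.25, correlation 0.15, knowledge violation 0.15, abundance
0.10, each privacy slot 0.05, remaining utility slots 0.05), *system
development* (dimension-wise 0.15, abundance 0.15, privacy 0.50 split
evenly, remaining slots 0.04), *medical AI* (model performance 0.5, privacy
0.3 split evenly, remaining 0.2 spread evenly over the six other utility
slots — the exact residual split is a package choice, overridable with
custom profiles), plus a uniform *default*.

## The fixture generator

`default_cohort_spec`/`generate_cohort` produce a cohort emulating the data
shape the framework targets: a few thousand patients; a few hundred sparse
binary concepts (prevalences drawn from a Beta(1.2, 18) scaled to [0, 0.6],
median around 3 %); three latent patient classes, each enriching its own
third of the concept space (×6 + 0.05, capped at 0.9) so the cohort carries
strong cross-feature correlation for the joint-structure metrics to detect;
binary gender (55 % female) with three exclusive codes per gender zeroed in
the other; a one-hot race block with a realistic skew; seven vitals from
per-class truncated normals on [0, 1]; and a logistic outcome on ten
concepts plus one vital whose intercept is calibrated by root-finding to a
4 % positive rate. Ground truth (class labels, profiles, informative
features, intercept) is returned alongside for recovery tests.

What the fixture does *not* emulate: longitudinal structure, missingness,
code hierarchies and vocabulary mapping, feature counts in the thousands,
and within-class concept dependence beyond the class mixture. Passing tests
therefore demonstrate that the metrics and ranking behave correctly on data
with known structure — not that any particular generator is safe or useful
on real EHR data.

Built-in generators: `baseline` draws every binary column independently at
the training prevalence and resamples continuous columns from their
empirical values, except the one-hot demographic block, which is resampled
jointly (a categorical draw over observed combinations) so one-hot validity
holds; `perturbation_copier(copy_fraction, flip_rate)` emits near-copies of
training rows (sampled without replacement while possible) with symmetric
Bernoulli bit flips and uniform ±flip_rate continuous jitter, filling the
remainder from the baseline sampler — a tunable overfitting gradient the
privacy metrics must flag; `exact_copy` is the worst case. Continuous
baseline sampling is empirical resampling; kernel smoothing is out of
scope.

## Determinism and problem sizes

Every stage seed derives from the global seed mixed with a CRC32 hash of a
stage label (reduced below 2³¹), so two runs of `run_benchmark` under one
seed produce byte-identical reports and no two stages share a stream. The
test suite exercises the full pipeline on cohorts of 300–600 records with
30–60 concepts and 20–50-tree learners, and the structure-recovery
simulation on 2000 records × 200 concepts — sizes chosen so the qualitative
contrasts (copier versus baseline on joint structure, marginals and
attack risk) are decisive over sampling noise while the whole suite stays
quick to run.

## Known limitations

- Exact-value QID matching makes identity disclosure conservative for
  continuous quasi-identifiers; the source attack's generalization
  hierarchies are not searched.
- The λ_s error model is a documented default, not an estimate from any
  adversary study; absolute identity-disclosure values should be read
  relative to the same configuration, not across configurations.
- Metric values are compressed to ranks before aggregation, so final scores
  are comparable only within one benchmark run.
- No statistical testing across the three replicates — the ranking is
  deliberately rank-based rather than significance-based.
- Multi-category features are supported only through one-hot encoding, and
  no neural generators are bundled; external synthetic datasets enter as
  CSV files.
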