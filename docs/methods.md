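# Methods

This note documents the models implemented in `simfish`, the parameters
that matter, the synthetic data the test suite runs on, and the design
choices made where more than one reasonable construction existed.

## Reference-library curation

Raw records carry (ligand, SMILES, target, activity type ∈ {IC50, Ki,
Kd, EC50}, value, unit ∈ {nM, μM, M}, source).  Values are harmonized to
nM and pooled per (ligand, target) pair across activity types and
sources — the concordance rule is applied to the pooled set, not per
type.  Rules, in order:

1. **Concordance** — discard the pair if max/min > 10 (the "order of
   magnitude" bound is inclusive: a 10.0× spread is still concordant).
2. **Consolidation** — the median of the concordant set is the pair's
   activity; an even-sized set takes the mean of the two central values.
3. **Potency** — keep only median < 1000 nM (strict).

Censored values ("> 10 μM") are not modeled; the input schema carries
exact values only.  Structures are standardized before identity checks:
largest organic fragment, charge neutralization where valence-legal,
canonical SMILES.  Ligand identity is identifier-level; two identifiers
with the same structure remain distinct ligands (exercised by the
structural-twin tests).  Targets whose every pair is discarded stay in
the target set, flagged unpredictable.  The library serializes to sorted
TSV tables, so serialization is a pure function of content and record
order can never leak in.

## Fingerprints and similarity

Eight 2D fingerprint kinds, all via RDKit: AtomPair, Avalon, ECFP4,
FCFP4 (circular, radius 2 = diameter 4), RDKit path, Layered, Torsion —
each folded to 1024 bits — and MACCS (166 keys; RDKit's reserved,
never-set bit 0 is dropped).  Hashed-generator parameters (path lengths
etc.) are toolkit defaults and recorded in run manifests.  Tanimoto
similarity of two all-zero vectors is defined as 0 — a featureless
fragment should not match another featureless fragment perfectly.
Library fingerprints are stacked into a boolean matrix per kind with a
content hash; query-vs-library similarity is a single vectorized pass
and is exact (no approximate indexing).

Murcko scaffolds use RDKit's Bemis–Murcko framework.  Acyclic molecules
(empty framework) are grouped under one dedicated `<acyclic>` key so the
scaffold map partitions the ligand set.  Scaffolds only drive
validation-set sampling, so implementation-level differences from other
toolkits' scaffold definitions affect which ligands are sampled, not any
score.

## Scoring and ranking

`MaxTc` is the top-1 similarity, `KNNTc(K)` the mean of the top K,
`MeanTc` the mean over all of a target's ligands; `MaxTc ≡ KNNTc(1)` and
`MeanTc ≡ KNNTc(∞)` exactly (both identities are asserted in tests).  A
K larger than a target's ligand count falls back to all available
ligands rather than discarding sparse targets.  Ranking is by descending
score with ties broken by target id ascending, giving deterministic
ordinal ranks 1..T.  Every prediction entry carries `best_similarity`
(top-1 Tc) and the nearest ligand id regardless of scheme, because
threshold filtering always acts on the nearest-neighbor similarity.

## Ensembles

Fusion operates on per-fingerprint MaxTc scores by default (the
best-performing single scheme; configurable).  For z-score fusion each
member's scores are standardized over the scored targets with the
population standard deviation — the formula (x − μ)/σ requires σ in SD
units — and a member with constant scores maps to all zeros (it carries
no ranking information).  Near-zero σ (≤ 1e-12 relative) is treated as
zero to avoid amplifying rounding residue.  Rank-sum fusion adds ordinal
ranks and sorts ascending: rank 1 everywhere is the best possible sum.
Fusion is restricted to targets scored by every member; for a held-out
query the fused entry's `best_similarity` is the strongest
nearest-ligand similarity across members.  With n fingerprint kinds
there are 2ⁿ − 1 − n subsets of size ≥ 2 (247 for eight), enumerated in
deterministic order for ensemble scans.

## Validation and metrics

Validation queries are sampled per target from its scaffold groups:
below 70 distinct scaffolds, ⌈0.30 · n_scaffolds⌉ scaffolds (minimum 1);
at 70 or more, 20 scaffolds; one ligand per sampled scaffold, all driven
by one seed.  A ligand sampled for several targets becomes a single
event carrying all its known targets.  For each event the query is
removed from every target's reference list — by identifier by default,
optionally also by identical canonical structure — and scored against
the remainder; targets left empty are unpredictable for that event and
can only contribute false negatives.

Metrics are micro-averaged: TP/FP/FN are pooled over all events before
RE_n, PR_n, and F1 are computed (single summary numbers over many events
imply pooling; macro-averaging would weight promiscuous and selective
queries equally).  An event with more known targets than n caps its
achievable RE_n below 1; the formula is kept as defined, with no
renormalization.  Stratified reports split by query promiscuity (full
metrics per group), by target reference-ligand count (cumulative ≥ c
baskets), or by target class annotation; per-target strata report
pair-level recall only, since a retained non-known prediction does not
belong to any known-pair stratum (precision is NaN there by design).

## Threshold analysis

`apply_threshold` removes entries with `best_similarity` < τ and keeps
pre-filter ranks: "top-10" always means the top-10 of the unfiltered
ranking, then filtered, so rank-cutoff and threshold are independent
axes.  The sweep grid is {0, 0.01, …, 1.00} (101 points); τ_F1 is the
smallest grid point attaining the maximum F1, reported at grid
resolution.  The bin profile uses 10 equal-width bins on [0, 1),
half-open with the last bin closed; τ_TP is the lower edge of the first
bin whose precision exceeds a configurable floor (default 0, i.e. the
first bin containing any true positive).  The improved enrichment rate
is operationalized as ER(τ) = PR_n(τ)/PR_n(0): at matched recall the
number of targets that must be picked per true positive is 1/precision,
so the fold reduction in picks is exactly the precision ratio.  ER(0) = 1
identically and ER is undefined when baseline precision is 0.

RE_n(τ) and retained-prediction counts are non-increasing in τ (asserted
across the full grid); PR_n(τ) is *not* guaranteed monotone and the
suite deliberately asserts only the documented monotonicities.

## Synthetic fixtures

The generator emulates the statistical structure the method assumes,
not real chemical space:

- each target family grows from a distinct parent ring system
  (naphthalene, benzodioxole, 1-cyclohexylpyrrolidine, benzothiophene,
  indane, … — the leading cores are mutually dissimilar chemotypes,
  pairwise ECFP4 Tc < 0.35);
- in-family scaffolds attach one family-specific ring fragment at
  different core positions (position changes the Murcko framework),
  like a congeneric series;
- ligands are acyclic decorations (halogens, alkyl, hydroxy, amino,
  nitro, methoxy, cyano, …) drawn from a family-specific 3-substituent
  slice of the alphabet, so families have their own substituent
  preferences and cross-family similarity stays low;
- a controlled fraction of ligands (default 10 %) is promiscuous,
  binding one extra target;
- replicate activities are multiplicative log-normal around a potency
  drawn near 50 nM (log₁₀ mean 1.7, SD 0.5), with replicate spread
  capped well inside the 10× rule; discordant pairs are forced by one
  30× outlier replicate and weak pairs are drawn in 3–50 μM, so every
  pair's curation outcome is known at generation time and the
  discordant/weak counts equal round(fraction · n_pairs) exactly.

Default conditions are 5 targets × 4 scaffolds × 5 ligands per scaffold
(100 ligands), replicate counts 1/2/3 with probabilities 0.5/0.3/0.2,
and 5 % each discordant and weak pairs — large enough to exercise every
curation and scoring path, small enough that the full suite runs in
seconds.  The "clean" variant used for parameter recovery switches off
promiscuity and the discard fractions, giving a genuine similarity gap
between family analogs and cross-family background; on it, held-out
analog queries recover their family target at rank 1 far above the 1/5
random baseline and τ_F1 lands inside the measured gap.

What passing these tests does **not** show: performance on real
libraries.  Real chemical space has overlapping chemotypes, activity
cliffs, heavy-tailed ligand counts per target, and far weaker
family/background separation, so absolute recalls and thresholds from
the fixtures do not transfer; fixture results validate the machinery
(curation rules, exact search, metric arithmetic, threshold logic), not
library-scale recall values, which depend entirely on the reference
data used.

## Numerical and interface choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs and seeds give
  byte-identical outputs, and run manifests record config snapshots and
  input content hashes (timestamps live only in the manifest).
- Ties anywhere (ranking, fusion, similarity sorting) break on the
  lexicographically smaller identifier.
- The acceptance script reports hold-out and leave-one-out metrics at
  the default fixture sizes above; quantities on a percentage scale are
  reported as percentages.
- Known limitations: no censored-activity handling, no approximate
  nearest-neighbor search (exact all-pairs only, fine at library sizes
  up to ~10⁵ ligands per fingerprint), no weighted or learned fusion,
  and target-class labels are taken as input annotations rather than
  derived from an ontology.
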