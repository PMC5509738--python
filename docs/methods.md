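# Methods

`jointcov` implements joint covariate detection: feature selection on
three-dimensional expression profiles (probes x patients x tissues) for a
binary patient phenotype, here written as metastasis (group 2, n2
patients) versus metastasis-free (group 1, n1 patients), with each patient
contributing a matched tumour and adjacent-normal measurement per probe.

## Model and procedure

### Two-step Fisher projection

For one probe, patient j contributes the 2-vector
x_j = (tumour_j, normal_j).  The *combined projection* is Fisher's linear
discriminant fitted on all patients:

    w = S_w^{-1} (m_1 - m_2),
    S_w = (n_1 * sum_{x in D_1} (x - m_1)(x - m_1)' +
           n_2 * sum_{x in D_2} (x - m_2)(x - m_2)') / (n_1 + n_2),

with m_g the group means.  Note the group-size weighting of the scatter
sums; it differs from the textbook unweighted form and is kept as the
method defines it.  The sign of (w, w_0) is flipped if the tumour
component of w is negative, so tumour expression always enters
non-negatively; each patient is then summarised by the scalar w'x_j.

For a probe pair, the per-patient data form a 2x2 matrix X (rows =
tissues, columns = probes).  The full matrix-variate discriminant u'Xv is
approximated by two separated linear steps: the combined projection of
each member probe, then a second Fisher discriminant — the *dimension
reduction projection* — on the pair of combined scalars.  When the two
members share combined weights, the two-step value is exactly the rank-1
bilinear form u'Xv (verified by test).  No sign convention is imposed at
the second stage; downstream statistics are sign-invariant.

### Classification rule and balanced error

The decision boundary is w'x + w_0 = 0 with w_0 = -w'(m_1 + m_2)/2, i.e.
a sample is assigned to the group whose projected mean is nearer
(midpoint rule); a sample exactly on the boundary goes to group 2.  The
nearest-mean rule is used instead of a hard-coded inequality direction
because w = S_w^{-1}(m_1 - m_2) projects group 1 high, which makes a fixed
"< 0 means group 1" convention self-contradictory.  Errors are reported
per group, Er_1 = (group-1 samples sent to group 2)/n_1 and symmetrically
Er_2, and combined as the balanced error Er = (Er_1 + Er_2)/2 so that the
dominant group cannot mask errors on the minority group (the cohorts this
method targets are strongly unbalanced, 102 vs 29 by default).

Singular within-class scatters are ridge-regularised with
eps * trace(S_w)/2 on the diagonal, eps = 1e-8, before inversion.  A fit
with exactly equal group means returns a flagged degenerate model with
w = (1, 0) and chance-level error rather than raising, so enumeration
over tens of thousands of pairs survives pathological features.

### Integrative hypothesis test (IHT)

Each feature (probe or pair) is judged by two complementary statistics on
its projected scalars:

* **Model-based**: Welch's t,
  t = (m_2 - m_1) / sqrt(s_1^2/n_1 + s_2^2/n_2), with
  Welch–Satterthwaite degrees of freedom, and a two-sided permutation
  p-value obtained by rearranging group labels (group sizes preserved)
  over the *fixed* projected values.  The add-one estimator
  p = (1 + #{|t_0| >= |t|}) / (B + 1) is used; its floor 1/(B + 1) at
  B = 10^4 reproduces the canonical floor of 10^-4.  Pairs are tested with
  a stepwise escalation: all pairs at B = 10^4, floor-p pairs re-tested at
  10^5, then 10^6 (the desk preset scales these budgets down; the schedule
  logic is identical).  Each (feature, stage) draws from its own seeded
  generator stream so results are reproducible and a feature's p at a
  given B does not depend on how it got there.
* **Boundary-based**: the mean balanced classification error over
  repeated stratified splits, floor(0.7 * n_g) patients of each group
  training and the rest testing, with one shared split stream per run so
  feature errors are comparable.  For individual probes the default
  ("faithful") mode evaluates the single combined-projection classifier
  fitted on all patients and only averages its balanced error over random
  test subsets; `refit_in_cv` instead refits the discriminant inside each
  training split for leakage-free estimates.  Pair classifiers always
  refit the second stage on the training split.

### Bootstrap voting and accumulation

Each round draws a stratified 90% subsample (round-half-up per group:
102 -> 92, 29 -> 26), refits the combined projections on the subsample,
recomputes p and mean error for every feature, and ranks features
ascending on each statistic — individuals and pairs in separate pools.
Votes per rank band: 1–3 -> 20, 4–5 -> 15, 6–10 -> 10, 11–15 -> 5,
16–20 -> 1, otherwise 0; a feature scores vote(rank_p) + vote(rank_err)
only when both ranks are <= 20, else nothing that round.  Rank ties break
on the other statistic, then on lexicographic feature id, making the
ranking a deterministic permutation that is invariant to input order.
After all rounds (canonically 100), features whose accumulated score
strictly exceeds twice the round count (200 for 100 rounds) become
candidates.  An earlier screening variant — top-10%-by-p subset, min-max
normalisation of (p, error) and ranking by Euclidean distance to the
origin — is retained as `euclidean_rank_screen` for comparison only.

Because enumerating all pairs inside every bootstrap round is
prohibitive, a broad whole-sample screen (one full-data pass over every
enumerated pair) shortlists pairs before the bootstrap rounds; only the
shortlist is re-scored per round.

### Affirmation

Candidate probes (union of selected individuals and pair members) are
characterised by their combined-projection values, z-scored per probe
(mean 0, sample sd 1; constant rows are centred and flagged).  Probes are
clustered by complete-linkage agglomeration under the centred-Pearson
distance d = 1 - r and the tree is cut into k cliques; samples are
clustered the same way on the sample axis at k = 2 and the minority
mismatch count under the best label-to-cluster matching is reported.
Candidate pairs are annotated by whether their members fall in different
cliques; cross-clique pairs are the structurally interesting ones.  k = 4
is a default reflecting the observed group structure in the motivating
data, not a rule; a different k is a one-line config change.

## Key parameters

| parameter | default (desk / canonical) | meaning |
|---|---|---|
| `k` (imputation) | 10 | neighbour rows for kNN imputation, per tissue |
| `screen_B` | 999 / 10^4 | permutations, individual screen |
| `pair_schedule` | (999, 9999) / (10^4, 10^5, 10^6) | escalation budgets for pairs |
| `screen_splits` | 500 / 10^4 | CV splits, whole-sample screens |
| `train_fraction` | 0.7 | per-group training proportion (floored) |
| `rounds` | 20 / 100 | bootstrap vote rounds |
| `fraction` | 0.9 | per-group subsample proportion per round |
| `round_B`, `round_splits` | 199, 100 / 10^4, 10^4 | per-round budgets |
| `threshold` | 2 x rounds / 200 | strict lower bound on candidate scores |
| `pair_shortlist` | 50 | pairs carried into the bootstrap rounds |
| `k_cliques` | 4 | clusters in the probe-axis affirmation cut |
| ridge eps | 1e-8 | relative diagonal ridge on singular scatters |

The desk preset changes only Monte-Carlo resolution, never procedure; the
`paper` preset restores the canonical budgets.  The default test-suite and
acceptance runs use 25–200 probes and the 102/29 cohort — sizes chosen so
a full cascade, including the ~10^4-pair broad screen, completes on one
workstation core in seconds to a couple of minutes.

## Synthetic data

The generator emulates the statistical skeleton of a two-tissue miRNA
microarray cohort: log2-scale baselines near 7, unit Gaussian noise per
tissue, the 102/29 group imbalance, optional missing cells.  Planted
structure, recorded in a ground-truth manifest:

* **Marginal probes**: a group mean shift of `effect_size` (default 2.0)
  noise-sd units in the (tumour, normal) plane along a random direction
  with non-negative tumour component.
* **Pair probes**: two probes sharing a latent noise term (sd 10 x
  noise-sd) with the metastasis group shifted +delta on one member and
  -delta on the other, delta = 0.9 * effect_size * noise-sd.  Marginally
  each member's shift is buried under the latent variance (standardised
  effect ~ 0.18), while the member difference cancels the latent term and
  exposes a joint effect of sqrt(2) * 0.9 * effect_size ~ 2.5 — larger
  than any single marginal probe, which is the premise the construction
  exists to embody.  Pair members are generated with perfectly
  tissue-correlated values (normal = tumour - constant); this pins their
  combined projection to the (1, 1) tissue direction and makes the
  pair-only geometry exact rather than approximate.  The latent and shift
  scales were fixed analytically from these two requirements (members
  quiet, pair dominant) and are deliberately idealised.
* **Clique probes**: blocks sharing a per-clique factor (within-clique
  correlation `rho`, default 0.9) identical in both tissues.

What the generator does **not** emulate: array-platform artefacts, batch
effects, probe-specific variances, heavy-tailed intensity distributions,
correlated missingness, or biological annotation structure.  Passing
tests therefore demonstrate that the machinery behaves as specified under
its own assumptions — not that the method's selections on real cohorts
are biologically correct.

## Statistical behaviour worth knowing

These are properties of the method itself, measured by the test suite and
the acceptance script on null designs:

* **Projection-level p-values are anti-conservative.**  The combined
  projection is fitted on the group labels and then held fixed while
  labels are permuted.  On a fully null 200-probe design ~14% of probes
  reach p <= 0.05 at the probe level (3x the nominal rate), purely because
  the projection was chosen to separate the groups.  The permutation test
  is exactly calibrated on exchangeable values (verified against full
  enumeration); the inflation is inherited from the supervised first
  stage.  Selection decisions in this method are relative (rank-based),
  so the inflation cancels between features, but the per-feature p values
  must not be read as calibrated significance levels.
* **The accumulation threshold is not a null-error control.**  Successive
  90% subsamples share roughly 81% of patients, so the extreme order
  statistics of a fixed null dataset keep their top ranks across rounds:
  on the null 200-probe design, ~20 features exceed the "two votes per
  round" threshold and the luckiest reaches ~740 of 800 possible points.
  The accumulated score measures the *stability* of a feature's rank
  under resampling — useful for ordering features — and any absolute
  cutoff inherits the optimism of the dataset's extremes.  Interpreting
  candidates requires an external control (validation data or a
  label-permutation run of the whole cascade), which is out of scope here.
* **The supervised projection suppresses shared correlated factors.**  A
  within-clique common factor is, from the discriminant's viewpoint,
  high-variance noise; S_w^{-1} downweights it.  Clique structure is
  therefore recovered from (z-scored) expression values; projections of
  phenotype-null clique probes largely lose it.  The affirmation stage
  still clusters projection values, faithful to the described procedure,
  which is most informative when the candidates actually carry phenotype
  signal.

## Numerical choices

* Permutation counting uses #{|t_0| >= |t| - tol} with a relative guard
  tol = 1e-9 * max(|t|, 1): permutations mathematically tied with the
  observed statistic can differ in the last floating-point bits depending
  on summation order, and exact enumeration counts such ties.
* Zero-variance degeneracies: equal means with zero variance give t = 0
  (df n1 + n2 - 2, flagged); unequal means with zero scale give a signed
  infinity flag; permutation p handles both consistently.
* Seeding: every stochastic component draws from
  `numpy.random.default_rng` seeded by structured integer lists (run
  seed, stage tag, feature index, budget), so any stage is reproducible
  in isolation and whole runs are byte-identical given the seed.
* Splits sample without replacement per group via a dedicated stream;
  degenerate training splits are skipped and counted, and a run errors if
  more than half of its splits degenerate.
* Complete-linkage clustering and maxclust tree cuts use
  scipy.cluster.hierarchy; merge-height ties resolve by scipy's
  deterministic ordering.

## Limitations

* Feature tuples beyond pairs, and the un-approximated matrix-variate
  discriminant, are not implemented.
* The faithful evaluation mode reuses the all-patient projection inside
  cross-validation (by design); leakage-free numbers require
  `refit_in_cv=True`, which is provided but not the default.
* Probe-to-miRNA annotation, target retrieval and pathway analysis are
  outside the package's scope; outputs stop at ranked candidate tables,
  cliques and cross-clique pair annotations.
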