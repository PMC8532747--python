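# Methods

This note documents the scientific and numerical choices behind
`broilerenv`: the scoring heuristic, the synthetic-data generator, the tree
miner and the evaluation stage, together with the places where the design
was genuinely open and what the test suite does and does not demonstrate.

## The scoring heuristic

The heuristic grades a broiler-house microclimate record on a four-level
ordinal scale (Excellent < Good < Moderate < Inadequate by severity). Three
ingredients are configurable YAML data, shipped with packaged defaults:

- **Environmental weight bins** (`table2_env_weights.yaml`): for each of
  dry-bulb temperature T (°C), relative humidity RH (%) and air velocity AV
  (m·s⁻¹), and each recorded age (21, 28, 35, 42 d), an ordered list of
  half-open bins `[lower, upper)` carrying a quality class and an integer
  weight 1–10. Half-open intervals match the `x ≤ V < y` notation the
  source tables use; a boundary value belongs to the upper bin.
- **Ammonia cutpoints** (`table3_ammonia.yaml`): three ascending values per
  age splitting `[0, ∞)` into the four classes. The published interval
  notation is self-contradictory; the shipped cutpoints (21/28 d: 4.2, 8.3,
  13.0; 35/42 d: 8.3, 11.8, 13.0 mg·m⁻³) are the only monotone reading of
  the published numbers and remain user-overridable.
- **Rule constants**: ARC multipliers 1 / 0.75 / 0.5 / 0.25 by ammonia
  class, ARCf cutpoints 4 / 6 / 8.

**RC aggregation.** The published formula multiplies each "standardized"
variable by its weight yet asserts the result lies on a 0–10 scale; no
standardization recoverable from the text keeps a product `T × W_T` on that
scale. We therefore read the standardized variable as the indicator of its
bin membership, collapsing RC to the mean of the three bin weights,
`RC = (W_T + W_RH + W_AV)/3 ∈ [1, 10]` — the only reading under which the
downstream ARC ∈ [0, 10] discretization is well-formed. The aggregator is a
pluggable callable (`rearing_condition(..., aggregator=)`); the mean is the
default.

**Table repairs.** The published bins contain blemishes; loading
canonicalizes them with logged, overridable repairs: gaps are closed by
extending the preceding bin's upper bound (T gains `[24, 25)` at every age
and `[17, 18)` at 28/35/42 d), overlapping bins are truncated with the
earlier bin winning (the duplicated AV `[0.5, 0.6)` row at 21 d is dropped),
and the T 28-d `[28, 39)` row labelled Excellent with weight 1 is relabelled
Inadequate via a point patch, consistent with every other age. The RH 42-d
Inadequate row keeps its printed weight 4 even though all other Inadequate
rows carry 1. `validate_weight_config` audits any config (including the raw
shipped tables via `load_weight_config(repair=False)`) for gaps and
overlaps.

**Out-of-table values** clamp into the extreme bins rather than erroring:
field sensors occasionally read outside the tabled ranges and a scoring
pipeline should not abort on them. Ages other than the four recorded days
map to the nearest recorded age, ties to the younger age, since the tables
are defined only at those ages.

The composite labeling function is deterministic and piecewise constant on
axis-aligned boxes in `(age, T, RH, AV, NH3)` space. This is the property
the tree miner exploits, and it makes 100%-training-accuracy representation
by an unbounded binary tree an exact invariant (tested; requires
`min_leaf=1`, since a minimum leaf size of 2 leaves e.g. 2-vs-1 nodes
unsplittable).

## Synthetic data generator

The generator emulates the original campaign's *shape* and *marginal
moments*, not its physics. Records form a full factorial design: 4 houses ×
3 in-house locations (air intake, center, exhaust) × 4 ages × 52 replicates
= 2,496 rows. The factorization into 52 replicates per cell is our
reconstruction — only the total is published.

Each variable is drawn independently from a normal with the published
per-age mean and SD, truncated to its physical range (RH ∈ [0, 100],
AV ≥ 0, NH₃ ≥ 0, T unbounded) by rejection resampling of out-of-bounds
rows. Consequences worth knowing:

- The nominal mean/SD parameterize the *parent* normal. For AV the lower
  bound sits only 1.25–2.5 SD below the mean, so the truncated mean is
  shifted up by as much as ≈ +0.08 m·s⁻¹ at 21 d. Moment-recovery tests
  therefore compare against the analytic truncated-normal mean
  (`scipy.stats.truncnorm` as an independent oracle); for T and NH₃ the
  truncation effect is negligible (bounds ≥ 3 SD away, < 10⁻⁴ shift).
- Variables are independent within a record; no covariances are published.
  A 4×4 correlation-matrix hook exists (Gaussian coupling before
  truncation) but defaults to identity. Real microclimate data are
  cross-correlated (T–RH, AV–NH₃) and serially correlated within a house
  and day; the generator has neither, so passing tests demonstrate
  correctness of the pipeline under the stated marginals, not performance
  on real field data.
- Under the default moments, ammonia is low (≈ 4 mg·m⁻³) relative to the
  interesting cutpoints. A packaged **stress scenario**
  (`stress_nh3.yaml`, NH₃ mean 9.0, SD 4.5 at all ages) places substantial
  mass in all four ammonia classes; it is used to exercise the
  ammonia-driven branches and the structure check that the learned tree
  roots on NH₃.

Everything is driven by one `numpy` `Generator` seeded from the config, so
identical `(config, seed)` gives bit-identical datasets.

## Tree induction

Binary numeric splits only — all five attributes are numeric (age is
treated numerically, matching threshold-style age rules). Candidate
thresholds are midpoints between consecutive distinct sorted values,
constrained so both children have at least `min_leaf` (default 2) records.
Split quality is the gain ratio in bits, with the standard C4.5 guard: only
candidates whose information gain reaches the mean gain of all
positive-gain candidates compete on gain ratio. Without the guard the ratio
favours tiny unbalanced splits and test accuracy drops about five points
below an entropy CART on the same data. Ties between equally good splits
break toward the earlier attribute in `(age_days, t_db, rh, av, nh3)` order
and then toward the smaller threshold, making fitting fully deterministic.

The random-tree variant draws a sorted random subset of
`k = ⌈√p⌉ = 3` attributes per node (configurable) from a seeded generator;
`k = p` reproduces the decision tree exactly.

Leaf prediction is the majority class; ties break toward the less severe
class — a deliberate, documented convention (an environmental alarm should
not over-report severity on a coin flip).

**Cost-complexity pruning.** The weakest-link α sequence is computed from
the training counts stored in every node (`g(t) = (R(t) − R(T_t))/(|T_t| − 1)`,
collapsing all minimal-g nodes each step), and the subtree minimizing
holdout misclassifications is selected, ties toward fewer leaves. The
α-selection protocol was an open choice; holdout selection was chosen over
training-error selection because the latter always returns the full tree on
noise-free data. In the pipeline the holdout is carved from the training
80% (default 25% of it) so the final 20% test set stays untouched.

**Minimum-support pruning.** Leaves covering under a support threshold
(default 1%) are merged: a node whose children are both leaves with either
under-supported becomes a leaf over the summed counts, repeated to a fixed
point so merges cascade upward. An under-supported leaf whose sibling is an
internal subtree is deliberately left in place — collapsing its parent
would discard the entire sibling subtree, which in measurements reduced a
~100-leaf tree to a single root leaf (47% accuracy, κ = 0).

**No missing-value handling.** Records are complete by construction; a
missing or NaN attribute at predict time raises rather than imputes.

## Evaluation

Confusion matrices are indexed `(predicted, true)` in severity order.
Accuracy generalizes the binary TP+TN form to trace/total; per-class
precision is TP over the row total and recall TP over the column total,
with empty rows/columns flagged `undefined` and reported as 0 (matching the
printed-table convention) instead of raising. Cohen's κ uses the marginal-
product chance agreement; κ = 1 exactly when the off-diagonal is empty, and
a model is accepted when κ > 0.60. Printed-style integer percentages use
round-half-up. All metrics are cross-checked against scikit-learn on random
matrices to 10⁻¹²; scikit-learn is used only as an oracle, never as the
implementation.

The packaged reference confusion matrices
(`reference_confusion_{random,decision}_tree.json`) carry per-cell
consistency flags: several printed metric values disagree with the matrices'
own counts (e.g. a printed recall of 97 where the counts give 427/432 → 99,
printed κ values of 0.72/0.81 where the counts give 0.23/0.9913). Flagged
cells are documented and excluded from equality tests; only internally
consistent cells are asserted.

**Train/test split** is stratified by the label with largest-remainder
allocation (train size within one row of the exact fraction); a stratum
with a single member falls back to an unstratified split with a warning.

## Observed performance and problem sizes

At the study scale (2,496 rows, 80/20 split) the decision tree reaches
85–91% test accuracy (κ 0.76–0.87) across seeds, and the full pipeline with
its 60/20/20 fit/prune/test split and 1% support pruning reaches 76–82%
(κ 0.63–0.71, accepted). An independent entropy-criterion CART
(scikit-learn) reaches 90–94% on the same data, so this is the intrinsic
difficulty of the task at this sample size — the label function has on the
order of a thousand distinct boxes, which 2,000 training rows cannot pin
down — not an induction defect. At ~20,000 rows the tree exceeds 95% test
accuracy robustly (tested), and training accuracy on the fitting data is
exactly 100% at unbounded depth.

Test problem sizes were chosen to keep the full suite under a minute on one
CPU: moment-recovery tests run at 10–40× replication (25k–100k rows per
cell group), representability at ~5,000 rows, the out-of-sample accuracy
check at ~20,000 rows, and the acceptance script at 100,008 records per age.

## Known limitations

- The generator's independence and normality assumptions are conveniences;
  none of the tests say anything about model performance on real,
  correlated field data.
- The RC aggregation is a reconstruction of an ambiguous published formula;
  alternative aggregators can be supplied but have no packaged defaults.
- The ammonia cutpoints at 35/42 d are a documented canonical guess at
  self-contradictory published intervals.
- Random-tree attribute-subset size is not specified in the source
  material; ⌈√p⌉ is the field-standard default.
- No ensembles, multiway splits, surrogate splits or cross-validation; the
  pipeline mirrors a single-split protocol.
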