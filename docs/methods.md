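# Methods

This note documents the statistical procedures the package implements, the
parameters that matter, the synthetic-data model, and the design choices
made where the design was genuinely open. Every number quoted here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not reproduce.

## The sequential proficiency criterion

Association experiments present two options, one rewarded, one choice per
trial. Proficiency is a sequential rule evaluated at the end of each
completed block of `block` trials (default 10), beginning once `window`
trials (default 20) exist:

- the most recent `window` trials contain ≥ `min_correct_window` correct
  choices (default 17), and
- each of the two most recent blocks contains ≥ `min_correct_per_block`
  correct choices (default 8).

`trials_to_criterion` is the smallest such evaluation point, hence always a
multiple of the block size and ≥ the window. The two-tailed exact binomial
probability of the window rule under chance responding is
2 · P(X ≥ 17 | Binomial(20, ½)) ≈ 0.00258.

Two readings were open and are resolved as follows. First, the criterion is
checked only at block boundaries, never mid-block: every trials-to-
proficiency count in the source dataset is a multiple of 10, which is only
guaranteed under block-boundary evaluation. Second, the per-block
sub-criterion ("a minimum of 8 or 9 correct out of 10 on the two most
recent sets of 10") is operationalized as ≥ 8 in *each* of the last two
blocks — the weakest reading consistent with the published counts. It
excludes 7 + 10 splits that reach 17 overall; a stricter pairing rule
(e.g. {8,9} exactly) would exclude 8 + 9 = 17 windows that the published
data appear to admit.

The refresher rule before a reversal: a bird remembers the prior
association iff its first block contains ≥ `refresher_first_block_min`
correct (default 9, i.e. 9 or 10 of 10); otherwise it repeats the original
criterion before the reversal begins. Whether the 10 probe trials count
toward a failed bird's re-learning total is not derivable from the summary
tables; the package counts re-learning from the sequence it is given.

## Learning-strategy classification

A learner on the contextual binary bandit is classified from its outcome
sequence alone:

1. **epsilon-first** — every incorrect trial lies within the first
   `exploration_budget` trials (default 4 = two samples per option; the
   optimal exploration samples each option once). The label is invariant
   to trailing correct padding by construction.
2. **epsilon-decreasing** — otherwise, if the ordinary-least-squares slope
   of the binned learning curve (proportion correct in non-overlapping
   complete bins of `bin_width` = 4 trials, trailing remainder dropped,
   regressed on 1-based bin index) is positive.
3. **unclassified** — late errors with a flat or falling curve.

Slope *significance* is deliberately not tested: a sequence that reaches
criterion in 20–130 trials yields 5–32 bins, and the original assignments
were made visually from exactly these curves; the sign is the only robust
feature at that resolution. Two anomaly flags annotate without demoting the
label, mirroring how qualitative exceptions were handled in the source
study: `late_dip` (a bin ≤ 0.5 after two consecutive bins ≥ 0.75 — a second
exploration phase) and `irregular_start` (a first-half bin drops more than
one step, 1/bin_width, below its predecessor — an early phase with no clean
probability-theory reading). The flags record these patterns; they do not
resolve them.

## Preference tests and multiple-testing correction

Water-tube experiments allow several object/tube insertions per trial.
Choice counts per option — accidental insertions included, since an object
falling into the water informs the bird regardless of intent; a flag can
exclude them — are tested against chance with an exact two-tailed binomial
test by tail doubling: p = min(1, 2·min(P(X ≤ k), P(X ≥ k))). At p₀ = ½
tail doubling coincides with the minimum-likelihood two-sided convention,
so the choice is observationally irrelevant here; it is stated for p₀ ≠ ½
extensions. p-values are Holm-adjusted within each experiment (all birds
given that experiment form the family; family composition always comes from
the input, never from a hard-coded list), with the cumulative maximum
enforced so adjusted values are monotone in the raw ordering. A preference
label names the majority option when the adjusted p < 0.05, else "none".

The packaged split table stores each count as the majority option's share.
The source table prints one experiment's counts in an inconsistent
orientation (one cell annotated with the majority option although the
column header defines counts as the minority's); because the two-tailed
test at chance is symmetric in k ↔ n − k, every p-value is independent of
orientation, and the package treats printed counts as majority splits. The
orientation of that one cell remains unresolved in the source.

## Flexibility measures and the cross-context correlation

- Color context: flexibility score = trials to reverse − trials to learn;
  missing when the reversal was not completed.
- Water-tube context: flexible ("yes") iff the preference label moved in
  the functional direction between the baseline and the switched
  experiment: formerly-functional → none, formerly-functional → newly
  functional, or none → newly functional. Anything else is "no". A
  per-bird confound annotation (in the source data, fixation on the magnet
  that disabled the heavy objects) overrides the outcome to "confounded";
  confounds are input annotations, never inferred.
- Cross-context: tie-corrected Spearman rank correlation between the
  binary water-tube coding (yes = 1, no/confounded = 0 — retaining
  confounded birds raises n from 3 to 5 and reproduces the published
  statistic, confirming that coding) and the color flexibility score.

Spearman ρ is the Pearson correlation of mid-ranks (average ranks for
ties); S is reported through S = (1 − ρ)(n³ − n)/6, which equals Σd² when
no ties are present; the two-sided p uses the t-approximation
t = ρ√((n−2)/(1−ρ²)) on n − 2 degrees of freedom — with ties there is no
exact null here, and at n = 5–7 the approximation is the standard report.

Summary means are arithmetic (initial learning over all birds with a value;
reversal over completers only) and rounded to whole trials only in reports,
as are p-values (two decimals from 0.10 upward, one significant figure
below; full precision is retained in `report.json`).

## Synthetic-data model

The generators reproduce the statistical structure the analysis assumes,
not the biology of any bird.

**Bandit agents.** Epsilon-first agents explore for `exploration_trials`
(default m = 2) trials — for m ≥ 2 the first two sample each option once in
random order — then exploit without error. Epsilon-decreasing agents
explore with probability ε_t = max(floor, (1 − r)^(t−1)): geometric decay
with a floor, chosen as the simplest one-parameter family in which
uncertainty starts complete (ε₁ = 1) and decays rapidly with experience.
Defaults: r = 0.03, floor = 0.02. The decay default balances two
requirements that pull in opposite directions: fast decay gives quick
criterion passage but frequently produces error-free tails that are, by
definition, indistinguishable from the epsilon-first pattern (the
probability of no error after trial 4 is ≈ exp(−Σ_{t>4} ε_t/2), ≈ 14% at
r = 0.15 but < 10⁻⁶ at r = 0.03). At r = 0.03, criterion passage within
200 trials occurs with probability ≈ 1, trials-to-criterion spans 20–90
(inside the observed 20–130 range), and the generating strategy is
recovered for ≈ 98% of agents. Sequences are truncated at criterion
passage, mirroring the study's stopping rule, so synthetic
trials-to-criterion distributions are comparable to observed ones. Each
agent also carries a pseudorandomized side sequence; agents are
side-agnostic (a side-bias hook is left to extensions).

**Side sequences.** The rewarded side alternates on the first two trials
and thereafter never repeats three times in a row, drawn uniformly among
admissible continuations. Both constraints are property-tested over 10,000
draws.

**Water-tube sessions.** 20 trials; 1–4 choices per trial (uniform), so
session totals fall in the 20–80 range bracketing the observed 30–67
choices; each deliberate choice is the functional option with probability
`pref_correct`; with probability 0.03 a choice is an accidental insertion
with uniform option (accidents were rare, noted events in the source
protocol); a trial succeeds when functional insertions reach
`success_threshold` = 2 (the water levels were set so 1–2 functional
insertions brought food within reach). Accidental insertions count toward
preferences and success, matching the analysis inclusion rule.

What the generators do *not* emulate: motivation loss and refusals
(truncation must be imposed by the caller), side biases, within-session
learning in water-tube choices (choices are i.i.d. given `pref_correct`,
whereas two real birds showed trial-number effects), and any coupling
between a bird's color-context and water-context behavior. Passing tests
on synthetic data therefore validate the *measurement machinery* — that
criteria, labels, tests and correlations compute what they claim on data
of the right shape — not the behavioral model of any species.

All randomness flows from one explicit integer seed per generator call
(`numpy.random.default_rng`); a fixed seed gives bit-identical output.

## Validation at a glance

The test suite checks, among others: criterion detection against a
brute-force block scan on 1,000 random sequences; the Spearman
implementation against a rank-then-Pearson oracle to 10⁻¹²; tail-doubling
binomial p's against direct coefficient summation; Holm against the
hand-worked step-down example; ≥ 95% strategy recovery on 200 simulated
agents per strategy at defaults; the per-trial accuracy of the decreasing
schedule against its closed form 1 − ε_t/2 over 10,000 agents (3 SE); and
a ≤ 10% family-wise false-positive rate for preference labeling under no
true preference (1,000 replicates, family of six). Problem sizes were
chosen so the full suite runs in about a minute on one core.

## Known limitations

- The strategy rule is a deterministic surrogate for a judgment originally
  made by eye; the `exploration_budget` and slope-sign conventions are
  configurable because other datasets may warrant stricter rules.
- The Spearman p-value is approximate; at n = 5 it should be read as
  descriptive.
- Holm families are defined by experiment membership in the input; users
  who test additional hypotheses on the same data must extend the family
  themselves.
- GLMM-based estimates (trial-level learning effects, odds ratios) are out
  of scope; `akaike_weights` accepts externally computed information
  criteria only.
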