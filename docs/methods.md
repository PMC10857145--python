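# Methods

This note documents the models, the numerical choices, and the design
decisions behind `cfrl`, in the order the pipeline runs them.

## Data model and preprocessing

Meals carry a seven-nutrient vector (calories kcal; carbohydrate, sugar,
fiber, protein, fat in g; sodium in mg) plus free-form attributes (cost,
preparation minutes, gluten flag, cuisine, ...).  Ratings are explicit
integers 1–5; duplicate (user, meal) ratings keep the one with the latest
timestamp, treating it as the user's current opinion.  The engagement
filter keeps only meals rated by at least `min_raters` (default 10)
*distinct* users — repeat ratings by one user do not count.  The
train/test split is uniform per interaction (not per user), the simplest
reading of a random 70/30 partition.

Hard dietary constraints are a named predicate registry with documented
numeric cut-offs (`low_sodium` ⇔ sodium ≤ 600 mg per meal, `low_sugar` ⇔
sugar ≤ 10 g, `low_calorie` ⇔ ≤ 500 kcal; `gluten_free` and `vegetarian`
read meal attributes).  Constraint names without published thresholds need
*some* concrete value; these are config-level choices, overridable by
editing the registry.

## Nutrition score (PV)

Each nutrient amount `x` is scored by a trapezoidal fuzzy membership
`μ(x; a,b,c,d)`: 0 outside `[a,d]`, 1 on `[b,c]`, linear on the ramps.
Trapezoids are the standard choice when only an acceptable range and soft
tolerances are known; degenerate plateaus (`b=c`) are allowed.  Default
windows approximate common adult reference intakes divided over three
meals (e.g. calories (100, 250, 700, 1000) kcal; sodium (0, 0, 600, 1500)
mg with no lower ramp — less sodium is never penalized).  Every window is
per-user overridable (`UserProfile.nutrient_targets`, or a YAML spec
file).

Memberships aggregate to the Prerow value

    PV = μ_min − (1/n) Σ_{i≠i_min} (1 − μ_i),   clipped to [0, 1],

the deficit form: the worst nutrient caps the score and every other
deficient nutrient subtracts its mean shortfall.  It satisfies the axioms
a nutrition-adequacy score needs — PV ∈ [0, 1], PV = 1 iff every
membership is 1, PV ≤ min μ, and monotone non-decreasing in every
membership (property-tested).  A multiplicative variant
`μ_min · (1/n) Σ (1/μ_i − 1)` exists in the literature's typography but
scores a perfectly adequate meal 0, contradicting the 0.7 = acceptable /
0.9 = optimal convention; it is kept behind `mode="reciprocal"` for audit
only.  Memberships are floored at 1e-6 before use (division safety in the
reciprocal mode), and ties for the minimum resolve to the first nutrient.
A per-day helper scores summed nutrients against windows scaled by the
number of meals.

## Preference score (AHP + TOPSIS)

Criterion weights come from the user's pairwise comparison matrix via the
principal eigenvector (power iteration, tolerance 1e-10), the canonical
AHP; the consistency ratio uses the standard random-index table (N ≤ 9)
and warns above 0.1 (hard error in strict mode).  The geometric-mean
shortcut was deliberately not used so that CR is exactly testable against
an independent eigendecomposition.

TOPSIS then scores each candidate meal on four criteria — nutrition (PV,
benefit), taste (CF-predicted acceptance rescaled to [0, 1], benefit),
cost (cost), convenience (preparation minutes, cost): vector-normalize
each column, weight, take per-direction ideal best/worst vectors, and
score by relative Euclidean closeness to the worst solution
`S_i = d_iw/(d_iw + d_ib)` ∈ [0, 1].  Degenerate cases are defined, never
crashes: all-zero criterion columns are dropped with re-normalized weights
(vector normalization is undefined there); if all alternatives coincide
(`d_iw + d_ib = 0`) every score is 0.5; ranking ties keep input order
(stable sort); a single-candidate set scores 1.0 by convention.  The
implementation is pinned to a brute-force step-by-step oracle at 1e-10 on
random instances.

## Collaborative filtering

"SVD" in the recommender sense: ratings are modeled as
`r̂(u,m) = μ + b_u + b_m + U_u·M_m` and fitted by epoch-wise shuffled SGD
on the observed entries with L2 regularization (classical SVD is undefined
on a mostly-missing matrix; a mean-imputed truncated-SVD variant is
available via `method="truncated"` for comparison).  Defaults: k = 16
(library) / k = 8 (evaluation harness), 30–60 epochs, lr 0.01, reg 0.05;
deterministic per seed.  Predictions clip to [1, 5]; normalized acceptance
is `(r̂−1)/4`.  Cold users/meals fall back to the available bias terms.

The online update after each fresh rating moves only the user's row,
`U_u ← U_u + η (e·M_m − reg·U_u)` with meal factors and biases frozen —
the user's taste estimate adapts within an episode while the shared meal
representation stays fixed.

## The MDP and the agent

State: the user's latent row `U_u` (nothing else by default).  An episode
is one day — breakfast, lunch, dinner in order — and at each step the
valid actions are the current slot's meals (an action mask over the fixed
candidate index).  Reward: `r = 0.3·ru + 0.4·PV + 0.3·p` with `ru` the
simulated user's actual rating normalized to [0, 1].  The transition is
the online CF update above, so high ratings visibly raise the predicted
acceptance of similar meals within the episode.

The Q-network is a 128/64/32 ReLU MLP with a linear value head, trained by
Adam on the squared temporal-difference error from uniform replay
(capacity 10 000, minibatch 32, sampling without replacement).  Plain SGD
reproduces the textbook update `w ← w + α·δ·∇Q` exactly (loss ½δ², one
sample), which the arithmetic tests rely on.  Three stabilization choices
matter and are worth stating:

* the value head is initialized near zero — a randomly initialized head
  over ~100 actions encodes a spurious, slowly-erased preference ordering;
* terminal transitions do not bootstrap (`done` flag) — episodic
  Q-learning convention;
* bootstrap maxima respect the next step's action mask, so every action's
  value receives targets of one consistent horizon (dinner values are
  terminal, lunch bootstraps on dinner, breakfast on lunch).

Without the last two, the discount-0.99 online-bootstrap loop diverges on
this problem (identical states receive terminal and non-terminal targets
interchangeably).  An optional frozen target network
(`target_sync`) is available but off by default.  ε decays per episode by
0.995 to a floor of 0.05.  Hyperparameter presets: "experiments"
(lr 2.5e-3, γ 0.99; default) and "methods" (lr 0.01, γ 0.95).  Training is
single-threaded numpy and bit-reproducible per seed.

## Synthetic world

The generator emulates the statistical shape of public recipe-rating
dumps:

* **Utilities.**  `u*(u,m) = σ((0.5·P_u·Q_m/√k + b_m + b_u)/1.2)` with
  rank-2 Gaussian taste vectors, a per-meal popularity offset (sd 1.0) and
  a per-user generosity offset (sd 0.3).  Popularity-dominant variance is
  the empirical signature of explicit-rating datasets, and it is what
  makes the utility ordering recoverable at the default sparsity (~7
  training ratings per user); a purely latent structure of the same
  magnitude would not be, at any fitting accuracy.
* **Ratings.**  `clip(round(1 + 4u* + N(0, 0.3)), 1, 5)`, observed at 10%
  density; defaults 200 users x 100 meals.
* **Nutrients.**  Per-meal-type log-normals spanning realistic magnitudes
  (breakfast median 300 kcal, dinner 550 kcal; sodium medians 300–650 mg
  with heavy tails past 1000 mg); sugar and fiber capped at carbohydrate.
* **Profiles.**  Each user gets a consistent AHP pairwise matrix built
  from a Dirichlet draw over the four criteria.  Hard constraints are off
  by default so the whole population shares one candidate catalogue (one
  action head); set `constraint_fraction` to exercise them.

What the simulator does *not* model — and what passing tests therefore do
not show about real data: temporal or seasonal rating dynamics, review
text, correlated nutrient-taste structure (tastiness is independent of
nutritional adequacy here by construction), selection bias in who rates
what, and cold-start churn.

## Evaluation harness

Four methods produce one plan per evaluation user (20 users, 10 repeated
runs, per-run seeds derived from one master seed; the CF fit is shared
across runs within a master seed):

* **cfrl** — DQN on the full composite reward;
* **cf** — argmax CF-predicted rating per slot (no nutrition signal);
* **nutrition** — the same DQN with the rating weight zeroed
  (weights renormalize to 4/7 nutrition, 3/7 preference);
* **nutrition-pref** — no learning: TOPSIS ranking with PV as an explicit
  criterion, top-ranked meal per slot.

Metrics: mean PV (0–1), mean TOPSIS preference (0–1), and mean *actual*
oracle rating (1–5) of the recommended meals.  A one-way ANOVA across
methods is reported per metric as a descriptive convenience only.  The
expected qualitative pattern, which the acceptance checks pin: the
composite agent beats rating-only CF on PV by a wide margin and beats the
rating-free agent on acceptance, while the pure preference ranker tops the
preference metric — no method dominates everything, which is the point of
the trade-off.

Problem sizes in the shipped tests and the acceptance script (200 x 100
world, 10 runs, 20–25 training environments, 300 episodes x 3 steps) were
chosen as the smallest configuration at which these orderings are stable
across master seeds.

## Known limitations

* The taste criterion feeds CF predictions into the preference score, so
  `p` is partially endogenous to the model being evaluated.
* The agent's personalization is limited by what ~7 ratings per user can
  pin down; most of its edge comes from population-level structure.
* Grid search is exhaustive with a fixed per-cell seed — adequate for the
  small grids used here, not for large spaces.
* NMF and neural CF variants, double/dueling DQN, and prioritized replay
  are out of scope.
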