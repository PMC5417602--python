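# Methods

This note documents the models and procedures implemented in `trackclass`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that affect
reproducibility.

## Trajectory features

A trajectory is the linked sequence of per-frame detections of one
particle. Fifteen features summarise it: means and sample (n−1) standard
deviations of the five morphology measurements (area µm², perimeter µm,
major and minor ellipse axes µm, aspect ratio), the circular standard
deviation of movement direction, and mean/SD/max/min of per-step gross
speed (µm s⁻¹).

Conventions:

* **Gaps.** Detections may skip frames. Steps are taken between
  consecutive *detections* and speeds divide by the actual
  inter-detection time (frame gap / fps), so a missed frame does not halve
  the apparent speed.
* **Turning angles** are wrapped differences of successive step headings,
  in (−π, π]. The circular SD is the standard directional-statistics
  estimator `sqrt(−2 ln R̄)`, `R̄` the mean resultant length; it is 0 for
  identical angles and grows without bound as directions approach
  uniformity.
* **Degenerate trajectories.** Two detections define one step: morphology
  SDs are ordinary sample SDs over ≥ 2 frames, speed SD and turning SD are
  reported missing (NaN) when fewer than two steps / turning angles exist.
  Missing features exclude a trajectory from training (the preprocessing
  drops incomplete rows) but not from counting.
* **Units.** Image convention: origin top-left, y downward, 0-based
  frames. Default spatial calibration 4.05 µm/px (81 µm ≡ 20 px), default
  25 fps; pixel-unit dialects are converted on read (areas by the squared
  scale).

## Quality filters

Test-data filter: net displacement ≥ 50 µm, duration > 0.2 s, detection
rate ≥ 0.8, median step > 2 µm, mean speed > 50 µm s⁻¹. Training data use
the same criteria with a 200 µm s⁻¹ speed floor — debris drifts slowly, so
the stricter floor buys cleaner labels at the cost of discarding slow
organisms from training (they can still be classified at test time).
Inequalities are strict or not following the wording of each criterion
("at least" ≥, "greater than" >). The filter report attributes each
removed trajectory to the first failing criterion in the order above,
making reports deterministic. Species-specific area bounds, supplied as
per-day knots and linearly interpolated, optionally screen training
trajectories; labels without bounds pass with a warning.

## Preprocessing

Box–Cox per feature (λ by maximum likelihood; non-positive features are
shifted by 1e−6 + |min| first), then zero-mean/unit-SD scaling, then PCA
retaining the smallest k whose cumulative explained variance reaches the
target (default 0.95). The power transform needs strictly positive input,
so it must precede centering even though scaling is conventionally listed
first; this ordering is fixed. Features with any missing value or zero
variance in training are dropped, not imputed. All parameters are fitted
on the training window only and frozen for test data; at transform time
shifted values are clipped to a small positive floor so a test point
slightly below the training minimum does not produce NaN. Input matrices
are forced to a canonical memory layout so refits are bit-identical.
The preprocessing is fitted per training window (per target community),
not globally — phenotypic drift means a global transform would mix
regimes.

## Noise model

Control samples contain no organisms; everything they yield is spurious.
A full-covariance Gaussian mixture (default 40 clusters, auto-reduced to
⌊n/10⌋ with a warning when data are few; k-means++ initialisation, fixed
seed, ridge-regularised covariances) is fitted to the pooled candidate
training + control observations in retained-PC space. Each observation is
hard-assigned to its maximum-responsibility cluster; a cluster is *noise*
iff its control fraction strictly exceeds 0.5 (configurable — "mostly
control" needs a number, and a strict majority is the natural reading).
Species-labeled observations in noise clusters are relabeled to the noise
class; their features never change. Afterwards a 90 % confidence ellipse
of a bivariate normal fitted to PC1/PC2 removes residual outliers per
class (inlier iff squared Mahalanobis distance ≤ χ²₂ quantile). GMM before
ellipse: the mixture explains structured noise, the ellipse trims
unstructured tails.

## Sliding window, balancing, forest

The training pool holds monoculture trajectories (training-stringency
filter, labeled with their sample's single species) and control
trajectories (test-stringency filter, labeled noise — test-time noise is
what passes the test filter, so that is what the noise class must look
like). For a target community the window keeps pool observations with
|day − target day| ≤ w/2; at the experiment edges the window is shifted,
not shrunk, preserving training-set size. Temperature mode `same_only`
keeps the target temperature; species-pool mode `composition_only` keeps
the community's species plus noise (maximum 6 + 1 classes). Replicates are
pooled. Majority classes are randomly under-sampled without replacement to
`n_per_class` (250 default, 1000 optional); shortfalls keep everything
with a warning. No synthetic oversampling.

The classifier is a 500-tree random forest, √p candidate features per
split, terminal nodes of one observation, Gini splits, bootstrap samples
the size of the training set. Out-of-bag success per class is the fraction
of that class's training observations whose OOB majority vote (over trees
not containing them) is correct. Prediction is majority vote with
lexicographic tie-break over the sorted class list, so results are
reproducible. Exact invariance of the fit under arbitrary row permutation
is not guaranteed (bootstrap draws depend on row order), so permutation
properties are asserted only where the solution is unambiguous
(well-separated classes).

Abundance: each trajectory predicted as species s contributes
(detections / video frames) to the mean per-frame count of s, so short
spurious tracks carry little weight; counts convert to individuals mL⁻¹
via the sampled volume (chamber height × filmed area, 41.2 µL by default)
and the dilution factor. The per-frame weighting is one reading of a
"weighted average across the video"; trajectory-count weighting is
available by passing raw counts instead.

## Validation

The reference label is a strict-plurality consensus over observers
(experts and, by default, the automatic classifier): a label wins iff it
has strictly more votes than any other; ties discard the trajectory before
any confusion matrix is computed. With four observers strict plurality and
absolute majority differ; plurality is the default and absolute majority a
flag. Sensitivity tp/(tp+fn) and specificity tn/(tn+fp) are computed
one-vs-rest per class; zero denominators report missing, not 0.

## Synthetic-data generator

Each species is an archetype: baseline major axis, aspect ratio, speed,
turning SD, plus a fractional size change per day (temporal drift), a
fractional size change per °C (−2 %/°C around 20 °C; warmer cells are
smaller), lognormal individual- and frame-level variation (positivity),
and a lognormal-Poisson abundance per sample. Minor axis, area and
perimeter (Ramanujan approximation) derive from the ellipse. Movement is a
correlated random walk with wrapped-normal heading increments; per-frame
detection dropout is i.i.d. (default 0.05). The six default archetypes
span ~35–350 µm major axis, mirroring a realistic ciliate size gradient.
Noise trajectories emulate drifting debris: slow directed drift plus
jitter and small, erratically measured shapes — mostly below the
200 µm s⁻¹ training floor yet often above the 50 µm s⁻¹ test floor, so
controls genuinely anchor the noise class. A `with_crossing_sizes`
variant provides two species with identical movement whose size
distributions cross mid-experiment — the regime where the sliding window
is essential.

What the generator does **not** emulate: population dynamics between
sampling days (abundances are drawn, not grown), species interactions,
within-video flow fields, segmentation artefacts beyond i.i.d. dropout,
and trajectory fragmentation/crossing errors. Passing tests therefore
demonstrate correctness of the pipeline's logic and its statistical
behaviour under controlled drift, not performance on any particular real
imaging setup.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately compact designs chosen to make
the contrasts statistically clear: the drifting two-species experiment
uses 13 sampling days over 60 days at ~100 trajectories per monoculture
sample; the six-species design uses 7 days over 30 days at ~160 per
sample. Directional contrasts (window size, species pool, n per class)
average over two or three target communities with fixed seeds. Tolerances:
feature-oracle equivalence at 1e−9 relative; ellipse coverage ±0.01 at
n = 10,000; chance-level OOB ±0.05 at n = 1,000. Covariance ridge 1e−6 in
the GMM; Box–Cox positivity floor 1e−6. Display rounding (volumes to one
decimal, window fractions to integer percent) is separate from internal
full precision — e.g. a 40 mL mix split three ways is exactly 40/3 mL
internally and prints 13.3.

## Known limitations

* The per-window GMM can mislabel a rare species as noise when it overlaps
  the control cloud; the dominance threshold is configurable but no
  supervised alternative is provided.
* Window selection assumes sampling days are comparable across
  temperatures (no per-temperature day offsets).
* The forest's OOB success on balanced training data estimates balanced
  accuracy, which can differ from field accuracy under strong abundance
  imbalance; abundance estimates partially compensate through frame
  weighting.
* Alternative classifiers (SVM, naive Bayes) are not bundled; the
  `classify` module's interface accepts drop-in replacements.
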