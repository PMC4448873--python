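# Methods

## The problem

Wintering songbirds such as great tits forage in fission–fusion flocks:
group membership turns over in minutes, yet season-long association
networks can still be strongly structured by phenotype (sex, age,
residency, body size). Automated feeders fitted with RFID antennae record
a timestamped stream of individual visits. `flocknet` reconstructs the
flocks from that stream, summarises their composition and temporal
stability, builds a weighted association network, and — its central
purpose — attributes any phenotypic assortment to *social* processes
(preference or avoidance in grouping decisions) versus *spatial* processes
(phenotypes settling unevenly across the landscape), using two contrasting
permutation null models.

## Group inference

Visits at one feeder on one day arrive in bursts. The detection times are
modelled as a one-dimensional Gaussian mixture: each mixture component is
one gathering. For each feeder-day, mixtures with K = 1..k_max components
are fitted by expectation–maximization (three restarts each; restart seeds
derived from the global seed and a CRC of the feeder/day key, so results do
not depend on iteration order) and K is selected by BIC. The scan stops
after five consecutive K values without BIC improvement, which in practice
terminates shortly past the true burst count. Detections are hard-assigned
to their maximum-responsibility component, ties broken toward the earlier
component; a gathering's member set is the set of unique individuals among
its detections. Components lighter than `min_component_weight` (default 0,
i.e. off) are merged into the nearest-mean component. `k_max` defaults to
one component per 10 minutes of day span. Times are centred before
fitting, making segmentation exactly invariant to a constant time shift.

The result is the binary **group-by-individual matrix** with per-group
metadata (feeder, day, sampling period, centre time) — the single object
every downstream statistic consumes.

## Association network

Following the gambit of the group, the edge weight for a dyad is the
simple-ratio index SRI = x / (x + y_A + y_B), where x counts gatherings
containing both individuals and y_A, y_B those containing exactly one: 0 =
never together, 1 = always together. Assortment of a categorical trait is
Newman's coefficient r = (Σ_i e_ii − Σ_i a_i b_i) / (1 − Σ_i a_i b_i) on
the weight-proportional mixing matrix e (each undirected edge contributes
half its weight to each orientation); continuous traits use the weighted
Pearson correlation of endpoint values over ordered dyads. Individuals
with unknown trait values stay in the network but are excluded from
assortativity. Dyads never observed together carry zero weight and hence
no influence; structural zeros are not added.

## Group statistics

**Stability.** For two groups j, k both containing a focal individual X
and separated by lag τ, S = G_jk / (G_j!k + G_k!j + G_jk), with G_jk the
count of shared non-focal individuals and G_j!k, G_k!j the counts
exclusive to each group. S = 1 for identical membership; S = 0.5 when
two-thirds of an evenly sized group persists. Pairs qualify when they
share at least `min_shared` (default 1) non-focal members. Each shared
member of a pair acts as focal in turn, so a pair with I common members
contributes I equal terms; per-bin values pool qualifying focal-pairs
(per-focal averaging is available as an option). Lags are binned on a
log10 scale; group times are placed on a common axis as
(day − 1)·86400 + time-of-day. The observed curve is divided by the same
curve computed on the final matrix of the data-stream permutation chain,
since stability is too expensive to evaluate along the chain.

**Size classes.** Sizes below 14 each form their own class; larger sizes
are merged greedily upward until each class carries ≥5% of all group
memberships, the trailing remainder being absorbed into the previous
class. Composition statistics are reported per class: the mean per-group
proportion of a focal class (known-trait members only), the mean binomial
probability C(n,k) p^k (1−p)^(n−k) of each group's composition — p being
the focal-class share of unique participants at that exact group size;
values near the pmf maximum indicate disassortment, small values
assortment — and the Pearson kurtosis (m₄/m₂², normal reference 3,
population moments) of group-mean trait values; bins need ≥4 groups and
non-zero variance, otherwise NaN.

**Body size.** Wing and tarsus are standardized within sex, the first
principal component of their 2×2 covariance is extracted, oriented to
correlate positively with wing, and rescaled to mean 0, variance 1 within
sex. Sexes with fewer than two fully measured individuals yield no scores.

## Null models and attribution

*Node-label (phenotypic) null*: phenotype rows are reshuffled jointly
across individuals (preserving trait covariance; single-trait shuffling is
an option), leaving the observation stream untouched. Default 1000
iterations (tests and the bundled configs use fewer; see below).

*Data-stream (spatio-temporally restricted) null*: a cumulative Markov
chain of restricted swaps. Each step draws a (feeder, sampling-period)
stratum with probability proportional to its number of group pairs (a
uniform-over-strata draw would over-mix sparse strata), two distinct
groups in it, and one individual exclusive to each; the two individuals
exchange groups. The proposal is symmetric — the exclusive-set sizes are
unchanged by the swap — so the chain's stationary law is uniform over
matrices with the observed margins within strata. Group sizes, every
individual's number of memberships (globally and per stratum), and all
group metadata are conserved exactly. Only successful swaps count as
iterations; failed candidate draws are logged, and the chain stops early
only if 100 consecutive draws fail (no legal swap remains). The statistic
is recorded every `sample_every` successful swaps; the final matrix is
kept for expensive statistics.

**Attribution.** A statistic "differs" from a null when it falls outside
the null's central 95% interval (scalars) or outside the null's entire
range in any size class (multi-bin profiles; the whole-range rule avoids
multiplicity corrections over strongly correlated bins — Bonferroni is
inappropriate here because bins share groups). Outside both nulls →
**social**; outside the node-label null only → **spatial** (the stream
null retains the spatial distribution of phenotypes, the node null does
not); inside both → **none**; outside the stream null only → **ambiguous**.

## Synthetic data

The generator emulates the field design: a stratified grid of feeders
(default 9, 250 m apart) sampled over consecutive two-day periods (default
4), birds with sex/age/residency drawn independently (defaults 0.5 / 0.45
/ 0.35) and sex-specific wing–tarsus bivariate normals (males larger).
Each bird's home range is centred on a feeder; per feeder-day, a Poisson
number of gatherings (default 6) occurs at uniform daylight times, group
size is a zero-truncated negative binomial whose mean follows a logistic
map of the local availability pool (asymptote K = 8, midpoint K, scale
K/2), members are drawn sequentially with weights = Gaussian availability
(scale `home_range_sd`, default 80 m — chosen so mean group size is ≈5)
times the product of pairwise social-preference factors against current
members, and each member emits ≥1 detection at N(gathering time, 30 s).

Planted effects: a same-sex factor below 1 plants social sex
disassortment; `spatial_segregation_strength` displaces immigrant home
ranges toward the eastern grid edge (feeder choice weighted by
exp(strength·(x − x_max)/home_range_sd), so strength 0 is exactly neutral
and a single-feeder layout is a fixed point), planting spatially driven
residency assortment. The generator does *not* model patch depletion,
dominance queues, weather, diel activity rhythms or realistic movement;
passing recovery tests therefore shows the statistical machinery is sound
under the stated generative assumptions, not that field data meet them.

## Problem sizes and numerical choices

Defaults throughout are desk-scale versions of the field design, chosen so
the full test suite and the benchmark script run in minutes on one CPU:

- recovery experiments: 80 birds, 6 feeders, 2 periods; full chain
  (detections → mixture segmentation → matrix); node null 200 iterations,
  stream null 20 000 swaps sampled every 200; 10 replicates per scenario.
- null-model calibration: 60 birds, 6 feeders, 3 periods, *homogeneous*
  availability (`home_range_sd` = 10 000 m) and all preferences neutral;
  node null 500 iterations, stream null 100 000 swaps sampled every 250;
  30 replicates. Homogeneity matters: with fine-scale spatial
  heterogeneity inside a stratum, sequential weighted sampling is not
  uniform-given-margins, and the stream null — correctly — detects that
  structure, so coverage of a "neutral" trait drops below nominal. The
  calibration scenario therefore removes all structure the nulls are
  designed to detect.
- paper-scale settings (10⁶ swaps sampled every 10³, 10³ node
  permutations) remain available through configuration.

Other numerics: GMM regularisation 1e-3 s² on component variances;
degenerate streams (< 2 distinct times) become a single gathering; the
logistic saturation fit uses three starts (K₀ = 1.05·max y, x₀ = median x,
s₀ = sd(x)/2, plus two perturbations) under positivity bounds, Gaussian
likelihood with σ̂² floored at 1e-12, AIC with k = 3 (linear) and 4
(logistic) parameters; ΔAIC = AIC_linear − AIC_logistic.

## Known limitations

- Hard assignment only: a bird visiting during two overlapping gatherings
  is assigned to one component per detection; soft membership is out of
  scope.
- The swap chain explores the margin-preserving matrix class connected by
  single swaps; for pathological strata (for example, all groups nested)
  some states may be unreachable.
- The stream-null envelope is estimated from autocorrelated chain samples;
  very short chains understate its width. The defaults above were sized so
  that envelope coverage is nominal in calibration runs.
- Mixed-effects models of week effects on group size are not implemented;
  the saturation module provides fixed-effects linear and logistic fits
  only.
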