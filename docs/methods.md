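# Methods

## Cascade reconstruction

A repost's text embeds the texts of the reposts it was forwarded from,
newest first, separated by `//`. The forwarding level is therefore the
number of segments after splitting on the separator: an empty text is a
bare direct forward (level 1), and empty segments between separators are
bare forwards along the chain and count as segments. Level-1 reposts
attach to the root post; a level-k repost attaches to the level-(k−1)
repost whose author handle equals (case-sensitively) the leading
`@name:` mention of its second segment.

Three situations need conventions the raw data do not fix:

* **Ambiguity.** If several same-level reposts by the same handle could
  be the parent, the nearest earlier-or-equal timestamp wins, then the
  smallest repost id; if no candidate precedes the child, the earliest
  candidate is used. The map is total and deterministic.
* **Orphans.** A repost whose parent cannot be found (deleted or blocked
  intermediate post) is dropped and counted, and its own descendants are
  dropped with it. Re-attaching orphans to the root would deflate depth
  and inflate first-level width, biasing the structural classification
  toward radiation; dropping mirrors excluding uncapturable posts.
* **Conservation.** Resolved edges plus dropped orphans always equal the
  input records; rejected input rows are likewise counted, never
  silently discarded.

Timestamps are ISO-8601 at minute resolution throughout — the platform
exposes minute-level repost times, and the speed metric needs a declared
resolution.

## Topology metrics

For a tree with *n*<sub>ℓ</sub> nodes at repost level ℓ:
scale *S* = Σ<sub>ℓ≥1</sub> *n*<sub>ℓ</sub> (the root is not counted —
scale equals the number of forwards the root received); depth *D* =
max level; maximum width = max<sub>ℓ≥1</sub> *n*<sub>ℓ</sub>; average
width = *S*/*D*, i.e. the mean node count over levels 1..*D* (the root
level is excluded, which is the only convention under which
*W̄* ≤ *W*<sub>max</sub> and *W̄*·*D* = *S* hold exactly). Speed is
*S* divided by the elapsed hours from the root post to the latest
repost, floored at one minute to avoid division by zero; it is the
package's own definition (reposts per hour over the cascade lifetime),
chosen for interpretability, and is undefined for a cascade with no
reposts.

## Structural typology

Radiation: first-level width ≥ every deeper level's width. The
comparison is ≥, so width ties and all depth-1 cascades count as
radiation — a strict inequality would arbitrarily exclude ties in a
corpus dominated by shallow star-like cascades. Otherwise the *pivot*
repost node — argmax of max(forwards, likes), ties broken by larger
forwards, then earlier timestamp, then node id — decides: sector if its
forwards ≥ likes, viral otherwise. Collapsing the decision onto a
single pivot avoids the conflict that arises when the max-forwards node
and the max-likes node differ; the tie-breaks make the label invariant
under sibling permutation. Cascades with no reposts are labeled
undisseminated and excluded from type shares.

## User clustering

Features: user level (0–48), membership level (0–7), posts, followers
and following counts. The three counts are log1p-transformed (follower
counts are heavy-tailed with means above 10^5; raw counts would own the
Euclidean metric) and all features are z-scored. Zero-variance features
are dropped with a warning.

k is selected by the elbow on the within-cluster sum-of-squares curve,
scored as the ratio of successive drops
(WCSS(k−1) − WCSS(k)) / (WCSS(k) − WCSS(k+1)). The raw second
difference of WCSS was considered and rejected: it is dominated by the
k=1→2 drop whenever one split carries most of the between-cluster
variance, so it misses later elbows even for widely separated planted
partitions; the ratio is scale-free and recovers the planted k on every
tested well-separated configuration. Mean silhouette is reported
alongside. Two limitations are inherent to any elbow criterion and are
deliberate behavior here: clusters holding a negligible share of the
points (e.g. below ~3%) barely bend the curve, and hierarchically
separated groups can yield the coarser partition; `--k` overrides the
automatic choice.

Clustering is scikit-learn k-means (k-means++ seeding, 10 restarts,
fixed seed, ≤300 Lloyd iterations), deterministic for a fixed seed.
At k = 5, clusters are named by ordered centroid rules (counts compared
on the log1p scale, min-max normalized across centroids): *influential*
= largest posts+followers composite; *mingler* = among the rest,
most followers with below-median posts; *inactive* = smallest composite
of all five features; the remaining two split on membership level
(*platform* higher, *general* lower). These rules are heuristics
reverse-engineered from the archetypes' qualitative profiles; a rule
collision (e.g. identical centroids) raises and the pipeline falls back
to bare cluster indices.

## Association statistics

Spearman's ρ is the Pearson correlation of midranks (scipy's
implementation; the test suite cross-checks it against an independent
brute-force midrank oracle to 1e-12), with a two-sided p-value from the
t approximation. The topology × authority grid uses pairwise complete
cases; cells with fewer than three cases are reported missing with
their n. Raw p-values are reported, with an optional Benjamini–Hochberg
column — the grid's 25 cells invite multiplicity, but the headline
numbers stay unadjusted. Group summaries use the sample SD and the
t-based CI, mean ± t<sub>0.975,n−1</sub>·SD/√n. Week bins are anchored
on Mondays (ISO convention). Krippendorff's alpha is computed from the
coincidence matrix with the nominal distance, handling missing labels;
it is implemented in-package (no installed dependency provides it) and
is exactly 1 under perfect agreement.

## Synthetic-data generator

The generator emulates the structure the pipeline assumes, with one
integer seed determining every draw (byte-identical outputs on reruns):

* **Users.** Five archetypes with default mix 20.7% general, 26.4%
  platform, 50.0% inactive, 0.9% influential, 2.0% mingler (the
  qualitative shape of observed poster populations: inactive accounts
  dominate, influential accounts are rare). Counts are lognormal and
  levels truncated discrete normals, with centroids separated by ≥5
  within-cluster SDs on at least one feature per pair so that planted
  labels are recoverable.
* **Cascades.** Level-dependent Poisson branching. Radiation regime:
  λ = (5, 0.1, 0.05) — a wide first level and little onward spread.
  Sector/viral regimes: λ = (2, 0.5, 0.3, 0.1) plus a planted level-1
  hub whose offspring count always exceeds the first-level width, so a
  deeper level is the widest; the hub's engagement is forwards-heavy
  (sector) or likes-heavy (viral) with a +50 boost so the pivot rule
  identifies it. The default regime mix is 97% / 1% / 2%. A repost's
  forwards count equals its true number of children; likes are
  negative-binomial (dispersion 0.7). Inter-repost waits are
  exponential with mean 0.5 h, floored to minute resolution, which puts
  cascade speeds in the units-per-hour range.
* **Chain texts** are built recursively (child text = comment + `//` +
  `@parent-handle:` + parent text; 20% of comments empty), and
  reposters within one cascade are distinct, so the parser recovers the
  generated tree exactly — the generator↔parser round trip is an exact
  invariant, not an approximation.
* **Planted associations.** The first-level rate is scaled by
  (log1p(followers)/mean)^1.5, planting a positive scale–followers rank
  correlation; topic propensities depend on archetype (inactive users
  tilt toward social/livelihood topics, influential users toward
  medical ones); sentiment scores are Beta draws whose parameters skew
  negative for epidemic-spread misinformation and positive for medical
  misinformation. Engagement means default to likes 189, comments 13
  per post — likes far exceed forwards on average.
* **Defaults** are 2,500 users and 1,000 posts, the sizes at which the
  recovery and round-trip properties are exercised.

What the generator does **not** emulate: real text content (comments
are token strings), re-forwarding by the same user within a cascade,
clock skew or missing timestamps, deleted intermediate posts (orphans
are exercised by hand-built fixtures instead), cross-cascade user
correlation, and any calibration to a real corpus. Passing tests
therefore demonstrate that the pipeline's logic is correct under its
stated assumptions, not that real platform data satisfy them.

## Degenerate inputs and numerical conventions

Single-node trees have all metrics zero and undefined speed; constant
vectors make ρ undefined (reported missing, never 0); single-row groups
have no CI; a grid with no multiply-coded item makes alpha undefined
(error). Percentages in reports are rounded half-up to two decimals
from their exact numerator/denominator. Cycle or multi-parent edge sets
raise a structural error naming the offending nodes rather than being
silently pruned.
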