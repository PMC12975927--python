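# Methods

## Scope and model

`stratnet` analyzes a participant-by-variable table of 17 clinical measures
(4 sociodemographic, 6 psychopathology, 7 TCI-R personality dimensions) with
a binary stratification flag, supplied as an already-derived column. The
stratification instrument's item-level scoring is out of scope: the pipeline
consumes scored totals only.

Each stratum's network is an unregularized Gaussian graphical model estimate:
partial correlations from the inverse sample correlation matrix, thresholded
by significance. The method's assumptions, stated plainly:

- **Linearity/Pearson correlations throughout**, including for binary
  variables (point-biserial/phi as special cases). No polychoric machinery:
  all 17 variables enter one product-moment correlation system. Dichotomous
  measurement therefore *attenuates* the latent association — a property the
  synthetic generator deliberately reproduces (see below).
- **Degrees of freedom** `df = n − k − 2` with `k = 15` conditioned
  variables. For multivariate-normal data this makes the null distribution of
  each sample partial correlation exactly the distribution of a plain
  correlation at the reduced df, so the null p-values are exactly uniform —
  the property the calibration suite verifies. The df convention is the
  classical one for partial correlations; it is stated prominently because
  conventions vary across software.
- **Strict retention rule `p < 0.25`**: a boundary p equal to 0.25 is
  excluded. The threshold is liberal by design — the edge rule is a screen,
  not a test — and under the null it retains edges at rate α, which doubles
  as a calibration check of the p-value machinery.
- **No regularization, no multiple-testing correction on edges.** A condition
  number above 1e10 on the correlation matrix aborts estimation and names the
  near-collinear variable set (taken from the smallest eigenvector's large
  loadings).

## Graph statistics

Distances are **unweighted hops**: partial-correlation weights are
similarities, not costs, and the integer diameters commonly reported for
these networks presuppose hop counting. Consequences: the diameter is an
integer; average path length is the mean over ordered reachable pairs.

- *Eigenvector centrality*: power iteration on the absolute-weight adjacency
  matrix, shifted by an upper bound on the spectral radius (the shift leaves
  eigenvectors unchanged but prevents the two-cycle oscillation that plain
  iteration exhibits on bipartite-like graphs). Convergence at max
  componentwise change < 1e-8, capped at 1000 iterations, scores scaled so
  the maximum is exactly 1.
- *Closeness*: reachable-only sum with the Wasserman–Faust component
  correction `(n_r/Σd)·(n_r/(n−1))`; isolated nodes score 0. The
  "bridging node" is the closeness maximizer, ties broken by eigenvector
  centrality, then schema order.
- *Clustering*: triangle density on the unweighted topology; nodes of degree
  < 2 score 0 and are excluded from the average.
- Ranks use a stable sort, so ties resolve in schema order.

Closeness, clustering and BFS path lengths are delegated to networkx (their
conventions match the definitions above); eigenvector centrality, modularity
and Louvain are implemented here because the package pins their exact
numerical contract (shift, tolerance, tie-breaks, seeding).

## Communities

Modularity is Newman–Girvan weighted `Q` on **absolute weights** — signed
modularity variants are nonstandard, and the common implementations of this
analysis take magnitudes. Louvain alternates local moves with aggregation:

- Local phase: nodes visited in a freshly shuffled order each sweep; a node
  takes the *first* candidate community with strictly positive gain, scanning
  neighboring communities (plus one empty community) in shuffled order.
  First-improvement was chosen over best-gain deliberately: on dense
  signed-weight graphs, best-gain converges to the same local optimum from
  almost every start, while first-improvement diversifies the optima reached
  across restarts. The empty-community candidate is the only escape from a
  bad all-in-one merge (a genuine single-move local optimum on frustrated
  graphs), and zero-gain moves are rejected to prevent cycling.
- The procedure runs 16 restarts on substreams of the seed and returns the
  best-Q partition; identical seed ⇒ identical output. On every test graph
  with ≤ 8 nodes this attains the exhaustive optimum over all set partitions.
- Resolution fixed at 1.0, exposed as a flag. Final ids are relabeled by
  descending community size.

## Group comparisons

Pearson χ² without continuity correction (the Cramér's V convention
`V = √(χ²/(N·(min(r,c)−1)))` presumes the uncorrected statistic) and
pooled-variance Student t (Cohen's d uses the pooled SD). Effect flags at
V > 0.20 and |d| > 0.50. The Finner family is all comparisons of one
`table_one` invocation (17 tests for the default schema). Percentages are
rounded half-up to one decimal.

A note on a reference value: on the sex contingency table
[[36, 95], [38, 40]] the uncorrected closed form gives V ≈ 0.215, while the
value printed alongside that table in the literature is 0.22; the package
reports the uncorrected value and does not force a match (the provenance of
the extra 0.005 — a rounding chain or a bias-corrected V — is not
reconstructible).

`table_one` operates on the analysis coding of the 17 variables: binary
marital status (not-married = 1) and the ordinal 1–5 social-position score
treated as continuous. Multi-level raw categories (3-level marital, 5-level
social position) are upstream of the pipeline's input contract; SES as the
1–5 ordinal (high = 1 … low = 5) is an assumption, as is untransformed
duration-of-problem in years.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets: a
209-participant cohort split 78/131, mixed binary/continuous measurement,
and stratum-distinct sparse conditional-dependence structures.

- **Latent Gaussian**: per stratum, draws from `N(μ_s, Σ_s)` where `Σ_s` is
  the correlation-normalized inverse of a hand-specified sparse SPD precision
  matrix. The planted partial correlation of a pair is
  `−P_ij/√(P_ii·P_jj)` — zero exactly where the precision is zero.
- **Default design**: ~60 nonzero off-diagonal pairs for the positive stratum
  with a hub on self-directedness, ~68 for the negative with a hub on
  self-transcendence; supports and magnitudes (0.2–0.4 before SPD scaling,
  alternating signs) come from fixed internal streams, so the "hand-specified"
  structures are constants of the package. These are qualitative emulations
  of the reference analysis's edge counts and centrality pattern, not claims
  about any real data.
- **Mean shifts** (Cohen's d on the latent scale): +0.5 impulsivity, emotion
  dysregulation and distress; +0.4 harm avoidance; −0.5 self-directedness.
- **Binary variables** threshold their latent coordinate at
  `c = Φ⁻¹(1−p₋)` with the positive stratum shifted by
  `δ = c − Φ⁻¹(1−p₊)`, hitting target proportions in both strata. Targets
  for sex (male 0.725/0.513) and marital status (0.748/0.744) reproduce the
  reference cohort's margins; comorbid-disorder (0.55/0.75) and
  suicidal-behavior (0.25/0.40) proportions are realistic clinical values
  chosen once, since the reference margins for those variables were not
  available.
- **Observation units** (age 35.5 ± 15.5 years, etc.) are cosmetic affine
  rescalings; correlations are invariant to them. Continuous scores are not
  clipped to instrument ranges, so tails can exceed realistic bounds — this
  does not affect any network quantity.
- **Seeding**: one global seed feeds a `SeedSequence`; each stratum (and each
  replicate in experiments) uses an independent substream.

Two auxiliary designs observe the **latent scale directly** (no binary
thresholding): the identity-precision *null design* used for calibration —
exact p-value uniformity holds only for the continuous Gaussian case, which
is precisely what a calibration check should isolate — and the chain-
structured *strong-recovery design* (adjacent-pair partial correlations
exactly 0.45) used for support recovery and estimation accuracy.
Dichotomization attenuation is exercised separately by the default mixed
design. Passing tests on these designs show that the estimator, the
threshold rule and the test battery behave as advertised under their own
assumptions; they do not show robustness to non-Gaussian margins, outliers,
item-level measurement error or missing data, none of which the generator
emulates.

## What the suites compute

- Oracle equivalence: precision-route partial correlations vs.
  regression-residual correlations (1e-10); eigenvector vs. dense
  eigendecomposition (1e-6); paths vs. Floyd–Warshall; clustering vs. triple
  enumeration; modularity vs. the direct double sum; Louvain vs. exhaustive
  set-partition search on small graphs.
- Calibration: null edge-retention rate vs. α within 3 binomial SE (200
  replicates, both strata); comparison-battery type-I vs. 5% (500
  replicates of a mixed-type null design with equal binary targets).
- Recovery: at n = 5000 the planted 0.45 edges are always retained and
  estimated within ±0.05 for ≥ 95% of pairs.

Problem sizes in the suites (cohorts of ≤ 131 rows for calibration, 200
random graphs ≤ 20 nodes, exhaustive search ≤ 8 nodes, recovery at
n = 5000) were chosen so each property is measured with comfortable
statistical margin while the whole suite stays fast.

## Known limitations

- The p < 0.25 network at n = 78 is intentionally noisy; centrality rankings
  and community memberships vary across seeds (no bootstrap stability
  analysis is provided, matching the analysis the package reimplements).
- Pearson treatment of binary nodes attenuates and can distort conditional
  structure; recovered supports at clinical sample sizes are approximate.
- No regularized (glasso/EBIC) estimation, no mixed graphical models, no
  betweenness or expected-influence centrality — deliberately out of scope.
- Exact reproduction of any particular clinical dataset's networks is not a
  goal; the raw data behind the reference analysis are not public.
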