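# Methods

## The model

A brain state is a functional connectome: a symmetric N×N matrix G of
Pearson correlations between ROI time series, with unit diagonal. A
cohort of M states is treated as M points whose pairwise dissimilarity
is the Frobenius distance restricted to off-diagonal entries,

    d(a, b) = sqrt(2) * || triu(G_a − G_b) ||_F ,

identical to the full-matrix Frobenius norm because the diagonal
difference is identically zero. Multidimensional scaling of the M×M
distance matrix yields coordinates in D dimensions (default D = 3, a
choice made for visualisation, not optimality). State change over time
is modelled by an operator K with K G(t) = G(t+1); between two measured
visits K is realized as a finite difference. Diagnosis labels induce
convex regions (hulls of member coordinates) in the embedding;
"healthy" is defined extensionally as membership of the healthy
region at every visit.

## Connectivity and harmonization

Pearson correlation is the default connectivity measure; Fisher z
(arctanh of off-diagonal entries, diagonal kept at 1 by convention) is
available where variance stabilisation is wanted. Raw Pearson is the
default because the reduced-space contribution tables operate on
connectivity *changes* bounded by 2, which only holds on the
correlation scale. A missing ROI is an entirely-NaN row and column; a
partially observed ROI is an input error. Zero-variance signals have no
defined correlation and abort with the ROI named. Harmonization keeps
exactly the ROIs present in all states, ordered as in the first state,
and records what was dropped per state; it is idempotent and preserves
symmetry. Label matching is exact string match after whitespace
trimming — no fuzzy atlas reconciliation.

## MDS

Two estimators are exposed:

* **classical** (default): Torgerson double centering
  B = −½ J D² J followed by the top-D spectral factorization.
  Deterministic, exact (stress 0) when D² is Euclidean-realizable in D
  dimensions; eigenvalues are sorted descending with a stable tie-break
  on the original index, and negative eigenvalues are clipped to zero.
  If the negative eigenvalue mass exceeds 30 % of the spectrum the
  embedding is flagged as badly non-Euclidean (a warning on the
  Embedding, not an error).
* **smacof**: stress majorization (scikit-learn), seeded, 4 restarts by
  default, eps 1e-12 / 1000 iterations so repeated seeded runs agree
  tightly.

Classical is the default because downstream artefacts (attribution
tables, reduced paths) should be reproducible bit-for-bit without a
seed convention. Reported stress is Kruskal stress-1, defined as 0 for
an all-zero distance matrix. MDS coordinates are defined only up to
rotation/reflection; all internal comparisons use inter-point distances,
and axis signs are meaningful only within a single fitted embedding.

## Axis attribution

For pair p = (i, j), i < j (lexicographic order), and axis d, the
pair–axis correlation is the Pearson correlation across states between
the pair's connectivity values and the axis coordinates; zero-variance
pairs get correlation 0 (not NaN) so sums stay defined. Pair influence
is the plain cross-state sample variance (denominator M−1), ranked
descending with lexicographic tie-break. The per-ROI impact on axis d is

    impact[i, d] = ½ Σ_{p ∋ i} corr[p, d] ,

the ½ sharing each pair between its two endpoints; per axis, impacts
sum to the total pair correlation exactly (tested to 1e-12). Raw
half-sums are reported by default; an optional normalization by the
number of incident pairs (N−1) puts values on a mean-contribution scale
comparable across cohort sizes — useful because raw half-sums grow with
N. No inferential statistics are attached to these rankings; they are
descriptive.

## K-operators and reduced paths

Additive mode (default) defines K as the element-wise change ΔG;
applying K to the source reproduces the target to 1e-12 (float
addition cannot guarantee bit equality; negation-based inversion is
bit-exact, and K is additive over chained visits). Multiplicative mode
(element-wise ratio) is kept for compatibility with the operator
notation; cells with zero source entries are masked NaN and counted,
and inversion requires a fully defined, nonzero operator. The additive
default follows the difference-like character of the reported
contribution tables and signed, zero-centred operator heat maps.

The reduced path between two embedded states reports, per dimension,
100·|Δx_d|/|x_d| (verified to reproduce the published worked example's
60.64 / 198.61 / 1838.24 % to two decimals); a dimension whose source
coordinate is below 1e-12 in magnitude reports NaN there with the
absolute change carrying the information. Per-pair axis contributions
are connectivity change × pair–axis correlation, so |contribution| ≤
|change| always; report rounding is 2 decimals for percentages, 3 for
contributions.

## Subspaces

A diagnosis region is the convex hull of its members' coordinates.
Membership is decided by linear-programming feasibility (is the point a
convex combination of members?), distances to and between regions by
small quadratic programs over the probability simplex (SLSQP). This
uniformly handles the degenerate cases that small cohorts produce —
single points, segments, flat sets — which are flagged but never
errors. Geometric tolerance defaults to 1e-9.

Trajectory verdicts use the healthy region only: *healthy-stable* iff
every visit is inside; *oscillating* iff the inside/outside indicator
flips at least twice; otherwise *diseased*. The third clause includes a
single exit ending outside and a single entry not yet shown stable —
a declared convention, since no quantitative stability criterion
exists; the rule is total and is tested against an exhaustive
truth-table enumeration.

## Synthetic cohorts

The generator emulates the statistical provenance of functional
connectivity rather than adding noise to matrices directly: each group
has a ground-truth block-structured correlation matrix (default 20
ROIs in 4 blocks of 5; within-block correlation 0.6, between-block
0.1 — module-like structure at a size small enough for exhaustive pair
oracles), disorder groups add edits (default: one whole block pair
shifted by 0.4, a strong between-module coupling effect), and each
state is the Pearson connectivity of T multivariate-Gaussian samples
(default T = 500, a typical resting-state scan length in samples).
Edited matrices are re-projected to the nearest correlation matrix
(Higham alternating projections, eigenvalue floor 1e-8), so every
ground truth is a valid correlation matrix and every sampled state is
realizable by construction. Follow-up visits add a single known edit
(default −0.5 on one within-block pair), making the true additive K
available; missing ROIs are injected per state at a configurable rate
(default 0, capped so two ROIs always remain). Everything is
deterministic given the config seed via spawned seed sequences.

What the generator does **not** emulate: BOLD autocorrelation and
spectra, scanner/site effects, head motion, atlas misregistration, or
heavy-tailed signal distributions. Passing recovery tests therefore
shows the pipeline's statistical machinery is correct under clean
Gaussian sampling, not that real cohorts of this size would separate
equally well.

## Problem sizes and verification

The default study conditions — 3 groups × 8 subjects, 20 ROIs, T = 500,
block perturbation max-abs 0.4 — give a mean group silhouette ≈ 0.8 in
the 3D embedding, pairwise-disjoint diagnosis hulls in ~100 % of 20
seeds, and the follow-up-edited pair in the top 3 of its axis
decomposition in ≥ 90 % of seeds (all recomputed by
`scripts/acceptance.py`). Unit tests check every operation against
independent oracles: longhand Pearson, double-loop Frobenius and
upper-triangle extraction, incidence-loop ROI impacts, shapely geometry
for 2D hulls, and exhaustive verdict enumeration. Numeric tolerances:
symmetry 1e-12; entries clamped to [−1, 1] only within 1e-9; exact-MDS
recovery 1e-8; conservation identity 1e-12.

## Known limitations

* Axis attribution is correlational and exploratory; it inherits the
  rotation indeterminacy of MDS and re-fits when states are added.
* Convex hulls are a crude subspace model: they cannot represent
  multi-modal or non-convex diagnosis regions, and with very few
  members they under-cover the true region.
* The percentage-variation path measure is undefined on zero
  coordinates and scale-sensitive near them (a small |x_d| inflates the
  percentage), which is why absolute changes are always reported
  alongside.
* Multiplicative K is ill-conditioned wherever source entries are near
  zero; additive mode is recommended throughout.
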