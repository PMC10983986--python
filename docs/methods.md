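# Methods

## Model and assumptions

The quantity of interest is the local, linear spatial trend of a
transcriptional program's activity.  Given per-spot program loadings
`F` (from NMF or any other non-negative phenotype quantification) and spot
coordinates `(X, Y)`, the method fits, within each small spatial window,

    F ~ β0 + βX·X + βY·Y      (ordinary least squares)

and reads `(βX, βY)` as the gradient direction (pointing toward increasing
activity) and the unadjusted `R²` as the evidence that a gradient exists
there at all.  No global spatial model is assumed: gradients may appear,
vanish, or reverse between neighboring niches, which is exactly why the
slide is scanned with many small overlapping windows instead of fitting one
trend over all spots.  The linearity assumption applies only at window
scale (~25 spots); any smooth field is locally linear at that scale.

## Window construction

Spots are partitioned into `P = round(N/S)` balanced clusters on their
coordinates (seeded k-means followed by greedy reassignment of members from
the largest to the smallest cluster until sizes differ by at most one).
Each cluster's member centroid is a grid point; its window is the `Q`
spots nearest to that grid point (Euclidean; distance ties broken by spot
index).  Total membership is exactly `P·Q`, so with `S = 5`, `Q = 25` each
spot is covered by `Q/S = 5` windows on average — an arithmetic identity,
not an approximation.  `Q` controls resolution: smaller windows see finer
gradients but leave fewer degrees of freedom for the three-parameter fit
(`Q ≥ 4` is enforced; `Q ≥ ~20` is sensible in practice).

A degenerate single-window tiling (`round(N/S) = 1`) is permitted; the
regression then runs once over the whole slide.

## Gating and retention

A fit is a gradient iff `R² ≥ r2_min`, inclusive, with default 0.6 —
deliberately above the conventional "moderate fit" of 0.5 so that a called
gradient explains a clear majority of the local loading variance.  Fits on
degenerate inputs never pass: constant loadings (zero variance, `R²`
defined as 0, direction as the zero vector) and rank-deficient designs
(collinear coordinates, fit through the pseudoinverse and flagged).
A program is retained iff it passes in at least `ceil(min_frac · P)` grid
points (default 5 %), which suppresses isolated noise windows.  An empty
result — no retained program — is a valid outcome on slides without
salient gradients, not an error.

## Factorization

Counts are normalized as `log(1 + count/depth · scale)` with
`scale = 10⁴` (library-size normalization; all-zero spots dropped).  NMF
runs on this matrix over all genes by default; an optional variable-gene
filter exists but is off, since gradient detection downstream is invariant
to per-program scale and benefits from the full gene space.

The solver is NNDSVDa initialization (deterministic SVD-based seeding with
a fixed sign convention) followed by multiplicative Frobenius updates.
This choice trades some convergence speed for two properties the pipeline
relies on: bitwise determinism for a fixed seed and input, and support for
an observation mask.  The mask enables Wold-style cross-validated rank
selection: 5 % of matrix entries are held out (3 repeats), the model is
fit on observed entries only per candidate `k` in 6…10, and the `k` with
the lowest held-out squared error wins, ties going to the smaller rank.
The scale convention fixes each `H` row to unit maximum with the scale
absorbed into `W`; `R²` is scale-invariant, so this only standardizes
reports.  Non-convergence at `max_iter` returns with a warning rather than
an error — the error trace is stored in the model's provenance.

Per-program signatures are the top 50 genes by gene loading, ties broken
lexicographically.

## Proximity, tumor ratios, TRCs

Gradient proximity from program A to program B is the mean, over A's
passing grid points, of the distance to the nearest B-passing grid point —
asymmetric by construction (a small set near a large set is close to it;
the reverse need not hold).  When B has no passing grids the distance is
reported missing, never imputed.  The display copy is `log(D + ε)` with
`ε = 1` coordinate unit to avoid `log 0` at coincident grids; the raw
matrix is always written untransformed.

With per-spot tumor/normal flags (supplied as input; aneuploidy calling is
out of scope), each window's tumor ratio is the fraction of flagged
members, and each retained program's mean ratio is the unweighted average
over its passing windows.  Programs are grouped into `k = 3` tumor-ratio
clusters by exact one-dimensional k-means — in 1-D the optimal partition
is contiguous in sorted order, so an `O(k·n²)` dynamic program over split
points is exact and needs no seed.  Labels are ordered by cluster mean:
1 = normal-leaning, 2 = boundary, 3 = tumor-leaning.  The clustering
method behind the published three-way categorization is named ambiguously
in the literature this mirrors; exact 1-D k-means is our reading, and `k`
is exposed.

## Meta-programs

Retained per-sample programs are clustered by top-50-gene overlap.  A
founder is the program with the most partners sharing **more than 20**
(≥ 21) of their top 50 genes, at least two partners required; ties go to
the larger total overlap, then lexicographic (sample, program).  The
cluster grows greedily: the unassigned program with the largest overlap
against the cluster's *current* 50-gene signature joins if it shares **at
least 20** genes; after each merge the signature is recomputed by ranking
genes on member support count, then mean loading, then name, keeping the
top 50.  (The two thresholds differ by design — the founder criterion is
phrased strictly, the merge criterion inclusively — and both are exposed
parameters; an option grows against the founder's static top-50 instead of
the evolving signature.)  The loop repeats on the remaining programs until
no founder qualifies; leftovers are Unclustered.  Because the catalog is
kept sorted and every tie-break is lexicographic, the partition is
invariant to input order.

Specificity of a meta-program to a label scheme (study or tumor type) is
the delta-Shannon entropy: the natural-log entropy of its member-category
fractions minus the mean entropy after shuffling the labels across the
whole catalog (preserving global label frequencies), averaged over 10
seeded draws.  Strong negative values flag category-specific
meta-programs.  A figure-style variant (shuffled mean minus real) is
available behind a flag; the subtraction order above is the primary
definition.

## Annotation

Enrichment of a signature in a gene set is the hypergeometric upper tail
`P(X ≥ m)` with `X ~ HG(M, K, n)` — `m` overlap, `n` query genes, `K` set
genes after intersection with the universe, `M` universe genes.  The
universe defaults to the genes present in the dataset's count matrix, the
standard choice in enrichment practice.  P-values are
Benjamini–Hochberg adjusted per query (across the sets tested for that
target), and `E = −log₁₀ p_adj`.  Annotation terms are selected in two
stages: top 40 sets by adjusted p (ties by larger overlap, then set name),
then top 5 by cross-program specificity
`spec(p, i) = E[p,i] − mean over other programs of E[·,i]`, which
penalizes sets enriched everywhere.  The log base only rescales both terms
of `spec` equally and is a parameter.

## Synthetic data

The generator emulates the geometry and noise structure the method is
designed for, not a full transcriptome.  Spots sit on a hexagonal lattice
(Visium packing; nearest-neighbor distance = pitch) or a square lattice.
A planted gradient is a planar loading field
`max(0, a + s·(cosθ·x + sinθ·y) + N(0, σ))` inside a disk; outside their
regions all programs carry a flat baseline `max(0, 0.5 + N(0, σ_b))`.
`sigma_for_window_r2` converts a target in-window `R²` into `σ` via the
variance of the planar projection over a `Q`-spot window
(`var = s²r²/4`, `r² = Q·pitch²·√3/(2π)`), so "planted R² ≈ 0.8" is a
calibrated statement.  Counts are `Poisson(c · W_true·H_true)` with one
global constant `c` setting the mean depth and near-disjoint block gene
supports in `H_true`; the expected count matrix is exactly rank k and
per-spot depth varies with total activity, as on a real slide.  The
baseline activity is essential: a gradient is observable after
library-size normalization only through the expression *composition*, and
without background the planted program's read share saturates and the
gradient disappears — real Visium spots are mixtures, which this mimics.
The tumor region is a disk over the first gradient's region.

What the generator does **not** emulate: gene-gene correlation beyond the
factor model, segmentation artifacts, spatial autocorrelation of noise,
platform-specific dropout.  Passing tests therefore demonstrate correct
recovery of the model the method assumes, not performance on arbitrary
real tissue.

A consequence seen in testing: NMF on the log-normalized synthetic counts
recovers the planted programs only partially — components mix, a known
identifiability limit of NMF on log-scale data (an independent
coordinate-descent NMF behaves the same).  Exact one-to-one retention of
planted programs is therefore asserted on the pipeline run from planted
loadings (the method's defined input is the embedding); count-level tests
assert that detected gradients are real and localized (≥ 80 % of passing
grids inside planted regions) rather than counting components.

## Numerical choices and problem sizes

- OLS via pseudoinverse; one design factorization per window serves all k
  programs.  `R²` clipped to [0, 1]; exactly constant loadings are given
  `SStot = 0` explicitly to sidestep rounding in the mean.
- All tie-breaks (nearest-neighbor membership, top genes, founder
  selection, annotation ordering) are deterministic — index or
  lexicographic — so a fixed config and seed reproduce every output table
  byte for byte.
- Thresholds are inclusive (`≥`).
- Test and acceptance runs use slides of 400–2000 spots, 150–200 genes,
  mean depth 2000–4000, and 5 programs — sizes chosen so the full
  pipeline, including NMF, completes in seconds while every planted
  structure remains comfortably detectable at the default S, Q, and R²
  gate.

## Known limitations

- The linear local model reports the best-fitting direction even for
  radial or saddle fields; such windows typically fail the `R²` gate but a
  strong curved gradient across a small window can still pass with a
  locally averaged direction.
- Balanced clustering is greedy, not optimal; only the grid-point
  placement depends on it, and windows are re-derived as Q-nearest sets.
- The MU solver can need many iterations near convergence; rank selection
  uses moderate iteration caps because held-out error curves flatten far
  earlier than the factors themselves.
- Meta-program growth is greedy and order-deterministic; it does not
  optimize a global objective, matching the published procedure it
  re-implements rather than improving on it.
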