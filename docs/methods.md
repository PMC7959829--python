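# Methods

## The model

morphnet implements an individual-subject morphological similarity network
for the cerebral cortex.  The data unit is a subject's vertex-wise surface
morphometry: every vertex of a triangulated cortical surface carries a
gray-matter volume (mm³), a surface area (mm²) and a cortical thickness
(mm), and belongs to exactly one parcel of a fixed parcellation.  Parcels
with fewer than 50 vertices are excluded before any network is built (a
parcel with exactly 50 vertices is kept); the default parcellation is a
32-parcel functional parcellation whose per-parcel vertex counts are built
into the synthetic generator.

### Edge definition: histogram distribution similarity

For one subject, one measure, and one pair of parcels (i, j):

1. pool the two parcels' vertex values and divide the pooled
   [min, max] range into `n_bins = 30` equal-width bins
   (left-closed/right-open, final bin closed);
2. count each parcel's vertex frequencies over those *shared* bins;
3. the edge weight s_ij is the Pearson correlation of the two frequency
   vectors.

Shared pooled-range bins are essential: correlating histograms computed on
different supports is meaningless.  Pearson correlation is location- and
scale-invariant, so raw counts and proportions give identical similarities
(asserted as a property test), and jointly rescaling both parcels' values
rescales the bin edges without changing any count.  Repeating step 1–3
over all pairs yields a symmetric P×P matrix with unit diagonal, one per
subject and measure.

Degenerate pairs — a zero-width pooled range, or a frequency vector that
is constant across bins — are assigned similarity 0 with a warning counter
rather than dropped, keeping the matrix complete.  0 is neutral under the
absolute-value and OMST stages that follow.  This rule takes precedence
even when the two multisets are identical (identical parcels normally give
similarity 1, but a constant frequency vector carries no distributional
shape to correlate).

### Topological filtering: orthogonal minimal spanning trees (OMST)

Negative similarities are informative connections (inhibitory
relationships), so the matrix is absolutized before filtering.  OMST is a
threshold-free filter: round m extracts the maximum spanning tree among
edges not selected in rounds 1..m−1 (trees are pairwise edge-disjoint,
hence "orthogonal"), and after each round the criterion

    GCE(m) = GE_w(union of trees 1..m) − Cost(m)

is evaluated, where Cost(m) is the selected fraction of total edge weight
and GE_w is weighted global efficiency with edge distance d = 1/w
(d = 1−w available as a config alternative).  The union at the
GCE-maximizing round is returned, binarized.  Choices fixed here, recorded
in the per-round diagnostics table:

- Kruskal construction with tie-break (descending weight, ascending
  (i, j)), for bit-reproducibility; equal weights yield the
  lexicographically smallest edge set.
- Iteration stops when no edge-disjoint spanning tree remains or after
  N−1 rounds; the argmax is over all completed rounds, not the first
  decline, for robustness to non-monotone GCE.
- The weighted graph is used only inside the criterion; all reported
  efficiency metrics are computed on the binary output, and the output is
  always connected because it contains the round-1 spanning tree.

### Efficiency metrics (binary graph)

With L_ij the shortest hop count and 1/∞ := 0:

- global efficiency  E_glob = Σ_{i≠j} (1/L_ij) / (N(N−1))
- nodal efficiency   E_nodal(i) = Σ_{j≠i} (1/L_ij) / (N−1)
- local efficiency   E_local(i) = E_glob of the subgraph induced on i's
  neighbors (i excluded); degree-0/1 nodes get 0.

The node-average of nodal efficiency equals global efficiency by
construction; the test suite asserts this to 1e−12 on every graph it
touches, and checks all three metrics against independent
Floyd–Warshall/enumeration oracles exhaustively on all connected graphs
with up to 6 nodes, on random graphs with up to 8 nodes, and against
networkx.  Shortest paths use level-synchronous breadth-first search over
all sources simultaneously (boolean matrix products), which is exact for
unweighted graphs.

### Interaction statistics

The behavioral model is ordinary least squares:

    beh = α1·age + α2·E + α3·sex + α4·edu + α5·ICV + α6·morph_global
          + β·(age × E) + γ

where E is one efficiency value (global, or one parcel's nodal/local
efficiency) and morph_global is the whole-cortex covariate matched to the
network measure (total volume / total area / vertex-weighted mean
thickness).  β tests whether the efficiency–behavior association changes
with age.  By default all continuous variables *including the behavior*
are z-scored and the interaction is the product of standardized age and
standardized E, so β is a standardized coefficient; raw-scale fitting is a
flag.  Tests are two-sided.  Rank-deficient or constant designs raise an
error naming the offending columns.

Multiple testing: Benjamini–Hochberg FDR at q < 0.05.  For nodal and local
efficiency the family is the set of parcels within one
(measure, behavior, metric) combination; for global efficiency (one test
per behavior) the family is the set of behaviors within a measure.
Columns that are constant across subjects (e.g. local efficiency on a
network that is a tree for every subject) cannot be tested and are
skipped.

Leave-one-out reproducibility: the model is refit n times with one subject
deleted; reproducibility is 100 × (folds with β's uncorrected p < 0.05)/n.
The fold-significance criterion and α are configurable; rank-deficient
folds are excluded from numerator and denominator with a warning.

## The synthetic cohort generator

The generator emulates exactly what the method consumes and nothing more:

- Each parcel is an i.i.d. bag of vertex values — log-normal for volume
  and area (right-skewed, strictly positive; per-vertex medians ≈ 25 mm³
  and ≈ 9 mm²), zero-truncated normal for thickness (mean 2.5 mm,
  sd 0.5 mm).  Per-parcel location/scale parameters are drawn once per
  cohort spec so parcels differ; parcels in the "similarity plant" share a
  template, so their histogram similarity is high by construction.
  Per-subject multiplicative jitter (sd 0.05 in log space) individualizes
  subjects.
- Covariates mirror a typical adult-lifespan design: n = 65 subjects, age uniform
  on 18–64 years, balanced binary sex, education ≈ N(15.4, 3.2²) years
  clipped to 8–22, ICV ≈ N(1.45·10⁶, (1.5·10⁵)²) mm³.
- Behaviors follow the interaction model forward, with efficiency taken
  from the *real* pipeline run on the synthetic morphometry — integration
  bugs therefore surface in recovery tests, not only unit tests.
- Default coefficients are on the standardized scale and sized so that
  Var(beh) ≈ 1 with noise sd √(1−0.465) (R² ≈ 0.47): planted and fitted
  standardized βs are then directly comparable, and the recovery test
  demands |mean bias| < 0.05 over 200 cohorts.  A second behavior with
  β = 0 is generated by default as a built-in negative control.

`simulate_glm_cohort` is a deliberately minimal sibling used to calibrate
the regression stage alone (efficiency drawn as a standard normal); the
type-I-error check (1000 null cohorts of n = 65, rejection rate inside
the 99% binomial interval around 0.05) runs on it.

What the generator does **not** emulate: cortical geometry and spatial
autocorrelation on the surface, scanner noise and site effects,
correlations between covariates (age and ICV are independent here), and
any realistic dependence of vertex distributions on age.  Passing tests
therefore demonstrate the correctness and calibration of the machinery,
not the empirical claims one could make on real scans.

## Numerical and design choices

- Binning uses numpy's histogram convention; the value-at-last-edge case
  is pinned by a test.
- Pearson similarities are clamped to [−1, 1] against floating overshoot.
- The OMST GCE comparison uses exact argmax over the diagnostics table;
  ties go to the earliest round.
- Efficiency identities are exact (the profile's global value is the mean
  of the nodal vector by construction).
- The pipeline is a pure function of (inputs, config): every artifact is
  written with a SHA-256 digest into a manifest, and re-running the same
  config reproduces the manifest byte for byte.  The manifest includes the
  serialized config, so runs into *different* output directories differ in
  exactly that one artifact.
- Problem sizes in the test suite: exhaustive oracle checks run on all
  26 704 connected 6-node graphs and 500 random 8-node graphs; OMST
  oracle equivalence on 100 random graphs of 4–6 nodes (spanning-tree
  enumeration is factorial in N); the end-to-end determinism check runs
  the full 65-subject, 32-parcel cohort with a single measure.

## Known limitations

- The OMST literature contains several selection-criterion variants; the
  diagnostics table exposes per-round cost/efficiency so alternatives can
  be compared downstream, but only the efficiency-minus-cost rule is
  implemented.
- The FDR family for global-efficiency tests (across behaviors) is a
  package convention; with very few behaviors the correction is weak.
- Whether per-vertex "volume" means FreeSurfer-style per-vertex gray
  matter volume or area × thickness is a choice adapters must document;
  the TSV contract is agnostic.
- LOO reproducibility uses uncorrected fold-wise p < 0.05; an
  FDR-corrected criterion within each fold would be stricter.
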