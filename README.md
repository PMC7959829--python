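# morphnet

Individual-subject **morphological similarity networks** of the human
cortex, with threshold-free topological filtering, graph-efficiency
metrics, and age-interaction statistics.

Structural covariance networks correlate regional measures *across*
subjects and yield one network per group. morphnet instead builds one
network **per subject** from a single structural scan: the connection
between two cortical parcels is the similarity of their vertex-wise
morphometric *distributions*. This gives every individual their own
volume, surface-area, and thickness network, which can then be related to
that individual's behavior.

## The method

For each subject, measure (volume mm³ / area mm² / thickness mm), and
parcel pair (i, j):

1. **Histogram similarity.** Pool the two parcels' vertex values, divide
   the pooled [min, max] range into 30 equal-width bins, count each
   parcel's vertex frequencies over the shared bins, and set
   s_ij = Pearson correlation of the two frequency vectors. Parcels with
   < 50 vertices are excluded first.
2. **OMST filtering.** Take |s_ij| (inhibitory connections count), then
   union successive edge-disjoint maximum spanning trees, keeping the
   round m* that maximizes global cost efficiency
   GCE(m) = GE_w(union) − Cost(m), with edge distance 1/w. Binarize the
   result; it is always connected.
3. **Efficiency.** On the binary graph with hop distances L_ij:
   E_glob = (1/(N(N−1))) Σ_{i≠j} 1/L_ij,
   E_nodal(i) = (1/(N−1)) Σ_{j≠i} 1/L_ij,
   E_local(i) = E_glob of the subgraph induced on i's neighbors.
4. **Statistics.** For each behavior and efficiency value E, fit

   beh = α₁·age + α₂·E + α₃·sex + α₄·edu + α₅·ICV + α₆·morph_global
         + β·(age × E) + γ

   by OLS on z-scored variables and test the age × efficiency interaction
   β (two-sided). Benjamini–Hochberg FDR (q < 0.05) runs across the
   parcels of each nodal/local family; leave-one-out reproducibility is
   the percentage of n single-subject-deleted refits in which β stays
   significant.

A fully synthetic cohort generator (per-parcel value distributions,
plantable cross-parcel similarity, covariates, and behaviors generated by
the forward model with the pipeline's own efficiency) makes every stage
testable without scan data. See `docs/methods.md` for assumptions,
parameter choices, and limitations.

## Worked example

```python
from morphnet import (
    default_cohort_spec, simulate_cohort,
    fit_interaction_glm, loo_reproducibility,
)

spec = default_cohort_spec(seed=1, n_subjects=65)   # 32 parcels, ages 18-64
subjects, cohort, efficiency = simulate_cohort(spec, measure="area")
print(f"subjects: {len(subjects)}, parcels: {len(spec.parcels)}")
print(f"mean global efficiency: {cohort['e_global'].mean():.4f}")

fit = fit_interaction_glm(cohort, "beh", "e_global")
print(f"age x efficiency beta = {fit.beta:.3f}, t = {fit.t_stat:.2f}, "
      f"p = {fit.p_value:.4f}")

loo = loo_reproducibility(cohort, "beh", "e_global")
print(f"LOO reproducibility: {loo.reproducibility_pct:.1f}% over {loo.n_folds} folds")
```

prints

```
subjects: 65, parcels: 32
mean global efficiency: 0.4066
age x efficiency beta = 0.380, t = 3.78, p = 0.0004
LOO reproducibility: 100.0% over 65 folds
```

The cohort's `beh` column was generated with a planted standardized
interaction of 0.35, so the fitted β = 0.380 recovers it within sampling
error; the mean global efficiency ≈ 0.41 reflects the sparse OMST-filtered
32-node graphs; and the interaction is significant in all 65 leave-one-out
refits.

## Command line

```bash
morphnet simulate --out-dir sim --n-subjects 65 --seed 1 --measure area
morphnet build-network --input sim/vertices.tsv --measure area --out matrix.tsv
morphnet filter --matrix matrix.tsv --out adj.tsv
morphnet efficiency --adj adj.tsv --out eff.tsv
morphnet stats --cohort sim/cohort.tsv --eff eff.tsv --behaviors beh --loo --out results.tsv
morphnet run --config run.yaml          # full chain with manifest + digests
```

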