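# marmoconn

Quantitative analysis of cortico-cortical connectivity from retrograde
tracer injections, built for mesoscale connectomics of the primate
(marmoset) cortex.  The package takes per-injection tables of labeled
neurons registered to a parcellated 3D template and computes:

* **Connectivity matrices.**  For an injection into area *A*, the strength
  of the projection from area *B* is the extrinsic fraction of labeled
  neurons

  FLNe(B→A) = N(B→A) / (N(all→A) − N(A→A)),

  and its laminar origin the supragranular fraction

  SLN(B→A) = N_supra(B→A) / N(B→A),

  with the field's aggregation rules across repeat injections (arithmetic
  mean for FLNe with unobserved projections as 0; pooled counts for SLN)
  and hierarchical-clustering ordering of the matrices.

* **Wiring-cost geodesic distances.**  Interareal distances are the lengths
  of simulated axonal tracts that traverse white matter easily
  (f_WM = 1.0), gray matter with difficulty (f_GM = 0.05) and never leave
  the brain.  A first-order upwind Fast Marching solver propagates the
  arrival time T (|∇T| = 1/speed) from each area centroid (the signed-
  distance-transform maximum of the area mask); tracts are traced by
  gradient descent on T, both directions per pair are averaged,
  d_ij = ½(d_{i→j} + d_{i←j}), and their relative difference is kept as a
  direction-discrepancy QC.

* **Connectivity distance vs. distance from primary areas.**  Per
  injection, the labeled-neuron-weighted mean afferent length (area-based
  from centroids, or cell-based from per-cell tracts after mid-thickness
  projection and exclusion-zone filtering), regressed on the wiring
  distance to the nearest primary area with location/volume covariates
  (OLS; standardized slope β with 95% CI and the overall F test).

* **Local vs. distant connectivity across networks.**  The ratio of the
  fraction of labeled cells within 4 mm of the injection center to the
  fraction beyond 8 mm, compared across functional networks (the five
  marmoset networks Pri/HOSom/VisM/CON/APEX ship as a packaged default)
  with a tie-corrected Kruskal–Wallis H test and Holm-adjusted Dunn
  post-hoc comparisons.

A **synthetic brain phantom** (spherical-shell cortex over a white-matter
core, contiguous area sectors, laminar labels, injections with halo
exclusion zones, and cell clouds with planted distance-dependent
projection strengths) makes every stage testable without portal data.
Real data from a connectivity portal can be imported through the CSV/NIfTI
readers (`marmoconn.io`), with a column-mapping option for external
spreadsheets.

## Worked example

```python
import marmoconn as mc
from marmoconn import phantom, wiring
import numpy as np

cfg = mc.PhantomConfig(seed=0)            # 80^3 voxels at 0.25 mm, 8 areas
tpl = phantom.build_template(cfg)
dmat = wiring.pairwise_area_distances(tpl)
print(f"mean interareal distance: {dmat.mean_distance():.2f} mm")
iu = np.triu_indices(len(dmat.areas), k=1)
print(f"discrepancy p95: {np.quantile(dmat.discrepancy[iu], 0.95):.4f}")
print(wiring.sensitivity_sweep(tpl, [1.0, 10.0, 20.0, 30.0]).round(3))
```

prints

```
mean interareal distance: 10.27 mm
discrepancy p95: 0.0466
1.0      9.313
10.0    10.230
20.0    10.271
30.0    10.269
```

The mean wiring distance (10.27 mm on this 16 mm phantom brain) is stable
to within 0.4% for white/gray speed ratios 10–30 — the biologically
relevant regime — and only drops (by ~9%) when gray matter becomes as easy
to traverse as white matter, so trajectories no longer detour through the
white-matter core.  95% of area pairs have forward/backward trajectory
discrepancy ≤ 0.047, the numerical-stability check applied to the distance
matrix.  The `examples/` directory holds one narrative script per
capability (phantom, matrices, distances, connectivity-distance GLM,
network comparison); a thin CLI runs the same stages from a shell
(`marmoconn all --config demo.json`).

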