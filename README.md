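# gyrihinge

Detection of **3-hinge gyral junctions** on triangulated cortical surfaces
and analysis of their role as **structural connectome hubs**.

## Scientific problem

The crests of cortical gyri form a network of ridge lines. Where three
gyral crests meet, the surface forms a *3-hinge junction* — a Y-shaped
convolution that is denser in fiber terminations than ordinary (2-hinge)
gyral wall. The question this package operationalises is whether cortical
patches centred on 3-hinge junctions behave as *hubs* of the patch-level
structural connectome: higher degree, strength, betweenness centrality and
participation coefficient than 2-hinge gyral patches, and preferential
survival in the deep cores of a weighted network decomposition.

The package provides every stage of that analysis, plus synthetic
generators with analytic ground truth so each stage can be validated
end to end:

1. **Surface geometry** — gyral altitude, watershed crest segmentation,
   geodesic distance transform, crest-tree pruning and 3-hinge extraction
   (`gyrihinge.hinges`).
2. **Parcellation** — equal-area cortical patches, labelled H3 (contains a
   3-hinge), H2 (gyral, hinge-free) or SULCAL (`gyrihinge.parcellation`).
3. **Connectome construction** — streamline endpoint snapping, fiber-count
   matrices with an explicit conservation audit (`gyrihinge.connectome`).
4. **Nodal graph metrics** — degree, strength, weighted betweenness, local
   efficiency, weighted clustering, participation coefficient
   (`gyrihinge.metrics`).
5. **Network decomposition** — s-core and nodal-strength decompositions,
   class ratio curves, and a label-shuffling test for the
   "3-hinge curve surpasses 2-hinge curve" event (`gyrihinge.decomposition`).
6. **Group statistics** — within-subject z-scoring, Welch t-tests, and
   size-preserving label permutation tests (`gyrihinge.stats`).
7. **Functional involvement** — sparse dictionary learning on signal
   matrices; per-vertex network involvement counts (`gyrihinge.functional`).
8. **Synthetic ground truth** — folded sheets with planted Y-junctions,
   planted-hub network cohorts, streamline sets realising a requested
   count matrix, and sparse-coded signal matrices (`gyrihinge.synthetic`).
9. **I/O and CLI** — GIFTI/PLY/OFF surfaces, TCK/TRK tractograms, CSV
   matrices and a `gyrihinge` command-line tool (`gyrihinge.io`,
   `gyrihinge.cli`).

## Worked example

```python
import numpy as np
import pandas as pd
from gyrihinge import (gen_folded_surface, detect_hinges, watershed_segment,
                       equal_area_parcellate, label_patches,
                       gen_network_cohort, CohortSpec, compute_all_metrics,
                       compare_classes)
from gyrihinge.decomposition import (S_CORE, crossing_permutation_test,
                                     default_s_levels, ratio_curves)

# 1. surface with five planted Y-junctions
mesh, truth = gen_folded_surface(n_junctions=5, seed=42)
crest = detect_hinges(mesh)
print(f"planted junctions: {len(truth.hinge_locations)}, "
      f"detected 3-hinges: {len(crest.three_hinges)}")

# 2. patch labels on that surface
seg = watershed_segment(mesh, mesh.altitude, 0.0)
parc = equal_area_parcellate(mesh, 100, seed=0)
labels = label_patches(parc, seg, crest, mesh)
print("patch classes:", {c: labels.count(i) for i, c in
                         enumerate(["H3", "H2", "SULCAL"])})

# 3. planted-hub cohort and hub statistics
cohort = gen_network_cohort(CohortSpec(n_subjects=10, seed=0))
tables = [compute_all_metrics(net, seed=i, subject_id=i, labels=lab)
          for i, (net, lab, _) in enumerate(cohort)]
comps = compare_classes(pd.concat(tables, ignore_index=True),
                        n_perm=999, seed=0)
for c in comps:
    print(f"{c.metric:>14}: H3 {c.mean_h3:+.2f}  H2 {c.mean_h2:+.2f}  "
          f"perm p = {c.p_permutation:.3f}")

# 4. s-core decomposition of the first subject
net, lab, _ = cohort[0]
levels = default_s_levels(net)
curve = ratio_curves(net, lab, levels, S_CORE)
p = crossing_permutation_test(net, lab, levels, S_CORE, n_perm=999, seed=0)
last = np.flatnonzero(curve.preserved_counts > 0)[-1]
print(f"deepest s-core: {curve.preserved_counts[last]} nodes, "
      f"H3 fraction {curve.ratio_h3[last]:.2f} "
      f"(intact fraction {curve.ratio_h3[0]:.3f}), crossing p = {p:.3f}")
```

Output:

```text
planted junctions: 5, detected 3-hinges: 5
patch classes: {'H3': 4, 'H2': 3, 'SULCAL': 93}
        degree: H3 +2.49  H2 -0.11  perm p = 0.001
      strength: H3 +2.58  H2 -0.24  perm p = 0.001
   betweenness: H3 +2.44  H2 -0.35  perm p = 0.001
    efficiency: H3 +1.84  H2 +0.02  perm p = 0.001
    clustering: H3 -0.37  H2 +0.34  perm p = 0.001
 participation: H3 +0.90  H2 +0.10  perm p = 0.001
deepest s-core: 23 nodes, H3 fraction 1.00 (intact fraction 0.125), crossing p = 0.006
```

Metric columns are z-scored within subject before pooling, so group means
are in standard-deviation units. The planted hubs dominate degree,
strength, betweenness and participation; the deepest surviving s-core is
composed entirely of 3-hinge patches even though they make up only 12.5%
of the intact network, and the label-shuffling test confirms that the
ratio-curve crossing does not arise by chance.

The same pipeline is available end to end from the command line:

```bash
gyrihinge run --out-dir scratch/demo --seed 0
gyrihinge simulate surface --n-junctions 3 --seed 1 --out scratch/sheet.ply
gyrihinge detect-hinges scratch/sheet.ply \
    --altitude scratch/sheet.altitude.txt --out scratch/crest.json
```

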