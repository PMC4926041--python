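# harmonyseg

Intensity-based segmentation of 2-D grayscale biomedical images (MRI
brain slices are the motivating case) by fuzzy c-means, with the
initial cluster centers optimized by an adaptive, rough-set-initialized
harmony search instead of drawn at random.

## The problem

Fuzzy c-means (FCM) clusters the pixel intensities of an image into
`c` tissue-like classes by minimizing the fuzzified within-cluster
scatter

```
J_m(U, V) = Σ_i Σ_j u_ij^m · d(x_j, v_i)²,    Σ_i u_ij = 1,  m > 1,
```

alternating the closed-form updates

```
u_ij = (1/d_ij²)^(1/(m−1)) / Σ_k (1/d_kj²)^(1/(m−1)),
v_i  = Σ_j u_ij^m x_j / Σ_j u_ij^m.
```

`J_m` is non-convex, so the quality of the result depends on the
initial centers `V`. This package replaces random initialization with
an optimized one:

1. **Rough-set memory construction.** Candidate centers are iterated
   under a rough partition: a pixel whose second-nearest center is
   within a margin of its nearest one is a *boundary* point shared by
   both clusters' upper approximations; all others are certain (lower
   approximation) members. Centers update as
   `w_low · mean(lower) + (1 − w_low) · mean(boundary)` with
   `0.5 < w_low < 1`, and a K-nearest-neighbor majority vote finally
   resolves the boundary pixels. The converged centers (plus small
   seeded perturbations) form the harmony memory.
2. **Adaptive harmony search.** Starting from that memory, harmony
   search minimizes the within-cluster sum of squared distances
   `Σ_j min_i (x_j − v_i)²`. The pitch adjusting rate ramps linearly,
   `PAR(t) = PAR_min + (PAR_max − PAR_min)·t/T`, and the bandwidth
   follows a two-regime schedule driven by the best/worst-harmony
   feedback statistic `T = Σ|x_best − x_worst| / Σ(x_best − x_worst)²`,
   which also terminates the run once the memory collapses.
3. **FCM segmentation.** The optimized centers initialize FCM; the
   label map is the argmax membership per pixel. Partition coefficient
   `Vpc = (1/n) Σ u_ij²` and partition entropy
   `Vpe = −(1/n) Σ u_ij ln u_ij` score the partition (higher Vpc /
   lower Vpe = crisper segmentation), and Vpc drives automatic
   selection of the cluster count.

A seeded phantom generator (piecewise-constant tissue classes +
Gaussian noise + optional smooth multiplicative bias field, with
ground-truth labels) makes every stage testable without any image
downloads.

## Worked example

```python
import numpy as np
from harmonyseg import generate_phantom, compare, segmentation_accuracy

ph = generate_phantom(shape=(128, 128), class_means=(0.2, 0.5, 0.8),
                      class_stds=0.05, geometry="nested_disks", seed=7)
report = compare(ph.image, 3, seed=7)
for row in report.rows:
    print(row)
res = report.results["improved"]
print("centers:", np.round(np.sort(res.fcm_result.centers), 4))
print("accuracy:", segmentation_accuracy(res.label_map, ph.truth))
```

prints

```
{'algorithm': 'improved', 'vpc': 0.924516387547966, 'vpe': 0.16185956348955755, 'iterations': 4, 'fitness_best': 40.366967059306546, 'fitness_worst': 40.37406128738297, 'fitness_average': 40.36837107679096}
{'algorithm': 'baseline_fcm', 'vpc': 0.9245163428269656, 'vpe': 0.1618595907704605, 'iterations': 10, 'fitness_best': None, 'fitness_worst': None, 'fitness_average': None}
centers: [0.198  0.4997 0.8015]
accuracy: 0.99847412109375
```

The improved pipeline recovers the true class means (0.2/0.5/0.8) to
three decimals and labels 99.8% of pixels correctly. Its FCM stage
needs 4 iterations against 10 from a random start, its harmony memory's
best/worst/average fitness are tightly clustered near the optimum, and
its validity indices are (slightly) better — on this easy, well
separated phantom both initializations reach the same basin, and the
gap widens with harder intensity structure.

The same operations are available from the shell:

```sh
harmonyseg synth --shape 128x128 --means 0.2,0.5,0.8 --stds 0.05 \
    --seed 7 --out phantom.png --out-truth truth.png
harmonyseg segment phantom.png --clusters 3 --algorithm improved \
    --seed 7 --out-labels labels.png --out-report report.json
harmonyseg compare phantom.png --clusters 3 --seed 7 --out-csv cmp.csv
```

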