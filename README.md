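# twang

Fast seeded segmentation of fluorescently stained nuclei in 2D and 3D
microscopy images (e.g. light-sheet stacks of developing embryos), with
built-in quality metrics and a synthetic phantom generator for
self-contained validation.

## The method

Densely packed nuclei at low contrast defeat global thresholding: plain
Otsu merges touching nuclei. TWANG (*Threshold of Weighted intensity And
seed-Normal Gradient dot product image*) instead turns segmentation into
many small, independent, easy thresholding problems:

1. **Seed detection.** A scale-normalised Laplacian-of-Gaussian filter
   −σ²∇²(G_σ ∗ I) is evaluated over a discrete scale set
   {σ_min, σ_min+Δσ, …, σ_max} and folded iteratively into a per-voxel
   maximum image (the *scale-space MIP*) plus an argmax-scale image, so
   at most two response volumes are ever in memory. Seeds are the local
   maxima of the MIP over the 8/26-neighbourhood, above an intensity
   threshold, with close maxima fused (strongest response wins within a
   fusion radius). Each seed carries a radius estimate r = σ√d from its
   argmax scale. Filtering is isotropic in physical space: the per-axis
   voxel sigma is σ/h_a for spacing h_a, so anisotropic stacks are
   handled natively.
2. **Per-seed transform.** Around each seed a cuboid of half-width 2r is
   cropped. With n(x) the unit normal from the seed to voxel x (physical
   units) and g(x) the Gaussian-smoothed image gradient, the transformed
   dot product ψ(x) = (1 − ⟨n, g/‖g‖⟩)/2 ∈ [0,1] scores 1 on the seed's
   own boundary (inward-pointing gradients), 0.5 for flat or
   perpendicular regions, and 0 on the near edge of a neighbouring
   nucleus. A plateau-Gaussian kernel w(x) = 1 for ‖d‖ ≤ m·r, else
   exp(−(‖d‖−m·r)²/2σ_w²), down-weights distant voxels. The combined
   image copies raw intensities within r and multiplies the rest by
   w·ψ.
3. **Threshold and extract.** Otsu's method (256-bin between-class
   variance) on the combined crop separates the nucleus; the connected
   component containing the seed becomes the mask, and region properties
   (centroid, volume, mean intensity, bounding box) are read directly
   off the crop. Because every region belongs to exactly one seed, merged
   segments cannot occur by construction. Seeds are processed
   independently and can be distributed over workers with bit-identical
   results.

Quality of a segmentation against a reference labelling is reported as
Rand Index (%), pair-based Jaccard Index (unbounded), per-object
Hausdorff distance, Normalized Sum of Distances, and
split/merged/added/missing object counts.

## Worked example

```python
from twang import (PhantomSpec, TwangParams, generate_phantom,
                   detect_seeds_from_volume, segment_all,
                   assemble_label_image, evaluate)

# clustered low-SNR phantom: 20 nuclei, radius 6-9 px, 75% clustering
vol, truth = generate_phantom(PhantomSpec(rng_seed=1))
params = TwangParams(sigma_min=3.5, sigma_max=5.5, sigma_step=0.5,
                     seed_intensity_threshold=20.0)
seeds, _ = detect_seeds_from_volume(vol, params)
segments = segment_all(vol, seeds, params, workers=4)
labels = assemble_label_image(segments, vol.shape, vol.spacing, seeds)
report = evaluate(truth.labels, labels)
print(len(seeds), report.rand_index, report.n_merged, report.n_missing)
```

prints

```
20 99.4083527765576 0 0
```

— all 20 nuclei were found (one seed each), voxel-level agreement with
the ground truth is RI = 99.4%, and no nuclei were merged or missed
despite 75% of them touching a neighbour.

The same pipeline is available from the shell:

```sh
twang simulate --config phantom.yaml --image img.tif --labels truth.tif
twang pipeline --input img.tif --config params.yaml \
      --seeds seeds.csv --labels labels.tif --regionprops props.csv \
      --reference truth.tif
```

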