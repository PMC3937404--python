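# Methods

## Model and assumptions

The pipeline targets roundish, bright-on-dark objects (stained nuclei)
whose radii fall in a known, narrow range. Two assumptions carry all of
the structure:

* **Blob model.** A nucleus is approximately a ball of radius r; the
  σ²-normalised Laplacian-of-Gaussian response at its centre is maximal
  at σ = r/√d (d = image dimensionality), which is why seeds carry the
  radius estimate r = σ√d and why the scale set should bracket
  [r_min/√d, r_max/√d].
* **Boundary-gradient model.** On the boundary of a bright object the
  intensity gradient points inward. Relative to the outward unit normal
  from the seed, the seed's own boundary therefore scores
  ψ = (1 − cos θ)/2 ≈ 1, while the near edge of a neighbouring nucleus
  (gradient pointing away from the seed) scores ≈ 0. ψ depends only on
  gradient *direction*, so it is invariant under positive rescaling of
  the intensities; contrast differences between nuclei do not matter.

Strongly elongated objects violate the blob model: the spherical
weighting kernel clips their tips. Raising `kernel_multiplier` and
`kernel_sigma` mitigates this at the cost of weaker neighbour
suppression.

## Parameters

| name | meaning | default | unit |
|---|---|---|---|
| `sigma_min`, `sigma_max`, `sigma_step` | LoG scale range | 6, 9, 3 | physical length |
| `gradient_sigma` | smoothing before gradients | 3.0 | physical length |
| `kernel_multiplier` (m) | plateau radius scale | 1.5 | — |
| `kernel_sigma` (σ_w) | kernel falloff | 3.0 | physical length |
| `seed_intensity_threshold` | minimum MIP response | 0 | response units |
| `fusion_distance` | minimum seed separation | σ_min·√d | physical length |

All sigmas are physical lengths (equal to voxels under unit spacing);
per-axis voxel sigmas are obtained by dividing by the spacing, making
every filter isotropic in physical space. The defaults are the 3D
light-sheet parameterisation; 2D plate imagery with larger nuclei wants
roughly `sigma 8–11 step 1`.

`seed_intensity_threshold` defaults to 0 (keep every positive response),
which on noisy images admits spurious low-response maxima. The LoG
response of a real nucleus scales with its contrast (foreground minus
background); in all validation runs the threshold is set to ~10% of the
phantom contrast (20 for fg−bg = 180), which separates true seeds
(response ≳ 100) from noise maxima (≲ 1) by two orders of magnitude.
Region-property post-filters (volume, mean intensity) are available for
downstream false-positive pruning but default to off.

## Numerical choices

* **Kernels.** Gaussian and derivative-of-Gaussian kernels are sampled,
  truncated at 4σ, with mirror boundary handling. Truncated sampled
  kernels do not annihilate constants/ramps exactly, so the
  second-derivative kernel is corrected to zero sum and unit second
  moment, and the first-derivative kernel to unit first moment; constant
  and affine images then give exactly zero LoG response and exact ramp
  slopes.
* **Scale-space MIP.** Responses are folded one scale at a time
  (max/argmax), so at most two full response volumes are resident
  regardless of the number of scales. Ties go to the smaller scale.
* **Maxima.** Local maxima are taken over the full direct neighbourhood
  (8 in 2D, 26 in 3D) of the MIP only — not across scales. A voxel
  qualifies if ≥ all neighbours and > at least one; each connected
  plateau keeps its lexicographically first voxel. Fusion is greedy by
  descending response (position as the deterministic tie-break).
* **Otsu.** 256 bins over the crop's min–max range; candidate thresholds
  are the interior bin edges; foreground is `values > t`. Empty bins
  between well-separated classes create a plateau of analytically equal
  between-class variance, so the argmax takes the first edge within
  1e-10 relative tolerance of the maximum — deterministic and immune to
  last-ulp summation noise. A constant field is flagged degenerate and
  the seed discarded.
* **Degenerate seeds.** Flat crops, empty foregrounds, and seeds whose
  crop has no foreground component within the seed radius yield `None`
  (logged with a reason); one failing seed never aborts a batch.
* **Label assembly.** Overlapping masks are resolved per voxel by
  physical distance to the owning seed, ties to the smaller seed id —
  each labelled region maps to exactly one seed, which is what makes
  merged segments structurally impossible.

## Evaluation conventions

* RI and JI are pair-counting metrics over *all* voxels, with background
  as one block, computed from the label contingency table. JI here is
  the pair-based variant (agreeing/disagreeing pairs) and is not bounded
  above; identical inputs give JI = inf (written as "inf" in CSV).
* Object matching assigns each segmented object to the reference object
  of maximal overlap (ties to the smaller label); only segments with
  zero overlap with every reference object are "added". The
  majority-background alternative was rejected because it declares a
  one-voxel dilation of a small object unmatched, which breaks the NSD
  fixture semantics.
* Hausdorff and NSD are computed per matched object pair in physical
  coordinates and averaged over pairs to one scalar per image. NSD
  weights each voxel by its distance to the reference object's border;
  the computation is restricted to the pair's union bounding box, which
  is exact because the border (the distance source) lies inside it.
* Split: a reference object claimed by k ≥ 2 segments contributes k−1.
  Merged: by the dual assignment, a segment that is the maximal-overlap
  target of k ≥ 2 reference objects contributes k−1.

## The phantom generator

Phantoms emulate clustered roundish nuclei at low SNR on a possibly
anisotropic grid: spheres (disks in 2D) with radius uniform in a
configured range, placed by rejection sampling — with probability
`clustering_probability` at centre distance 0.8–1.2×(r_i+r_j) from a
random existing nucleus (touching/nearly touching), otherwise clear of
every nucleus by > 1.5×(r_i+r_j). Labels are rasterised *before* the
Gaussian PSF blur and additive Gaussian (optionally Poisson) noise, so
ground truth is the sharp geometry. Measured SNR
((mean fg − mean bg)/σ_bg) is recorded in the truth object.

Defaults describe the clustered benchmark regime: a 60×150×150 stack
with 20 nuclei of radius 6–9, clustering probability 0.75, fg/bg
200/20, PSF σ 1 and noise σ 20 (measured SNR ≈ 7–8). Validation runs
use desk-scale stacks (up to 256×256×50); the method itself is
streaming-friendly since each seed touches only its own crop.

What the phantoms do *not* model: intensity texture inside nuclei,
optical sectioning and depth-dependent blur, light scattering and
attenuation, mitotic shape changes, and imaging-border truncation.
Passing phantom tests therefore demonstrates the geometric and
statistical machinery (scale selection, neighbour suppression, zero
merging, metric correctness), not robustness to real-microscope
artefacts — on real stacks expect more missed seeds near borders and
false positives in degraded regions.

## Known limitations

* Seeded segmentation stands or falls with seed quality; a missed seed
  is a missed nucleus (no recovery stage).
* The elongated-object clipping noted above.
* Otsu within a crop assumes the combined image is bimodal; extremely
  low contrast (SNR ≲ 2) breaks this before it breaks seed detection.
* Label images export as 16-bit TIFF, capping a single stack at 65535
  segments.
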