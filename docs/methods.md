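# Methods

This note documents the models and procedures implemented in
`cytoquant`, the parameters that matter, the synthetic-data model used
for validation, and the numerical conventions that make every run
bit-reproducible.

## Pipeline model and assumptions

The pipeline assumes widefield, single-plane, co-registered grayscale
images of cytospun cells on a uniform background — the situation global
Otsu thresholding is suited to. Cytospun cells lose adherent morphology
but present uniformly rounded, well-separated nuclei; clumped nuclei
show a definite indentation at the contact. These properties justify
the two central modelling choices: a *shape* (distance-transform)
declumping strategy for nuclei, and circularity (FormFactor =
4π·Area/Perimeter², 1 for a perfect circle) as the discriminator for
burst nuclei and burst cell bodies.

Intensities are normalized to [0, 1] on load by dividing by the maximum
possible value of the source dtype (255 or 65535); floating-point
images must already be in [0, 1]. All intensity thresholds below are on
this scale.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| nucleus diameter gate | 16–60 | px | removes debris and aggregates |
| smoothing scale | 1.3488 | – | pre-threshold Gaussian; σ = scale/1.3488 = 1 px |
| threshold correction (DAPI) | 0.7 | – | multiplies the Otsu threshold (lenient) |
| threshold bounds | 0.0, 1.0 | – | clamp on the corrected threshold |
| nucleus min FormFactor | 0.599 | – | burst-nucleus exclusion |
| threshold correction (VIME) | 0.9 | – | secondary foreground |
| regularization λ | 0.1 | – | distance-vs-intensity balance in propagation |
| body min area | 28 | px² | intact-cell filter |
| body min FormFactor | 0.35 | – | intact-cell filter |
| body min VIME mean intensity | 9·10⁻⁶ | – | intact-cell filter |
| SOX10 / EdU thresholds | operator-set | – | marker positivity per cytospin |

Marker thresholds deliberately have no default: staining intensity
varies by run and donor, so the operator sets them per cytospin after
inspecting the per-nucleus mean intensities (the pipeline emits
annotated images for this). An optional Otsu split of the observed
means (`auto_suggest`) is provided as a convenience extension; it is
off by default.

## Numerical conventions

* **Otsu threshold.** 256 uniform bins over [0, 1] (not over the data
  range); exhaustive between-class-variance maximization; the threshold
  is the upper edge of the selected bin, foreground is strictly above
  it; the first bin wins exact ties. A single-valued image returns that
  value, yielding an empty foreground.
* **Declumping.** Euclidean distance transform smoothed with
  σ_d = max(1, min_diameter/7); σ_d suppresses sub-nuclear maxima at
  the configured size gate and is itself exposed as a parameter.
  Maxima are accepted greedily in descending value (ties by row-major
  order), discarding any maximum within min_diameter (Euclidean) of an
  accepted one. Dividing lines come from synchronous ring growing
  (8-connected, one layer per iteration; the lower label wins when two
  labels reach a pixel in the same iteration).
* **Hole filling.** Background components not 4-connected to the image
  border, filled per object after dividing lines are drawn; only pixels
  still background are claimed.
* **Perimeter.** Boundary-crossing estimator with isotropic correction
  weights (straight 1, diagonal √2, corner-corrected), computed per
  object on its own padded mask so touching objects do not share
  boundaries. Raw pixel-edge counting would bias disk FormFactor down
  to ~0.78 and corrupt the 0.599 cut-off semantics; with the default
  estimator rasterized disks of radius ≥ 10 px measure within 10% of 1
  (a Crofton-formula estimator is available as an alternative, and the
  cut-offs remain configurable because any estimator shifts them
  slightly). FormFactor is not clamped: small rasterized objects may
  slightly exceed 1. Perimeter is ≥ 1 by convention for 1–2 px objects.
* **Propagation cost.** Step cost from pixel p to 8-neighbour q is
  √((I(p)−I(q))² + λ·d²) with d ∈ {1, √2}; the assignment minimizes the
  accumulated path cost from any seed (exact Dijkstra). λ → large
  converges to the nearest-seed geodesic partition; λ = 0 follows
  intensity ridges. Ties break by lower seed label, then row-major
  pixel order. Seed pixels keep their label even below threshold;
  bodies touching the border are kept.
* **Threshold comparisons** use ≥ ("minimum value" semantics), so an
  object exactly at a cut-off passes.
* **Degenerate inputs.** A stage yielding zero objects short-circuits
  the rest of the run with zero counts and a warning flag on the rates
  (zero denominators report 0, not NaN); this is a valid outcome.
* **Statistics.** The automated-vs-manual comparison is a standard
  paired t-test, t = mean(d)/(sd(d)/√n), df = n−1, two-sided. Zero
  variance of the differences is handled explicitly (mean 0 → t = 0,
  p = 1; nonzero mean → p reported as 0).

## Synthetic-data model

The generator emulates exactly the features the pipeline keys on, with
exact ground truth:

* Nuclei are disks with smooth radial perturbation (±6%), radius
  16–19 px, DAPI level ~0.75 on a 0.02 background with additive
  Gaussian noise (σ = 0.01, clipped to [0, 1]).
* Burst nuclei are star polygons (4–7 spikes, inner/outer radius
  ratio 0.33, outer radius 0.85× the nucleus radius). The ratio was
  calibrated so that ≥ 95% of burst shapes measure FormFactor < 0.599
  both as drawn and after segmentation (smoothing plus the lenient 0.7
  correction dilates and rounds masks, so the drawn shapes need
  headroom below the cut-off).
* Cell bodies are larger perturbed disks (radius 22–27 px, VIME ~0.4)
  around every nucleus; burst bodies are spiky stars (7–9 spikes,
  ratio ≈ 0.48 with inner radius just outside the nucleus), which fail
  the 0.35 body-circularity filter. This realizes the "burst body"
  exclusion through the shape route; the printed VIME intensity cut-off
  (9·10⁻⁶) is far below any nonzero noise floor and only discriminates
  in truly zero-background images.
* Clumped pairs are placed at center distance 1.2–1.6× the mean radius,
  giving a shared-boundary indentation; with 16–19 px radii the
  distance-transform maxima stay ≥ 16 px apart, so the declumping's
  maxima suppression does not merge the pair.
* Border-touching nuclei are centred within (radius − 3) px of an edge.
* Marker rendering: SOX10 ~0.72 inside SOX10⁺ nuclei (0.03 inside
  negatives), EdU ~0.78 / 0.015; EdU⁺ cells are drawn only within the
  SOX10⁺ subset. Separation far exceeds 5× the noise sd, so a 0.3
  threshold classifies perfectly — synthetic runs therefore use
  sox10/edu thresholds of 0.3.
* Marker counts are assigned exactly (round(frac·n) via permutation),
  so an undegraded 100-cell image has ground truth (100, 70, 35).

Placement is random-sequential with non-overlap constraints (except
within clumped pairs) and bounded retries; a single NumPy generator
seeded once per call drives every stochastic choice in a fixed order,
making output bit-identical for identical spec + seed.

What the synthetic model does *not* emulate: illumination gradients and
shading (the pipeline's global threshold assumes a uniform background),
point-spread blur, chromatic misregistration, intensity correlation
between markers, partial marker overlap distributions, debris, and
mitotic-figure morphology. Passing the recovery tests therefore shows
the pipeline's stages implement their contracts and compose correctly
under the stated phenomenology — not that the specific default filter
values are optimal for any particular microscope's real images, where
the operator-set thresholds and (if needed) correction factors must
still be tuned.

## Problem sizes used in validation

Synthetic validation uses 1024×1024 px images with 100 cells
(≈25% packing of cell bodies), 20 seeds for the recovery property and
6 images in the acceptance script; propagation-oracle equivalence is
checked exhaustively on ≤ 64×64 images with ≤ 5 seeds for
λ ∈ {0, 0.1, 1}, and the Otsu oracle on 100 random 64×64 images. At
these sizes recovered counts match ground truth within 1 cell and
purity/proliferation within 1 percentage point per image (typically
exactly).

## Design choices where the design was open

* The proliferation-rate denominator is real cells by default (reading
  "percentage of SOX10⁺/EdU⁺ real cells" literally); SOX10⁺ cells is
  available via `proliferation_denominator` since "SC proliferation
  rate" admits that reading too.
* The distance-map smoothing formula for declumping is not uniquely
  determined by the requirement that it scale with the object diameter;
  max(1, min_diameter/7) is documented and configurable.
* The propagation cost functional is one concrete realization of the
  two required limiting behaviours (λ small →
  intensity-dominated borders, λ large → distance-dominated); the exact
  functional is stated above and in the module docstring.
* EdU intensity is measured on all real nuclei, but positivity is only
  asserted within SOX10⁺, preserving the nesting
  EdU⁺ ⊆ SOX10⁺ ⊆ real cells by construction.

## Known limitations

* Only single-plane 2-D TIFF/PNG inputs; no proprietary microscope
  formats, z-stacks, illumination correction or channel registration.
* The exact Dijkstra propagation is implemented in pure Python/NumPy;
  a 1024×1024 image with ~200k foreground pixels takes a few seconds.
* More than 65535 objects cannot be written to 16-bit label TIFFs.
* Adaptive/local thresholding and intensity- or Laplacian-based
  declumping variants are out of scope by design.
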