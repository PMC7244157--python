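# cytoquant

Automated quantification of Schwann-cell (SC) culture purity and
proliferation from four-channel cytospin immunofluorescence images.

Primary SC cultures isolated from peripheral nerve are invariably
contaminated by fibroblasts, so every culture used for experimentation
must demonstrate its purity, and the proliferation status is a key
read-out of culture condition. Cytospins — cells centrifuged onto a
microscope slide — allow this to be measured from an aliquot of only
~10⁴ cells, stained for the nuclear SC marker SOX10, the proliferation
marker EdU, the cell-body intermediate filament vimentin (VIME) and the
DNA stain DAPI. `cytoquant` replaces the manual counting of such images
with a deterministic analysis pipeline, and ships a synthetic cytospin
generator with exact ground truth so every stage is testable without any
image download.

## Method

Per image, the pipeline runs these stages in order:

1. **Nucleus segmentation (DAPI).** Global two-class Otsu threshold
   (256-bin histogram on [0, 1]) of the smoothed image
   (smoothing scale 1.3488 ≙ σ = 1 px), scaled by a correction factor of
   0.7. Touching nuclei are split by *shape-based declumping*: local
   maxima of the smoothed Euclidean distance transform (minimum mutual
   separation = the 16 px minimum object diameter) seed a synchronous
   ring propagation that draws the dividing lines. Objects outside the
   16–60 px equivalent-diameter gate or cut by the image border are
   removed, holes are filled.
2. **Burst-nucleus filter.** Circularity
   FormFactor = 4π·Area/Perimeter² (1 for a perfect circle) is measured
   per nucleus; *real nuclei* require FormFactor ≥ 0.599.
3. **Marker classification.** Mean SOX10 and EdU intensity per real
   nucleus; SOX10⁺ (SC) and, within SOX10⁺ only, EdU⁺ (proliferating SC)
   via operator-set thresholds (`--sox10-threshold`, `--edu-threshold`;
   annotated intensity images support the choice, and an Otsu-based
   suggestion is available via `--auto-suggest`).
4. **Cell-body segmentation (VIME).** Seeded propagation from the real
   nuclei over the VIME foreground (Otsu × 0.9): each foreground pixel
   joins the seed minimizing the accumulated 8-connected path cost
   √(ΔI² + λ·d²), with regularization factor λ = 0.1 balancing
   intensity-gradient against distance-based borders.
5. **Intact-cell filter.** A cell body must satisfy Area ≥ 28 px²,
   FormFactor ≥ 0.35 and VIME mean intensity ≥ 9·10⁻⁶; *real cells* are
   real nuclei with a surviving body.
6. **Counts and rates.** Purity = 100 · SOX10⁺ real cells / real cells;
   proliferation = 100 · SOX10⁺/EdU⁺ real cells / real cells (the
   denominator is configurable). Results export as tab-delimited `.txt`
   plus a CSV twin, with red/green classification overlays and
   count-annotated images.

A paired t-test (`cytoquant compare`) reproduces the automated-vs-manual
validation analysis.

## Worked example

Simulate a degraded cytospin (100 cells, 70% SOX10⁺, half of those EdU⁺,
10% burst nuclei, 10% burst cell bodies, 10% clumped pairs, 5% cut by
the border), then analyse it:

```bash
cat > study.yaml <<EOF
frac_burst_nuclei: 0.1
frac_burst_bodies: 0.1
frac_clumped_pairs: 0.1
frac_border_touching: 0.05
EOF
cytoquant simulate --spec study.yaml --seed 1 --out fx
# ground truth: real cells 75, SCs 50, proliferating 26

cytoquant run --dapi fx/dapi.tif --sox10 fx/sox10.tif \
    --edu fx/edu.tif --vime fx/vime.tif --out out \
    --sox10-threshold 0.3 --edu-threshold 0.3
```

which prints:

```
DAPI effective threshold 0.2570; foreground 91872 px
primary objects: 100 declumped -> 95 after diameter/border gate
real nuclei after FormFactor >= 0.599: 85
SOX10+ nuclei: 59; SOX10+/EdU+ nuclei: 29
intact cell bodies: 75 of 85
real cells: 75  SCs: 50  proliferating SCs: 26
purity: 66.7%  proliferation: 34.7%
```

Reading the trail: all 100 nuclei are found and the 5 border-touching
ones are dropped by the gate; the 10 burst nuclei fail the 0.599
circularity filter; the 10 burst cell bodies fail the body filters. The
recovered counts (75 real cells, 50 SCs, 26 proliferating SCs) match the
generator's ground truth exactly, giving 66.7% culture purity and a
34.7% proliferation rate.

The same works from Python:

```python
from cytoquant import PipelineConfig, MarkerThresholds, SyntheticSpec, generate, run_pipeline

spec = SyntheticSpec(frac_burst_nuclei=0.1, frac_burst_bodies=0.1,
                     frac_clumped_pairs=0.1, frac_border_touching=0.05, rng_seed=1)
image, truth = generate(spec)
config = PipelineConfig(markers=MarkerThresholds(0.3, 0.3))
report = run_pipeline(image, config).report
print(report.n_real_cells, report.purity_pct)   # 75 66.66666666666667
```

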