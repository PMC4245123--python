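# vesiclepop

Population-scale morphometry of giant unilamellar lipid vesicles (GUVs) from
large-scale light video microscopy.

GUVs (cell-sized, 1–50 µm lipid vesicles) are routinely studied one at a time
under a light microscope, or in bulk by flow cytometry / dynamic light
scattering — which lose all shape information. An intermediate approach
records long, manually guided video tracks across a perfusion chamber,
stitches the ~3000 frames of each track into a single mosaic
(~20 000 × 762 px at 0.25 µm/px), segments every vesicle in the mosaic, and
reports per-vesicle morphometry for thousands of vesicles per sample, so
repeatable population statistics can be compared over incubation time or
between treated and control populations.

`vesiclepop` implements that computational pipeline end to end, plus a seeded
synthetic micrograph generator so every stage is testable without microscopy
data:

- **synthgen** — synthetic populations (truncated lognormal diameters,
  near-circular harmonic contours with a calibrated mean isoperimetric
  quotient, Stokes sedimentation), bright-field frame rendering with
  ground-truth label masks, camera tracks with 1-D jittered motion, and
  crystallized-lipid distractor blobs.
- **mosaic** — phase-correlation shift estimation with subpixel refinement,
  duplicate-frame dropping, feathered compositing of a track into one mosaic.
- **segmentation** — ring-evidence extraction, binary Markov-random-field
  labeling (Potts prior, ICM), contour closing + hole filling, physical
  filtering rules, and a file-based expert correction workflow
  (delete / add / merge / split edits).
- **morphometry** — subpixel contours; per vesicle the effective diameter
  and the isoperimetric quotient.
- **popstats** — per-chamber summaries, across-chamber repeatability (RSD),
  settling trend ratios, lognormal fits, histograms, box statistics.
- **pipeline / CLI** — `vesiclepop simulate|stitch|segment|measure|summarize|compare|run`.

## The two measurements

For each segmented vesicle cross-section with area $A$ and perimeter $P$
(both computed from the same subpixel contour polygon):

- **effective diameter** $d = 2\sqrt{A/\pi}$, reported in µm — the diameter
  of the circle with the same projected area;
- **isoperimetric quotient** $\mathrm{IPQ} = 4\pi A / P^2$ — a roundness
  measure that is 1 for a perfect circle and decreases toward 0 as the
  contour departs from circularity.

Perimeter estimation is the critical numerical step: counting boundary pixel
edges would inflate a disk's perimeter by ≈ 4/π and cap circular IPQ near
0.785. `vesiclepop` instead traces the 0.5 level set of the smoothed object
indicator and smooths the vertex chain adaptively, so a rasterized disk of
radius 200 px measures IPQ 0.999.

Chamber-to-chamber repeatability is quantified by the relative standard
deviation $\mathrm{RSD} = 100\,\sigma/\mu$ across chamber means, reported as
integer percent.

## Worked example

Four simulated chambers filled from the same kind of population, recorded at
30 minutes of incubation, segmented and aggregated:

```python
from vesiclepop.morphometry import measure_sample
from vesiclepop.popstats import fit_lognormal, summarize_population, summarize_sample
from vesiclepop.segmentation import segment_mosaic
from vesiclepop.synthgen import (
    PopulationParams, RenderParams, render_frame, sample_population, visible_at,
)

summaries = []
for chamber in range(4):
    params = PopulationParams(n_vesicles=260, chamber_um=(1200.0, 190.5), seed=40 + chamber)
    population = sample_population(params)
    visible = visible_at(population, time_min=30.0)
    scene = render_frame(visible, (0.0, 0.0), RenderParams(frame_shape=(4800, 762), seed=chamber))
    label_mask, report = segment_mosaic(scene.image, pixel_size_um=0.25)
    records = measure_sample(label_mask)
    summaries.append(summarize_sample(records, time_min=30.0, sample_id=f"C{chamber + 1}"))

pop = summarize_population(summaries)
print(f"chambers:        {pop.n_chambers}")
print(f"quantity:        {pop.quantity_mean:.0f} +/- {pop.quantity_std:.0f}  (RSD {pop.quantity_rsd_pct}%)")
print(f"mean diameter:   {pop.diameter_mean_um:.1f} +/- {pop.diameter_std_um:.1f} um  (RSD {pop.diameter_rsd_pct}%)")
print(f"mean IPQ:        {pop.ipq_mean:.2f} +/- {pop.ipq_std:.2f}  (RSD {pop.ipq_rsd_pct}%)")
mu, sigma = fit_lognormal([r.diameter_um for r in records])
print(f"lognormal fit:   mu = {mu:.2f} (ln um), sigma = {sigma:.2f}")
```

prints

```
chambers:        4
quantity:        198 +/- 4  (RSD 2%)
mean diameter:   9.0 +/- 0.3 um  (RSD 3%)
mean IPQ:        0.95 +/- 0.00  (RSD 0%)
lognormal fit:   mu = 2.05 (ln um), sigma = 0.54
```

Reading the numbers: the four chambers agree to within a few percent (the
repeatability the method is built for — quantity RSD stays below 8% and IPQ
RSD at or below 2% in practice); the vesicles visible after 30 minutes are
larger on average (9.0 µm) than the full generated population (median
6.5 µm) because heavier, sucrose-filled vesicles sediment into the focal
plane first; and the visible-sample lognormal fit is correspondingly shifted
(µ = 2.05 vs. the generator's ln 6.5 ≈ 1.87).

The same stages are available from the shell:

```bash
vesiclepop simulate --output sim --n-vesicles 120 --n-frames 60 --time-min 30 --seed 7
vesiclepop stitch   --input sim/frames --output mosaic.tif
vesiclepop segment  --input mosaic.tif --output mask.tif
vesiclepop measure  --mask mask.tif --output vesicles.csv --sample-id C1
```

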