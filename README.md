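# sloquant

Semi-automated quantification of GFP-labeled myeloid cells (microglia and
infiltrating monocytes) in confocal scanning laser ophthalmoscopy (cSLO)
fundus images of the mouse retina.

In CX3CR1-GFP reporter mice the retinal myeloid compartment fluoresces in
blue-autofluorescence fundus imaging, so microglial activation — e.g. during
experimental autoimmune encephalomyelitis (EAE), a model of multiple
sclerosis — can be tracked *in vivo*, longitudinally, without histology.
`sloquant` implements the two-stage analysis protocol that turns one fundus
frame into per-cell and per-image numbers, plus the statistical layer that
turns a cohort of such numbers into a diagnostic score:

1. **Mask creation** — rolling-ball background subtraction (radius 500 px,
   grayscale opening with a ball-top structuring element), FFT bandpass
   between 3 px and 30 px (difference-of-Gaussians transfer function), then
   an adjustable intensity threshold. The threshold is auto-suggested from
   the histogram and may be overridden per image; whichever is used, it is
   serialized, so the segmentation criterion stays auditable.
2. **Measurement** — the binary mask is superimposed on the *original*
   frame; every particle is measured (area, min/max/mean brightness,
   equivalent-circle diameter, maximum Feret diameter) and summarized into
   five per-image readouts:

   | readout | definition |
   |---|---|
   | CC  | cell count |
   | SuA | sum of all cell areas (px) |
   | MVI | mean over cells of per-cell mean brightness |
   | MCB | mean over cells of per-cell maximum brightness |
   | AvA | average cell area, SuA / CC |

3. **Scoring** — each readout is standardized to a Z-score within a week
   stratum, z(x) = (x − x̄)/s; the composite score is the unweighted mean
   of the component Z-scores (CC and SuA by default). Discrimination of
   immunized vs control animals is quantified by an ROC whose AUC equals
   the Mann–Whitney pair probability (ties ½), and a cut-off is chosen from
   the candidate table (balanced sensitivity/specificity, Youden, or
   floor strategies).

A seeded synthetic-image generator (`sloquant.synth`) renders fundus-like
frames — noisy vignetted background, dark vessel streaks, Gaussian-blob
somata with known positions and areas — and full longitudinal cohorts with
an activation bump peaking at week 6, so the whole pipeline is testable
against planted ground truth.

## Worked example

```python
from sloquant import (SynthImageParams, generate_image, run_protocol,
                      ProtocolConfig)

params = SynthImageParams.high_snr(seed=7)          # 512x512, 50 planted somata
frame, truth = generate_image(params)
result = run_protocol(frame, ProtocolConfig(min_area_px=10))
s = result.summary
print(f"planted cells:   {truth.count}  (total soma area {truth.total_area_px} px)")
print(f"measured CC:     {s.cc}")
print(f"measured SuA:    {s.sua_px:.0f} px")
print(f"auto threshold:  {result.threshold.lo:.2f} (origin={result.threshold.origin})")
```

prints

```
planted cells:   50  (total soma area 1519 px)
measured CC:     50
measured SuA:    1493 px
auto threshold:  6.38 (origin=auto)
```

All 50 planted somata are recovered and the segmented area is within 2% of
the planted area; the automatically suggested threshold (triangle method
with a robust noise floor) sits just above the background speckle, which is
where a blinded evaluator would place it.

The same pipeline runs from the shell over a whole cohort:

```bash
sloquant simulate cohort --seed 2 --out cohort/         # frames + manifest + truth
sloquant run --manifest cohort/manifest.csv --out-dir results/
sloquant score --table results/cohort.csv --week 6 --out-dir scored/
sloquant validate --auto results/cohort.csv --manual manual_counts.csv --out report.json
```

`score` writes the per-row composite table, ROC curves, the full
cut-off/sensitivity/specificity table per score, and a JSON report.

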