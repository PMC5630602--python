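# filaquant

Quantification of filamentous structure in endothelial-matrix biology:
per-pixel **correlation-length mapping** of fibronectin fibre networks
(fluorescence) and capillary-like cord networks (phase contrast), plus
cell-trajectory motility statistics (speed and persistence length) and
the small statistical utilities that accompany such experiments
(unpaired t-tests with the star convention, ΔΔCt fold changes).

It is aimed at groups running matrix-assembly and tube-formation assays
who need a reproducible, scriptable replacement for one-off GUI tools:
everything is a library call or a CLI subcommand, every run stores its
exact configuration, and a synthetic-data module provides ground-truthed
images and trajectories so the whole pipeline can be validated without
any experimental data.

## The method

The image *I(x, y)* is matched against a bank of oriented line kernels —
anti-aliased straight capsules of length *L* (µm) and orientation *θ* ∈
[0°, 180°), optionally blurred to the data's optical resolution. For
each placement the **zero-normalised cross-correlation** (ZNCC) is
computed over the kernel's own footprint (the capsule plus a small
background margin):

    Corr(x, y, L, θ) = ⟨ I − mean(I) , K_{L,θ} ⟩ / ‖ I − mean(I) ‖ ∈ [−1, 1]

with means and norms taken over the footprint, so the score is invariant
to local brightness and contrast and insensitive to unrelated structures
outside the footprint. A placement *passes* when its best-over-θ score
reaches a threshold τ; the per-pixel **maximum correlation length**

    Lmax(x, y) = max { L : some passing L-kernel placement covers (x, y) }

is 0 where nothing passes. A mask *M(x, y)* combines detection with the
rescaled image intensity, and the map is rendered in HSV — hue encodes
Lmax from blue (short) to red (long), value is *M*. τ is calibrated on
noise-free single-fibre probe images so that the modal recovered length
matches the true probe length.

Phase-contrast images are first reduced to a **local contrast map**
(windowed standard deviation, noise-floor subtracted and percentile
normalised) and then analysed with a cord-scale kernel bank, so the 300
µm cord statistic of tube-formation assays is computed the same way as
the 25 µm fibre statistic.

Cell tracks (CSV: `track_id,frame,t_s,x_um,y_um`) are summarised per
track by mean speed (µm/h) and by persistence length: the contour-length
decay constant of the tangent-direction autocorrelation, fitted
log-linearly. For a persistent random walk with step *d* and Gaussian
turning noise σ the theoretical value is ξ = 2d/σ².

## Worked example

```python
import numpy as np
import filaquant as fq
from filaquant import synthetic as syn

# ground-truthed two-population fibre field: 40 segments, 15 vs 60 um
spec = fq.FibreFieldSpec(
    n_segments=40,
    length_sampler=syn.choice([15.0, 60.0]),
    seed=7,
)
image, truth, label = fq.generate_fibre_field(spec)

bank = fq.build_kernel_bank(
    lengths_um=np.arange(10.0, 81.0, 10.0),
    orientations_deg=np.arange(0.0, 180.0, 5.0),
    width_px=3.0, pixel_size_um=0.5, blur_px=1.0,
)
stack = fq.correlate(image, bank)
lmap = fq.length_map(stack, image, tau=0.85)
dist = fq.length_distribution(lmap)

measured = fq.fraction_below(dist, 25.0)
expected = syn.label_fraction_below(label, 25.0)
print(f"fraction of fibre signal below 25 um: {measured:.3f}")
print(f"ground-truth pixel fraction:          {expected:.3f}")
```

prints

```
fraction of fibre signal below 25 um: 0.122
ground-truth pixel fraction:          0.142
```

i.e. the detector recovers the short-fibre share of this mixed field to
within a few percent of the rendered ground truth. `fq.render_hsv(lmap,
(10, 80))` produces the colour-coded image, and
`fq.compare_conditions(a, b)` the starred t-test between two conditions.

The same workflows are available from the shell:

```bash
filaquant simulate-fibres --n-segments 40 --lengths 15,60 --seed 7 --out sim/
filaquant fibres sim/fibres.tif --lengths-um 10,20,30,40,50,60,70,80 \
    --tau 0.85 --pixel-size-um 0.5 --out analysis/
filaquant compare analysis_ctrl/ analysis_treated/
```

Each output directory contains the resolved `config.json`, per-image
`*_lmax.tif` / `*_mask.tif` / `*_hsv.png`, distribution CSVs and a
`report.json`; re-running from the stored config reproduces every
numeric output byte-for-byte.

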