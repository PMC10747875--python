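# micromix

Quantification of mixing performance in microfluidic mixers from images.

Passive micromixers homogenize co-flowing laminar streams, and their
performance is usually scored from a micrograph of the observation zone.
`micromix` implements the two complementary routes used in practice, for
people who design or characterize such devices:

* **Concentration-field route** (dye experiments): pixel intensities inside a
  region of interest are mapped linearly to concentrations `C ∈ [0, 1]` and
  summarized by the intensity of segregation — standard deviation σ
  (population), coefficient of variation `CoV = σ/Cm`, mixing index
  `M = 1 − CoV`, and Danckwerts' `I = σ²/(Cm(1 − Cm))` — by the scale of
  segregation, read off the variogram
  `γ(h) = 1/(2N(h)) Σ (Cˢ(x) − Cˢ(x+h))²` of the standardized field as the
  lag where γ first reaches the unit sill (mean horizontal/vertical length
  scales LH, LV), and by the exposure E, the summed concentration difference
  across 4-neighbour cell interfaces.

* **Particle-tracking route** (fluorescent-bead experiments): an HSV color
  mask, morphological opening and 8-connectivity blob detection turn a
  micrograph into sub-pixel bead centroids; the point pattern is scored by
  the quadrant-count CoV, the point-to-nearest-neighbour (PNN) distance
  distribution, its variance-to-mean ratio `Idisp`, the filtered
  point–particle deviation `σ_fpp` (root mean squared excess of PNN
  distances over the homogeneous-grid spacing `X_R = √(A/P)`), and the
  maximum striation thickness.

For devices with more than two inlets, a single dye CoV cannot resolve
per-reagent mixing, so each bead color is compared against its own unmixed
inlet state through the **normalized particle mixing index**

```
m_p = 1 − (Idisp/Idisp₀ + SR/SR₀ + σ_fpp/σ_fpp₀) / 3
```

where the subscript 0 marks the unmixed reference: `m_p = 0` for the unmixed
state itself and grows toward 1 as all three statistics shrink relative to
it (SR defaults to the mean PNN distance and may be overridden).

A synthetic-data module generates concentration fields (binary half/half,
lamellae, uniform, noisy), particle patterns (CSR, jittered grids, Thomas
clusters, striations, a half-segregated inlet state) and rendered
fluorescent-bead images with ground-truth centroids, so the whole pipeline
is testable without a microscope.

## Worked example

```python
import numpy as np
from micromix import *

# render 40 fluorescent beads and detect them again
spec = PatternSpec(kind="csr", width=256, height=256, count=40, min_separation=12)
ps = gen_points(spec, seed=7)
truth = ParticleSet(0.92 * ps.positions + 10, 256, 256)
image, gt = render_image(truth, RenderSpec(radius=3, color=(230, 25, 25), noise_sigma=4.0), seed=8)
detected = detect_particles(image, cfg=DetectionConfig(color="red"))
print("detected", detected.count, "of", truth.count)

s = summarize(detected, grid=(4, 4))
print(f"Idisp={s.idisp:.3f}  SR={s.sr:.3f}  sigma_fpp={s.sigma_fpp:.3f}  MST={s.mst:.0f}  CoV={s.cov:.3f}")

# the mixing index from published unmixed/mixed statistic triples
ref = SegregationSummary(idisp=529.6032, sr=64.2695, sigma_fpp=356.1561)
cur = SegregationSummary(idisp=348.1996, sr=42.2825, sigma_fpp=239.5713)
r = mixing_index_particles(cur, ref)
print(f"mp={r.mp:.7f}  ratios={tuple(round(x, 4) for x in r.ratios)}")

# a perfectly segregated binary concentration field
f = gen_field("half_half", (64, 64))
st = intensity_stats(f)
print(f"Cm={st.cm:.3f} M={st.mixing_index:.3f} I={st.intensity:.3f} E={exposure(f):.1f}")
```

prints

```
detected 40 of 40
Idisp=2.197  SR=25.013  sigma_fpp=1.078  MST=3  CoV=0.386
mp=0.3373252  ratios=(0.6575, 0.6579, 0.6727)
Cm=0.500 M=0.000 I=1.000 E=64.0
```

All 40 rendered beads are recovered; the detected pattern is random-like
(quadrant CoV 0.39, Idisp near the Poisson baseline).  The red-bead mixing
index 0.337 means the three segregation statistics dropped to about two
thirds of their unmixed-inlet values.  The binary half/half field is the
fully segregated limit: mixing index M = 0, Danckwerts intensity I = 1, and
an exposure of 64 — one unit interface per column of the 64-wide grid.

The same workflows are available from the shell:

```
micromix simulate points --spec spec.yaml --seed 3 --out beads.csv
micromix detect --image zone.png --roi 10,20,400,600 --color red --out particles.csv
micromix particles --positions particles.csv --area 600x400 --grid 8x8 --out mixed.json
micromix mp --current mixed.json --reference inlet.json --out mp.json
```

## Documentation

`docs/methods.md` describes the statistical model behind every metric, the
synthetic generators and their defaults, numerical conventions and known
limitations.
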