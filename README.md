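# fretkin

Quantification pipeline for **FRET-based ATP biosensor time-lapses** of
epithelial tissue, built around live imaging of the *Drosophila* wing-disc
pouch expressing the AT1.03NL sensor. When ATP production is acutely
inhibited (e.g. antimycin A blocking oxidative phosphorylation), the
sensor's FRET efficiency declines from its resting plateau toward a fixed
sensor floor; the spatial pattern of the decline's kinetics reports which
tissue regions can compensate metabolically. `fretkin` turns raw
two-channel stacks into per-region kinetic parameters and their
statistical comparisons, and ships a ground-truth synthetic scene
generator so every stage is testable by round trip and parameter recovery.

## The model

**Per-pixel efficiency.** With donor image I_D and FRET-channel image I_F
(both 5×5-smoothed and background-subtracted) and donor bleedthrough
fraction β calibrated from a donor-only specimen (β = I_bth / I_D):

    I_FRET = I_F − β·I_D          η = I_FRET / (I_D + I_FRET)

**Decay kinetics.** Post-inhibition region traces of mean η are fit with a
constrained four-parameter logistic

    f(t) = base + (max − base) / (1 + (t½ / t)^n)

with *base* fixed at 0.2827 (the mean − 2 SD efficiency of the
ATP-insensitive AT1.03RK construct), *max* ≤ 0.7, half-life t½ in minutes
and Hill coefficient n (negative for decay; more negative = steeper
transition). t½ and n are the quantities compared across regions
(organizer boundary stripes vs the rest of the pouch; dorsal vs ventral
compartments), with Kruskal–Wallis / Mann–Whitney / t-tests and a
Gardner–Altman-style estimation difference.

## Worked example

Simulate a pouch whose organizer stripes lose ATP more slowly
(t½ = 45 min) than the surrounding tissue (30 min), run the full
analysis, and recover the generating parameters:

```python
import numpy as np
from fretkin import (SceneSpec, build_pouch_labels, make_ground_truth,
                     render_frames, CorrectionConfig, compute_efficiency,
                     organizer_traces, make_roi_scheme, FitConfig, fit_cohort)

spec = SceneSpec(height_px=96, width_px=96, pixel_size_um=1.0,
                 n_frames=80, drug_time_min=10.0, noise_sigma=2.0, seed=0)
labels = build_pouch_labels(spec)
truth = make_ground_truth(spec, labels)          # organizer t1/2 45 min, rest 30 min
raw = render_frames(spec, truth)

cfg = CorrectionConfig(beta=spec.beta, bg_donor=spec.bg_donor, bg_fret=spec.bg_fret)
eta = compute_efficiency(raw, cfg)               # 5x5 smoothing, correction, ratio

scheme = make_roi_scheme((48, 48), ap_direction=(1, 0), dv_direction=(0, 1),
                         pixel_size_um=1.0, image_shape=(96, 96),
                         diameter_um=12.0, spacing_um=18.0)
traces = organizer_traces(eta, scheme)
fits = fit_cohort(list(traces.values()), FitConfig(drug_time_min=10.0))
print(fits[fits.disc_id != "mean"][["region", "max_eta", "t_half_min", "hill", "converged"]]
      .round(3).to_string(index=False))
```

prints

```
region  max_eta  t_half_min  hill  converged
   APB      0.6      44.999  -2.3       True
   DVB      0.6      44.999  -2.3       True
   ORG      0.6      45.000  -2.3       True
    NO      0.6      29.999  -2.3       True
```

i.e. despite pixel noise and the 5×5 smoothing, the fitted half-lives of
the boundary regions (APB/DVB/ORG) and the non-organizer quadrants (NO)
recover the generating 45 vs 30 min to a fraction of a percent, the
plateau comes back at 0.6 and the Hill coefficient at −2.3.

The same stages are available as a CLI for file-based workflows:
`fretkin simulate | bleedthrough | efficiency | traces | fit | compare |
pipeline` (TIFF stacks in, CSV/TSV tables out; see `fretkin --help`).

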