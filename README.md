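# segcomplexity

Image-complexity measures and resampling audits for medical image
segmentation design.

Training segmentation networks at native resolution is often infeasible,
so practitioners downsample their images or shrink their networks — but
how much can a given dataset tolerate?  The answer depends on how much
fine spatial structure the annotations carry: retinal vessel masks fall
apart under 4× downsampling while optic-disc masks barely notice.
`segcomplexity` turns that intuition into numbers, for anyone choosing
input resolution or macro-level architecture (deep vs. shallow,
large-size vs. lightweight) for a new segmentation dataset.

The toolkit provides:

* **Four complexity measures** per image/mask or per dataset:
  * *delentropy* `DE = -(1/2) Σ p_ij log2 p_ij`, the entropy of the joint
    gradient histogram (deldensity) — sensitive to spatial structure, not
    just intensity statistics;
  * *mean frequency* `MNF = Σ f_i P_i / Σ P_i` and *median frequency*
    `MDF` (the half-power frequency) of the power spectrum
    `P_i = |F_i|²`, in cycles/sample on [0, 0.5];
  * *perimetric complexity* `PC = P²/(4πA)` of a binary mask (1 for a
    disk, hundreds for thin branching shapes).
* **A degradation audit**: low-pass at the resampling Nyquist → bilinear
  downsample by factor f → bilinear upsample → Dice-optimal rethreshold →
  seven metrics (Se, Sp, A, BA, Dice, Jaccard, overlap error E = 1 − J)
  against the original mask.
* **Regression and model selection**: polynomial fits of E against any
  measure with R², adjusted R², RMSE, MAE, `AIC = n ln(RSS/n) + 2k` and
  `AICc = AIC + (2k²+2k)/(n−k−1)`; degree sweeps select by AICc.
* **A design advisor** mapping (complexity, resolution) to one of four
  macro-level network categories plus the maximum acceptable downsampling
  factor at an error tolerance.
* **Seeded synthetic fixtures** (blob masks, branching vessel masks,
  power-law textures) and a packaged ten-dataset reference table, so
  everything runs without downloading imaging data.

See `docs/methods.md` for definitions, conventions and limitations.

## Worked example

```python
import numpy as np
from segcomplexity import (
    make_vessel_mask, make_spectral_image, dataset_profile,
    degradation_audit, recommend_design, rank_measures, load_reference_table,
)

# a synthetic "dataset": textured images with vessel-style annotations
images = [make_spectral_image((256, 256), beta=1.0, seed=s) for s in range(4)]
masks = [make_vessel_mask((256, 256), seed=s) for s in range(4)]

profile = dataset_profile(zip(images, masks))
print({k: round(v, 4) for k, v in profile.as_dict().items()})
# {'de': 6.778, 'mnf': 0.2017, 'mdf': 0.1904, 'pc': 277.2494, 'n_images': 4}

audit = degradation_audit(masks, factors=(2, 3, 4))
print(audit.round(4))
#             se      sp       a      ba    dice  jaccard   error
# factor
# 2       0.8891  0.9902  0.9868  0.9397  0.8197   0.6949  0.3051
# 3       0.6658  0.9936  0.9825  0.8297  0.7198   0.5640  0.4360
# 4       0.6797  0.9862  0.9758  0.8329  0.6532   0.4859  0.5141

rec = recommend_design(profile, resolution=(256, 256), audit=audit)
print(rec.category, rec.max_downsampling)
# shallow large-size 1
```

Reading the output: MDF = 0.19 cycles/sample marks this as a
high-complexity dataset (vessel-like annotations), and the audit shows
why — even 2× downsampling already destroys 31% of the annotation overlap
(E = 0.3051), rising to 51% at 4×.  The advisor therefore recommends a
shallow network on full-resolution input (`max_downsampling = 1` at the
default 5% error tolerance); the large-size choice follows from the low
resolution (0.07 MP < 1 MP).  A blob-style dataset run through the same
pipeline keeps E below 0.6% even at 4× and is recommended a deep network
on downsampled input instead.

On the packaged ten-dataset reference table, degree-1 regressions of E at
factor 2 rank the measures

```python
rank_measures(load_reference_table(), factor=2, dof=1)
# [('mnf', 0.9786), ('mdf', 0.9761), ('de', 0.9545), ('pc', 0.9182)]
```

— the two frequency measures are effectively tied and clearly ahead of
delentropy and perimetric complexity: spectral content is the best
predictor of downsampling loss.

## Command line

```bash
segcomplexity synth --kind vessel --size 256x256 --seed 7 --out mask.png
segcomplexity measure --images imgs/ --masks masks/ --out profile.json
segcomplexity degrade --masks masks/ --factors 2,3,4 --out audit.csv
segcomplexity regress --measure mdf --factor 2 --dofs 1:5 --out fits.json
segcomplexity advise --images imgs/ --masks masks/ --out recommendation.json
```

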