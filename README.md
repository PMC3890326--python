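# serialct

Diffeomorphic change detection in serial lung CT.

Radiologists following lung-cancer patients compare hundreds of thin-slice
CT images per examination pair, looking for nodules that grew, shrank,
appeared or vanished over weeks. `serialct` automates the geometric part of
that comparison: it registers the follow-up scan onto the baseline with a
**topology-preserving (diffeomorphic) deformation** and turns the fitted
map into reader-facing evidence.

The core is Large Deformation Diffeomorphic Metric Mapping (LDDMM) with
**cascading elasticity**: after 12-parameter affine initialization, the
pair is registered by consecutive diffeomorphic fits at decreasing
stiffness ratios α/γ = 0.01 → 0.005 → 0.002 of the velocity-regularizing
operator L = −α∇² + γ·Id, composing the per-stage maps φ = φ₁∘φ₂∘φ₃. Every
accepted iterate is certified by its Jacobian determinant, so connected
structures stay connected. Two complementary outputs follow:

- **Temporal subtraction image** S = registered t₂ − t₁: residual signal
  marks structure the diffeomorphism *cannot* explain — emerged or
  vanished nodules;
- **Jacobian determinant map** det(Dφ): > 1 where existing structure grew,
  < 1 where it shrank, ≈ 1 where nothing changed (color-coded red / green /
  yellow).

On top of the registration the package provides per-region change-pattern
classification (unchanged / growing / shrinking / emerged / vanished),
automated nodule volumetry by propagating a baseline segmentation through
the inverse map, landmark-based accuracy evaluation with ANOVA + post hoc
statistics, and a deterministic synthetic serial-lung phantom with exact
ground-truth deformations so the whole pipeline is testable without
patient data. See `docs/methods.md` for the model details and design
choices.

## Worked example

Register a synthetic serial pair containing one growing nodule (volume
factor 1.3) under a smooth breathing-like deformation, classify the change
and measure the volume:

```python
from serialct import (PhantomSpec, NoduleSpec, make_phantom_pair, CascadeLDDMM,
                      subtraction_image, classify_change, propagate_mask,
                      volume_ml, percent_change, jacobian_volume)

spec = PhantomSpec(shape=(48, 48, 48), seed=7, warp_amplitude=2.0,
                   nodules=(NoduleSpec(radius=5, change="grow", factor=1.3,
                                       center=(15.0, 32.0, 30.0)),))
pair = make_phantom_pair(spec)

fit = CascadeLDDMM(pair.vol_t1, pair.vol_t2, iterations=40).fit()
print(fit.summary())

S = subtraction_image(pair.vol_t1, fit.warp(pair.vol_t2))
pattern = classify_change(pair.regions[0], S, fit.jacobian())
v1 = volume_ml(pair.masks_t1[0])
v2 = volume_ml(propagate_mask(pair.masks_t1[0], fit.phi, fit.phi_inv))
```

which prints:

```
Cascading-elasticity LDDMM, schedule [0.01, 0.005, 0.002]
  stage α/γ=0.01    iters=40   cost 0.0017197 → 0.00046465  minJ=0.872
  stage α/γ=0.005   iters=40   cost 0.00081771 → 0.00042082  minJ=0.772
  stage α/γ=0.002   iters=3    cost 0.00036096 → 0.00036093  minJ=0.996
  composed min det(Dφ) : 0.7486
  composed max |u|     : 2.034 voxels

nodule call: growing  (mean S = +0.003, relative J = 1.255)
volumetry: 0.515 ml -> 0.627 ml (+21.7% change; Jacobian prediction 0.627 ml)
```

Reading the output: each stage reduces the residual mean squared intensity
difference while keeping the stage Jacobian strictly positive (`minJ`);
the composed map stays diffeomorphic (`min det(Dφ) = 0.75`). The grown
nodule disappears from the subtraction image (mean S ≈ 0 over the region —
the registration explained it) and surfaces in the Jacobian map instead
(region median J 1.26× its background shell → "growing"). The
mask propagated through φ⁻¹ measures the follow-up volume at +21.7%
(the scripted truth is +30% of which the registration captured most; the
independent Jacobian-integral prediction agrees with the propagated-mask
volume to three decimals — volume change is conserved between the two
accountings).

The same workflow runs from the shell:

```
serialct run --phantom --seed 1 --single-alpha 0.01 --outdir out/
serialct run --fixed t1.nii.gz --moving t2.nii.gz --landmarks lmk1.csv --outdir out/
```

writing warped volumes, per-stage subtraction images and logs, the
Jacobian map with color/hybrid renderings, `classification.csv`,
`volumetry.csv`, `accuracy.csv` and a reproducibility manifest. Individual
stages are available as `serialct preprocess | affine | lddmm | cascade |
analyze | volumetry | evaluate | make-phantom`.

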