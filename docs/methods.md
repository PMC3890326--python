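# Methods

`serialct` detects and quantifies temporal change between two chest-CT
volumes of the same subject: it registers the later scan onto the earlier
one with a topology-preserving (diffeomorphic) deformation, then reads
change off two complementary maps — the temporal subtraction image and the
Jacobian-determinant map of the fitted deformation — and measures nodule
volume change by propagating a baseline segmentation through the inverse
map. Everything is testable without patient data through a synthetic
serial-lung phantom with analytic ground truth.

## Preprocessing

Volumes are resampled to 1.0 mm isotropic spacing (trilinear; output shape
`ceil(extent/spacing)` so anatomy is never cropped; out-of-grid samples take
the volume minimum, i.e. air) and display-windowed with the lung window
(level −600 HU, width 600 HU) to [0, 1]. All registration operates on the
windowed intensities. Grids are axis-aligned (`world = origin + index ·
spacing`); oblique orientations are rejected rather than silently
mishandled.

## Affine initialization

The second time point is aligned to the first with a full 12-parameter
affine transform minimizing the mean squared intensity difference
(same-modality serial CT), optimized by multi-resolution regular-step
gradient descent with full sampling (SimpleITK registration framework
behind the `AffineRegistration` model class); the optimization is
deterministic. The fitted transform acts on world coordinates, `y = A·x +
t`, mapping fixed-frame points into the moving frame, and must be
orientation-preserving (`det A > 0`). A defensive check returns the
identity if optimization ever ends worse than it started.

## Diffeomorphic registration

### Velocity regularization

Deformations are generated by smooth velocity fields regularized through
the elasticity operator `L = −α∇² + γ·Id`, applied spectrally with periodic
boundary conditions and the 7-point discrete Laplacian on the grid
normalized to the unit cube (so a given α/γ ratio means a comparable
physical stiffness across grid sizes). Gradients are smoothed with
`K = (L†L)⁻¹`; only the ratio α/γ matters (γ is fixed at 1; the overall
scale is absorbed by step-size normalization). High ratios give stiff,
near-linear behaviour; low ratios admit localized deformation. Volumes are
padded with 8 voxels of background so the periodic FFT cannot wrap
anatomy.

### Greedy optimization (default)

The default optimizer composes small diffeomorphisms: at each iterate the
Sobolev (kernel-smoothed) gradient of the matching term is scaled so its
largest displacement is `step_voxels` (default 0.4 voxel) and composed onto
the current map, subject to three acceptance conditions checked on every
candidate (step halved on violation):

1. the total objective `β·mean‖α∇²u‖² + SSD_matched/σ₀²` decreases (the
   curvature energy is nearly free for smooth bulk deformation but prices
   out localized small-scale collapse; β = 0.02 by default, and the
   penalty's kernel-preconditioned gradient is part of the step direction;
   σ₀² is the initial matched mean squared difference, fixed across
   cascade stages so later, more elastic stages cannot rationalize large
   deformations against an ever-shrinking residual);
2. the stage map's Jacobian determinant stays strictly inside
   `jacobian_bounds` (default 0.5–2.0) at every interior voxel — bounded
   elasticity; in particular every accepted iterate is certified
   diffeomorphic (`det(Dφ) > 0`);
3. the cost is finite (otherwise a `DivergenceError` carries the log).

The inverse map is tracked incrementally (each small step `id + εv` is
inverted to second order and composed), then polished by an under-relaxed
residual iteration `u⁻¹ ← u⁻¹ − ω(u⁻¹ + u∘(id+u⁻¹))` (ω = 0.5), which
remains contractive where the plain fixed point stalls; typical
self-consistency `max|φ(φ⁻¹(x)) − x|` on the phantom suite is below 0.05
voxel.

An optional coarse-to-fine mode (`levels=2`) solves the smooth bulk of the
deformation on a 2× downsampled grid first; it is markedly faster but
biases the Jacobian inside correspondence-masked zones, so the default is
a single resolution level.

### Unmatched-structure masking

Serial pairs contain topology-violating change: nodules that emerge or
vanish have no counterpart to register to. Left to itself, an intensity
registration will "explain" them — compressing an emerged nodule out of
the warped image with extreme local expansion of the Jacobian — which
destroys the complementary reading (change of existing structure in the
Jacobian map, appearance/disappearance in the subtraction image). We
therefore apply cost-function masking, the standard practice when
registering images containing pathology. "Bulky" structure is defined by
a 5-voxel box erosion of the structure mask (windowed intensity above
0.3): nodule-sized masses keep a core, thin vessels and their junctions
erode away. A bulky core with no bulky partner anywhere within the
correspondence radius (8 voxels, chosen above the largest expected
post-affine misalignment) is flagged as unmatched; the flagged cores are
dilated back over the whole mass plus a margin and smoothly excluded from
both the force and the accepted matching cost. A displaced or grown
nodule finds its partner and is registered normally. The velocity inside
the masked zone is filled from its surroundings by normalized
convolution, so unmatched structure advects with the ambient deformation
instead of lagging and shearing its neighbourhood. Emerged/vanished
nodules thus keep `det(Dφ) ≈ 1` and full contrast in the subtraction
image. The mask is computed once per registration from the input pair.

### Time-discretized velocity mode

A full time-dependent formulation is available (`method="velocity"`): T
velocity steps (default 10), semi-Lagrangian flow integration of
`φ_{t,0}` and `φ_{t,1}`, and gradient
`2v_t − K[(2/σ²)|Dφ_{t,1}| (J⁰_t − J¹_t) ∇J⁰_t]` with backtracking on the
total energy and the same Jacobian safeguards; the backward flow provides
the inverse. It costs roughly T times the greedy mode per iteration and is
exercised at small grid sizes in the test suite; the greedy mode is the
default operating mode because it reaches the same landmark accuracy on
the phantom suite at a fraction of the cost.

### Cascading elasticity

`CascadeLDDMM` runs consecutive registrations at strictly decreasing
ratios (default 0.01, 0.005, 0.002), each on the moving image re-warped
through the composed map so far; the final map is the composition
φ₁∘φ₂∘…∘φₙ and its inverse is the reverse composition of stage inverses.
Stage residuals are non-increasing by construction. The Jacobian map
reported for change detection is that of the composed nonlinear map only —
the affine is estimated and applied upstream, so det(Dφ) reflects elastic
volume change alone.

## Change detection

- **Subtraction image** `S = registered_t2 − t1`: zero where explained,
  positive (white) where tissue is new/denser at follow-up, negative
  (black) where it vanished.
- **Jacobian color map**: yellow inside the neutral band (0.95–1.05),
  ramping to red for growth and green for shrinkage (saturating at 2.0 and
  0.5); non-positive determinants are painted magenta and counted. A
  hybrid overlay blends the color map over the grayscale subtraction where
  J leaves the band.
- **Per-region classification**: regions (caller-supplied masks, phantom
  truth regions, or connected-component proposals from |S| and |log J|
  exceedances) are called from two statistics: the mean of S over the
  region and the median Jacobian normalized by the median over a
  surrounding background shell (dilations 4–10 voxels, starting beyond the
  correspondence-mask margin). The median is robust to small sub-volumes
  of extreme determinants; the shell reference cancels ambient volume
  change. Decision table with defaults τ_S = 0.1 (windowed units) and
  τ_J = 0.05: S≈0 & J≈1 → unchanged; S≈0 & J high/low → growing/shrinking;
  S strongly positive/negative & J≈1 → emerged/vanished; anything else →
  ambiguous, with both scores reported. The cutoffs are package choices
  (the source imagery convention is qualitative) fixed on the phantom
  suite.

## Volumetry

A nodule is segmented at baseline by seeded 6-connected region growing
(neighbour joins when within `intensity_tol` = 0.25 windowed units of the
running region mean). The mask is transferred to follow-up through the
inverse deformation with partial-volume interpolation, binarized by
volume-preserving rank thresholding: the propagated mask consists of the
`round(Σ occupancy)` most-interior voxels, so the voxel count equals the
partial-volume integral (a fixed 0.5 threshold erodes digitized spheres by
several percent). Volumes are voxel count × voxel volume / 1000 (ml);
percent change is `100·(v2−v1)/v1` (antisymmetric only through
`p12 = −p21/(1+p21/100)`). The Jacobian integral over the baseline mask is
an independent prediction of the follow-up volume and agrees with the
propagated-mask volume to a few percent on the phantom suite — a
conservation check on the whole chain.

## Accuracy evaluation

Landmarks (vessel bifurcations, labeled with lung side and
proximal/distal depth; the study layout is 20 right / 18 left with four in
the left S1+2) are transferred through each candidate transformation and
scored by 3D Euclidean distance to their true follow-up positions, pooled
within stratum. `summarize` reports mean ± sample SD (n−1) per method per
stratum; `anova_posthoc` runs one-way ANOVA (explicit degenerate path:
all-identical values → F = 0, p = 1) with Tukey HSD post hoc comparisons
by default (Bonferroni-corrected t-tests as an option) at α = 0.05.

## Synthetic serial phantom

The generator emulates what the pipeline needs from real serial chest CT:
dark parenchyma (0.05), bright branching vessel trees (0.9) whose
bifurcations give unambiguous landmarks, spherical nodules (0.8), Gaussian
noise (sd 0.02), and a scripted temporal change with exact ground truth:

- **Global deformation**: the curl of a random low-frequency vector
  potential, scaled to a peak displacement (default 4 voxels).
  Divergence-free displacement keeps the background Jacobian within a few
  percent of 1 — emulating breathing-matched serial CT, where parenchyma
  shifts but barely changes volume — so nodule growth is the dominant
  Jacobian signal. Displacement and gradient are evaluated in closed form.
- **Nodule change scripts**: none / grow / shrink (volume factor g; pure
  scaling by g^{1/3} inside the sphere, C² quintic-Hermite decay to zero
  by 2.2·r + 2 voxels, supports kept pairwise disjoint so the analytic
  Jacobian factorizes) / appear (painted only at follow-up) / vanish
  (present only at baseline).
- The truth map is `φ_global ∘ φ_radial`, evaluated exactly on the grid;
  the follow-up image renders the persistent scene at `φ⁻¹` positions
  analytically (no resampling blur beyond the 1e−3-voxel numeric
  inversion); truth landmark positions, truth masks at both times,
  fixed-frame evaluation regions and the analytic Jacobian map come with
  the pair. Generated warps are rejected unless min det(Dφ) > 0.1.
  Everything is deterministic per seed.

What the phantom does not emulate: real parenchymal texture, breathing-
level lung deformation with sliding at the pleura, beam hardening, partial
volume at the mediastinum, and contrast differences between scans. Passing
the suite shows the machinery is correct and calibrated on lung-like
geometry; it does not certify clinical-grade accuracy on patient data.

## Numerical choices and problem sizes

float32 field arithmetic with float64 reductions; trilinear interpolation
throughout (edge-extrapolated displacement sampling, air-filled image
sampling); central differences for Jacobians (one-sided at faces,
interior-only reporting for minima); inversion tolerance 0.01 voxel
(public `invert`), 0.005 for the internal polish; convergence at relative
cost decrease < 1e−5 or the iteration cap. The default test/acceptance
problem is a 96³ phantom at 1 mm (≈ the axial extent of a lung at the
study's resampling, reduced in-plane), with 24–64-voxel grids for unit
tests; a single-α plus cascading registration of the 96³ pair at the
60-iteration budget takes about ten minutes on one core.

## Known limitations

- The greedy mode optimizes a surrogate of the flow energy (stationary
  composition rather than a time-dependent geodesic); reported Jacobian
  bounds apply per stage, and the composed map's determinant can exceed
  them slightly.
- Cost-function masking keys on an intensity threshold; faint ground-glass
  structure below the threshold is treated as background and its
  appearance/disappearance influences the deformation only weakly.
- The affine cost is SSD, appropriate for same-protocol serial CT only.
- Landmark accuracy on the phantom is limited by the aperture problem
  along vessels; bifurcation landmarks mitigate but do not remove it.
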