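# Methods

This note records the model as implemented, the numerical choices behind it,
and what the synthetic test bed does and does not establish.

## Registration model

The pipeline estimates, for a reference image `R` and a floating image `F`
on a common grid, a rigid transform `t` and a dense displacement field `v`
such that `F(t(P + v(P))) ≈ R(P)`.  All field components are in voxel units
and the warp convention is *pull*: warping samples the floating image at
`P + v(P)` with linear interpolation (edge-replicate padding by default).
Both images are min–max normalised to [0, 1] on entry; every intensity-space
parameter below refers to that scale.

### Demons force and its sign

The classic demons force used here is

    u(P) = (r − f) ∇r / (‖∇r‖² + (r − f)²/k²)

with `f` the warped-floating intensity.  This is the Gauss–Newton descent
step on ½(f − r)² under the pull convention, with the reference gradient
standing in for the warped-floating gradient.  Statements of the demons
force with the opposite sign, `(f − r)∇r/…`, assume the forward-warp
convention in which the field moves floating-image pixels; mixing that sign
with a pull warp makes the aligned configuration an unstable fixed point
(on a 1-D ramp translated by `d` the update reduces to
`dv/dt = (v − d)/(1 + (v − d)²)`, which diverges from `v = d`).  Where the
denominator is exactly zero the force is defined as zero.  The magnitude is
bounded by `k/2` at every voxel, which makes `k` both a stability bound and
a weight on how much the raw intensity-difference force contributes — the
relevant knob when the two modalities' intensity mappings disagree and that
force is locally misdirected.

### Parzen joint density and the MI force

The joint density of normalised intensity pairs is estimated on an `M × M`
lattice over [0, 1]² with a separable Gaussian kernel of width `δ`,
implemented as bilinear binning of the `N` voxel pairs followed by lattice
Gaussian smoothing (the standard fast Parzen estimator; identical to
per-sample kernel sums up to `O(h²)` binning blur, `h = 1/(M−1)`), then
renormalised so the lattice integral is exactly 1.  Marginals are lattice
sums, MI is the Riemann-sum quadrature of `p log[p/(p_R p_F)]` in nats with
zero-density terms contributing zero.

The MI force evaluates `(1/N)[Ψ_δ ⊗ ∂L/∂j](R(P), F(P+v)) · ∇F(P+v)` with
`L = 1 + log[p/(p_R p_F)]`.  The lattice discretisation of the
convolution-derivative operator is chosen as the **exact adjoint of the
density estimator**: `L` (offset by the renormalisation constant) is
smoothed with the same Gaussian kernel, differenced per bin along the `j`
axis, and looked up at each voxel's intensity pair with the binning weights;
`∇F(P+v)` is the exact in-cell slope of the linear interpolant.  With this
discretisation the analytic force *is* the gradient of the discrete MI —
central finite differences agree to ~1e−5 relative error, against a few
percent for the naive smoothed-central-difference discretisation.  Away
from kinks of the piecewise-linear discrete objective (interpolation-cell
and intensity-bin borders) the two discretisations estimate the same
continuum operator.

A consequence worth knowing: at *exact* alignment of identical images the
discrete gradient is not zero but bin-scale noise (the binned MI prefers
samples at bin centres).  The per-iteration field smoothing averages this
jitter to near zero, and the per-level guard below prevents it from ever
degrading a converged configuration.

### Update, step sizes, and stopping

One GMI demons iteration computes `G_σ ∗ (v_n + u + α·N·∇MI)`: Gaussian
smoothing of the summed field (diffusion-like regularisation), applied
component-wise; `σ = 0` disables it.  The MI step `α` multiplies the
*per-sample* gradient `N·∇MI` because the raw `1/N` gradient would make a
fixed step 16× stronger at the coarsest level of a factor-2, 3-level
pyramid than at the finest; per-sample scaling keeps the update magnitude
comparable across levels.  The combined force is capped at `max_step`
voxels per voxel per iteration (default 1.25) as a stabilisation guard.

Each pyramid level iterates until the MI increment per iteration falls
below `mi_stop_threshold` or the iteration cap is reached.  The increment
is measured on an 8-iteration moving average of the MI trace: individual
demons steps overshoot, so the raw per-iteration increment oscillates in
sign well before convergence and would stop the level after one or two
iterations.  A level that ends with MI below its starting value reverts to
its starting field — a level never leaves the configuration worse than it
found it (this also makes registering an image to itself a no-op).

### Multiresolution schedule

Pyramids are built by repeated anti-alias smoothing (`σ = 0.5·factor`) and
subsampling; depth is reduced automatically if the coarsest level would
fall below 8 voxels per axis.  Fields are seeded coarse-to-fine by linear
interpolation with components multiplied by the factor (voxel-unit
rescaling).  MI for the stopping test is evaluated at the current level's
resolution.

### Rigid pre-alignment

The global stage maximises the same Parzen MI over rotation + translation
(1 + 2 parameters in 2-D, 3 + 3 in 3-D) with Nelder–Mead simplex searches
from three starts — the identity and ± the intensity-centroid offset —
each followed by a tight-simplex polish; the best of all results and the
identity is returned, so the stage never loses MI.  The transform maps
reference coordinates onto floating coordinates and is applied once, by
resampling the floating image, before the deformable stage; the returned
deformable field therefore excludes it, and `total_displacement` composes
the two into the end-to-end mapping `t(P + v(P)) − P`.

### Defaults and their calibration

`k = 0.6`, `σ = 2.2` voxels, `α = 8` (per-sample), `δ = 0.025`,
`M = 128`, 3 levels of factor 2, 150 iterations/level cap, MI tolerance
1e−5 nats.  None of these have canonical values; they were calibrated once
on the synthetic phantom suite (64² grids, organ-scale smooth deformations,
non-monotone intensity remap) by scanning each around literature-typical
values, and then frozen.  The calibration trade-offs: smaller `k`
suppresses the misdirected intensity force inside remapped tissue but
weakens boundary tracking where both modalities agree (k = 0.6 balanced the
two); larger `σ` regularises the MI force's sample-level jitter at the cost
of amplitude resolution; `δ` and `M` set how finely the density resolves
the distinct tissue intensity levels.  For monomodal problems the classic
settings `k = 1, α = 0, σ ≈ 1–1.5` are the sensible starting point.

## Evaluation metrics

Directed Hausdorff, symmetric Hausdorff, and the modified Hausdorff
distance (directed mean of nearest-neighbour distances, symmetrised with
the outer max) operate on explicit point sets, in voxel units, or in mm
when a spacing is supplied.  Nearest neighbours come from a k-d tree; for
small problems the full distance matrix is used so results are
bit-identical to the double-loop definition.

Image-pair evaluation extracts feature points as the boundary of the
hole-filled largest connected component at the per-image Otsu threshold
(`isocontour`), or gradient-magnitude maxima (`edge`).  Holes are filled
because interior organs can straddle one modality's threshold but not the
other's, producing pseudo-contours with no cross-modality counterpart that
floor the M-HD regardless of alignment; the body outline is the structure
both modalities share.

## The synthetic test bed

`generate_phantom_pair` renders one 2-D (or 3-D) anatomy — a body ellipse,
a muscle/fat ring and six organs of distinct intensities — and derives the
two channels from it: the reference adds a bright Gaussian "lesion" blob
(high focal uptake) and the floating passes the anatomy through an
intensity transfer function.  The default transfer function is
*non-monotone*: background/body contrast keeps its polarity while interior
organ contrasts invert, so intensity-difference forces are actively
misdirected inside the body — the regime the MI force exists for.  A
monotone and an identity mapping are available for contrast experiments.

The ground-truth deformation is Gaussian-filtered white noise
(smoothness length 10 voxels ≈ organ scale), windowed by a smooth
body-support envelope (tissue moves, surrounding air does not) and scaled
to a 5-voxel maximum.  The floating channel is built by sampling through
the *inverse* of this field (computed by fixed-point iteration) composed
with the inverse of the rigid offset ((5, −3) voxels + 5° by default), so
that recovering exactly `truth_rigid` then `truth_field` under the pull
convention re-aligns it.  Gaussian noise (σ = 0.02 of the intensity range)
is added to both channels.  Everything derives from a single integer seed.

What the phantoms do **not** emulate: Poisson/projection-domain PET noise,
CT beam-hardening, partial-volume effects, intra-tissue texture, sliding
motion at organ interfaces, or truly unrelated cross-modality structure
(every floating intensity is a function of the reference anatomy).  Passing
the suite therefore shows that the machinery recovers known smooth
deformations under intensity remapping and noise at desk scale — not
clinical-grade accuracy on real PET/CT.

Piecewise-constant compartment interiors carry no alignment information,
so part of the residual endpoint error is an observability floor shared by
any method; the suite's conditions were chosen so that this floor sits
well below the separation being demonstrated (full pipeline ≈0.86 voxels
mean endpoint error vs ≈3.2 for classic demons alone on the same cases).

## Known limitations

* Additive (not compositive) field updates and plain diffusion
  regularisation: no diffeomorphism guarantee; folding is possible for
  aggressive steps (the `max_step` cap is the only guard).
* The rigid stage's optimum is biased by whatever deformation is present;
  residual pose error of a degree or two is normal and is absorbed by the
  deformable stage.
* The MI force is global-statistics-driven; in textureless regions it only
  interpolates through the field smoothing.
* 3-D is supported by the same rank-generic operators but only
  smoke-tested; runtimes at clinical volume sizes are not addressed.
* Images must share a grid; resampling between differing physical spaces
  is out of scope.
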