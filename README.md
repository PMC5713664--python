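# gmidemons

Deformable registration of multimodal medical image pairs — typically a
functional, PET-like reference and an anatomical, CT-like floating image —
with a multiresolution demons algorithm driven by the **gradient of mutual
information** (GMI demons), preceded by a rigid MI-driven pre-alignment and
evaluated with modified-Hausdorff-distance feature metrics.

The package is aimed at medical-physics / image-analysis work where the two
images show the same anatomy under *different intensity mappings*, so that
plain intensity-difference (optical-flow) forces are misdirected and a
statistical similarity measure has to supply the direction of motion.

## The model

A displacement field `v` maps each reference grid point `P` to the floating
sample `F(P + v(P))` (pull-warp convention).  The classic demons update is

    v_{n+1} = G_σ ∗ ( v_n + (r − f) ∇r / (‖∇r‖² + (r − f)²/k²) )

with `r = R(P)`, `f = F(P + v_n(P))`, `∇r` the reference gradient, `k` a
normalisation factor bounding the per-voxel step by `k/2`, and `G_σ` a
Gaussian that regularises the summed field after every iteration.

The GMI demons update adds an external force along the gradient of mutual
information between the two images:

    v_{n+1} = G_σ ∗ ( v_n + demons force + α ∇MI(v_n) )

MI is made differentiable with a Parzen-window estimate of the joint
intensity density on a regular lattice,

    p(i, j) = (1/N) Σ_P Ψ_δ( R(P) − i, F(P+v)(P) − j ),
    MI(v)   = ∬ p(i,j) log[ p(i,j) / (p_R(i) p_F(j)) ] di dj   (nats)

with `Ψ_δ` a separable Gaussian kernel of width `δ` and `N` the number of
overlap voxels.  Its gradient with respect to the field is, per voxel,

    ∇MI(P) = (1/N) [ Ψ_δ ⊗ ∂L/∂j ]( R(P), F(P+v) ) · ∇F(P+v),
    L(i,j) = 1 + log[ p(i,j) / (p_R(i) p_F(j)) ]

Registration runs coarse-to-fine on Gaussian image pyramids; each level
iterates until the MI increment falls below a threshold, then the field is
upsampled (and rescaled to the finer voxel units) to seed the next level.
A rigid rotation + translation stage, optimised on the same MI measure with
a derivative-free simplex search, removes the whole-body pose error first.

Registration quality is scored on feature point sets `A`, `B` with the
Hausdorff family; the headline metric is the modified Hausdorff distance

    h_MHD(A,B) = (1/N_A) Σ_{a∈A} min_{b∈B} ‖a − b‖,
    M-HD(A,B)  = max( h_MHD(A,B), h_MHD(B,A) )

which is robust to isolated noise points (smaller = better aligned).

## Worked example

Generate a synthetic multimodal phantom (one anatomy rendered under two
intensity mappings, with a known smooth deformation plus a rigid offset) and
run the full pipeline:

```sh
gmidemons make-phantom --seed 42 --out-dir case42
gmidemons run --reference case42/reference.nii --floating case42/floating.nii \
              --out-dir case42/out
```

The manifest written to `case42/out/manifest.json` reports, for this case:

| stage            | MI (nats) | M-HD (voxels) |
|------------------|-----------|---------------|
| before           | 0.349     | 3.798         |
| after global     | 0.729     | 0.923         |
| after GMI demons | 0.890     | 0.532         |

MI rises and the body-contour M-HD falls at every stage: the rigid stage
removes the (5, −3)-voxel + 5° pose error, and the deformable stage the
residual local deformation (iterations per level: 15, 32, 26 from coarsest
to finest).  Because the phantom's ground truth is known, the recovered
total displacement can also be scored directly:

```python
from gmidemons import (PhantomSpec, generate_phantom_pair, register,
                       total_displacement, endpoint_error)
pair = generate_phantom_pair(PhantomSpec(seed=42))
res = register(pair.reference, pair.floating)
est = total_displacement(res.field, res.global_transform)
truth = total_displacement(pair.truth_field, pair.truth_rigid)
print(endpoint_error(est, truth, pair.body_mask))
# EndpointErrorSummary(mean=1.249, median=1.178, max=2.839)  (voxels)
```

against a do-nothing baseline of 7.28 voxels mean misalignment.  Across the
standard five-case suite the pipeline averages ≈0.86 voxels mean endpoint
error, while classic demons without the MI force fails on these
non-monotone-remap cases (≈3.4 voxels).

The same stages are available individually (`gmidemons global-register`,
`gmidemons register`, `gmidemons evaluate`) and as library functions
(`rigid_register`, `register`, `modified_hausdorff`, ...).

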