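# bootrecon

Bootstrap-optimised regularised image reconstruction for 2D emission
tomography (PET).

Iterative penalised-likelihood (MAPEM) reconstruction needs a penalty
strength β, and the right value depends strongly on the noise level of the
measured data: too small and the image stays noisy, too large and detail is
smoothed away. `bootrecon` selects β automatically *during* the
reconstruction, with no user-supplied value, no ground truth, and no grid of
trial reconstructions. It is aimed at researchers studying regularised
emission-tomography reconstruction who want each penalty to operate at its
appropriate strength without hand tuning.

## The method

The data model is Poisson: measured sinogram counts `m` with mean
`A θ + b`, where `A` is the system model (image-space Gaussian PSF followed
by a parallel-beam Radon transform, with the back projector its exact
adjoint) and `b` the known mean background (scatter + randoms). The
unregularised MLEM update is

    θ_meas = (θ / Aᵀ1) · Aᵀ( m / (Aθ + b) )

and the quadratically penalised update factorises (De Pierro's modified EM)
as a per-pixel denoising operator applied to the MLEM update,

    F_β(θ_em)_j = positive root of  βν_j x² + ξ_j x − θ_em,j = 0,
    ξ_j = 1 − βν_j θ_reg,j ,   ν_j = Σ_l w_jl / s_j ,

with `θ_reg` a locally smoothed copy of the previous iterate, `w_jl`
neighbourhood weights (uniform 5×5, or Bowsher-guided: each pixel keeps the
B most similar neighbours in a guide image) and `s = Aᵀ1` the sensitivity.

To choose β, each iteration also updates a fixed bootstrap replicate
`m_boot` of the counts (resampled with replacement, same total). The EM
update of the measured data models the *mean* of an ensemble of noisy
updates; the EM update of the replicate models one noisy member. Fitting
the regularised replicate update to the measured update,

    β_opt(k) = argmin_β  Σ_{j∈Ω} ( θ_meas,j − F_β(θ_boot)_j )² ,

estimates how much regularisation maps a noisy update onto the ensemble
mean. The running maximum β_use = max_k β_opt(k) is kept, and an
exponentially cooled over-regularisation λ(k) = λ⁰ exp(−k/N) is applied on
top early on (β_cool = β_use + λ β_opt), so that low spatial frequencies are
fitted before noise-dominated high frequencies enter the comparison. The
iteration applies θ ← F_{β_cool}(θ_meas); as λ decays the run becomes an
ordinary convergent fixed-β MAPEM reconstruction at the selected strength.
With several replicates, β_opt is the maximum of the per-replicate fits,
which prevents a single replicate from fitting β = 0 on high-count data.

## Worked example

```python
import numpy as np
import bootrecon as br
from bootrecon.hyperopt import DriverConfig, reconstruct_bootstrap_optimised
from bootrecon.penalties import make_context, uniform_weights
from bootrecon.projector import desk_geometry

geom = desk_geometry(psf_fwhm=3.0)          # 64x64 image, 60 angles x 95 bins
phantom = br.make_phantom("brain_like", geom.image_shape, geom.pixel_size, seed=0)
ds = br.simulate_acquisition(
    phantom, geom, br.AcquisitionSpec(total_counts_mean=3.5e6, seed=1)
)
ctx = make_context(
    uniform_weights(geom.image_shape, stencil=5), br.sensitivity_image(geom)
)
cfg = DriverConfig(lambda0=1000.0, N=30, max_iter=300, seed=2)
res = reconstruct_bootstrap_optimised(ds.m, ds.b, geom, ctx, cfg)
trace = res.beta_trace
print(f"measured counts        : {int(ds.m.sum())}")
print(f"selected beta_use      : {trace.beta_use[-1]:.3e}")
print(f"applied final beta_cool: {trace.beta_cool[-1]:.3e}")
print(f"beta_opt peak / final  : {max(trace.beta_opt) / trace.beta_opt[-1]:.2f}")
```

prints

```
measured counts        : 3499957
selected beta_use      : 8.300e-04
applied final beta_cool: 8.422e-04
beta_opt peak / final  : 3.08
```

The acquisition realised ~3.5 million counts; the driver settled on
β ≈ 8.3e-4 for the uniform 5×5 quadratic penalty, and its β_opt trace rose
to about three times its settled value before dropping — the expected
signature of the cooling schedule admitting progressively higher spatial
frequencies. Evaluating the final image against the clean FBP reference
over the head mask gives a normalised RMSE of 0.1534, within ~1% of the
best fixed-β reconstruction found by an 8-point grid search with knowledge
of the ground truth.

The same pipeline is available from the shell:

```
bootrecon simulate --counts 3.5e6 --seed 1 --out data/run1
bootrecon reconstruct --dataset data/run1 --out out/run1 -N 100 --max-iter 400
bootrecon evaluate --recon out/run1/recon.nii --recon out/run2/recon.nii \
                   --dataset data/run1 --out metrics.csv
```

`reconstruct` writes the image (NIfTI), a per-iteration `beta_trace.csv`
(columns `k, beta_opt, beta_use, lambda, beta_cool, emof_value`) and a run
manifest.

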