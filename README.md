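# pnss — pixel-level non-local self-similarity denoising for low-dose CT

Low-dose CT acquisitions trade radiation exposure for image quality: the
reconstructed slices carry heavy noise that obscures low-contrast anatomy.
`pnss` implements a three-stage, training-free denoiser built on the
observation that similar structures recur at distant image locations — and
pushes that prior from the usual patch level down to the level of individual
pixels.

## Method

For each reference patch, the m most similar patches inside a W×W search
window are stacked into an n×m matrix Y (n = patch pixels).  Row i of Y holds
the same in-patch pixel position seen across the m similar patches; the q
rows nearest to row i (Euclidean distance) form a q×m matrix of mutually
similar pixels.

1. **Stage 1 — grouped Haar thresholding.**  The spread among similar rows
   estimates the noise: σ_l = (1/(n(q−1))) Σ d/√m per group, σ_g = mean σ_l.
   Each q×m matrix is transformed with the orthonormal 2-D Haar transform
   C = H_q·Y·H_mᵀ and bi-hard thresholded: amplitude (|C| ≥ τσ_g²) plus a
   structural rule that zeroes the two finest-detail rows outside the first
   column.  Inverse transform and per-pixel averaging of the overlapping
   estimates give the pilot image; the cycle repeats K times on the blend
   λ·noisy + (1−λ)·previous.
2. **Stage 2 — fast non-local means.**  NLM weights are computed
   displacement-by-displacement: for each shift d the squared difference
   image (v(k) − v(k+d))² is integrated once (prefix sums), making every
   patch distance a four-corner lookup.  The cost no longer depends on the
   patch size, and the result is bit-identical to the direct sliding-window
   computation.
3. **Stage 3 — empirical Wiener refinement.**  Groups are re-found on the
   stage-2 image; paired pixel matrices from the stage-2 image and the
   original observation are both Haar-transformed, and the noisy coefficients
   are shrunk by gains p²/(p² + (σ_g/2)²), with p the stage-2 ("pilot")
   coefficient.  Inverse transform and aggregation give the final image.

Defaults (patch side 8, m = 16, q = 4, W = 40, τ = 2, K = 3, λ = 0.6, NLM
P = 5, h = 0.15) are the method's published operating point; see
`docs/methods.md` for every parameter, its units, and the reasoning behind
the open choices.

## Worked example

No dataset is needed — the package generates its own phantoms:

```bash
pnss simulate --size 128 --sigma-255 25 --seed 1 \
     --out-clean clean.tiff --out-noisy noisy.tiff
pnss denoise --in noisy.tiff --out denoised.tiff --ref clean.tiff
```

which prints (noise level σ = 25 added on the conventional 0-255 scale):

```
sigma_g estimate: 0.09275 (23.65 on 0-255)
noisy    vs ref: PSNR=20.5730 dB  SSIM=0.3438  RMSE=0.0936
denoised vs ref: PSNR=25.0664 dB  SSIM=0.7585  RMSE=0.0558
```

The estimator reads the injected noise slightly low (23.7 vs 25; the
similar-patch and similar-row selections both bias distances downward — see
the methods note), and the pipeline buys ≈ 4.5 dB of PSNR and more than
doubles SSIM on this fixture.  The same computation from Python:

```python
from pnss import DenoiseConfig, PhantomSpec, add_gaussian_noise, make_phantom, run, report

clean = make_phantom(PhantomSpec(size=128))
noisy = add_gaussian_noise(clean, sigma_255=25, seed=1)
result = run(noisy, DenoiseConfig())
print(report(result.image, clean))   # PSNR=25.0664 dB  SSIM=0.7585  RMSE=0.0558
```

`pnss nlm` exposes stage 2 alone and `pnss metrics` scores any image pair.

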