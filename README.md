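# camura

Single-view 3D coded-aperture emission imaging for breast scintigraphy:
mosaic MURA mask generation, an analytic Poisson acquisition simulator for a
voxelized breast phantom, near-field correction, mask/antimask MLEM
reconstruction, and CBR/PSNR/MSE image-quality scoring.

## The problem

A gamma camera with a coded-aperture mask replaces the pinhole of a
scintimammography system with a Modified Uniformly Redundant Array (MURA): a
prime-rank binary pattern, about 50% open, whose periodic cross-correlation
with its balanced decoder is a perfect delta function. Every point of a
radiotracer-filled breast casts a shifted copy of the mask pattern onto the
detector; because the shadow scale depends on the source depth
(magnification `m(z) = (a(z)+b)/a(z)` for a slice at distance `a(z)` in
front of the mask and a detector `b` behind it), a **single projection**
carries depth information, and decoding it slice by slice with the
depth-matched magnified mask yields a 3D volume — no camera rotation.

The package implements that pipeline end to end for a half-ellipsoidal
breast phantom (134 mL, 0.5 mm voxels) with a spherical lesion at half depth
and a 10:1 tumor-to-background activity ratio:

1. **mask** — rank-p MURA base patterns (quadratic-residue construction),
   2p×2p mosaics, rotated antimasks, balanced decoders, response functions;
2. **geometry** — magnification, geometric resolution `d(a+b)/b`, field of
   view `D·a/b`, the 40-slice stack (`z = −20 … +19`, 1 mm each,
   `a` from 120 mm down to 81 mm);
3. **phantom** — labeled voxel grid (skin / adipose / glandular / stochastic
   duct tree / lesion) and activity budgeting: 20 mCi dose × (134 mL / 80 L)
   → 33.5 µCi breast activity → ≈7.4×10⁸ emissions in 10 min;
4. **projector** — per-slice shadow formation by area-weighted convolution,
   `cosⁿθ` near-field modulation, Gaussian detector blur, Poisson counts;
5. **nfc** — near-field correction, analytic (known geometry) or
   envelope-fit (external projections);
6. **recon** — per-slice MLEM with the magnified mask shadow as PSF
   (statsmodels-style `CodedApertureMLEM(...).fit()` → `MLEMResults`),
   mask/antimask dual reconstruction with background-suppressing
   subtraction, and partial-copy folding;
7. **metrics** / **study** — CBR, MSE, PSNR against the ground-truth
   activity, and the full lesion-size × technique comparison study.

The MLEM update for a slice estimate `f` with PSF `h` is the standard
multiplicative EM step for Poisson data,

    f ← (f / s) · corr( p / conv(f, h), h ),    s = Σ h,

evaluated with linear (zero-padded) FFT convolutions; a truncated-detector
variant (`forward = crop(conv(f,h))`, spatially varying sensitivity) models
the physical detector that clips the mosaic shadow.

## Worked example

```python
import camura as c

# system constants of the reference design
print(c.magnification(100, 300))                    # 4.0
print(round(c.geometric_resolution(1, 100, 300), 2))  # 1.33  (mm)
print(round(c.field_of_view(664, 100, 300) / 10, 3))  # 22.133 (cm)
print(c.breast_activity_from_dose(20, 134, 80))     # 33.5  (uCi)

# desk-scale study: 8 mm lesion, three reconstruction techniques
cfg = c.RunConfig()
cfg.phantom.lesion_diameters = [8.0]
result = c.run_study(cfg)
print(result.table())
```

prints (seed 0, the default configuration):

```
 lesion technique                     CBR      PSNR          MSE
----------------------------------------------------------------
    8mm mosaic_mask_antimask       9.5238   28.9296     0.065536
    8mm mosaic_mask                0.3557   31.3628       2.6115
    8mm mura_mask_antimask        10.2096   27.1240        0.116
```

The mosaic mask/antimask difference suppresses the multiplexing background
(highest-contrast lesion, smallest MSE against the truth slice); the
mask-only reconstruction keeps the full breast background, so its ROI-mean
contrast is low; the plain (non-mosaic) MURA collects a quarter of the
counts through its smaller aperture. CBR is `(μ_lesion − μ_bkg)/μ_bkg` over
a lesion disk and a concentric background annulus on the lesion-depth
slice; MSE/PSNR compare against the ground-truth activity slice brought to
the reconstruction's intensity scale.

There is also a command-line interface:

```
camura make-mask --rank 83 --mosaic --out mask.tif
# wrote 166x166 pattern (13776 open, 0.4999) to mask.tif
camura run --out results/ --seed 0
```

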