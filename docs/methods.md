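# Methods

This note documents the model, its parameters, the numerical choices, and
the limits of what the reduced-scale simulations demonstrate.

## System model

A planar detector of side `D` sits a fixed distance `b` behind a coded
mask; the breast hangs in front of the mask, sliced into 1 mm planes
indexed `z = −20 … +19` at mask distances `a(z) = 100 − z` mm (farthest
slice 120 mm at the chest wall, closest 81 mm at the apex). Three
quantities govern the optics:

* mask-shadow magnification `m(z) = (a+b)/a` — 4.0 at the breast centre,
  3.5 to 4.75 across the stack;
* object magnification `b/a` — the reconstructed object's scale on the
  detector plane;
* geometric resolution `d·(a+b)/b` of a hole of size `d` — 1.33 mm at the
  centre for a 1 mm hole.

The aperture is a MURA of odd-prime rank `p` (quadratic-residue
construction, Gottesman–Fenimore conventions: row 0 closed, column 0 open
except the corner, interior element (i,j) open when the Legendre symbols of
i and j agree; balanced decoder `G = ±1` with `G(0,0) = +1`). Its periodic
cross-correlation with `G` is exactly two-valued — a central peak equal to
the open count `(p−1) + (p−1)²/2` over a flat zero floor — which is the
delta-like system response that makes multiplexed imaging decodable. The
mosaic is the 2p×2p periodic tiling, so every p×p window is a complete
cyclic shift of the base and sources anywhere in the field cast a fully
decodable pattern. The antimask is the mask rotated by 90°; for ranks
`p ≡ 3 (mod 4)` — the class the full-scale rank 83 belongs to — the
mask × rotated-mask cross-correlation is flat, i.e. the rotated pattern
carries no coding gain and acts as a pure background decode. (For
`p ≡ 1 (mod 4)` this fails: the rotation partially decodes the object.
Reduced-scale masks must therefore stay in the 3-mod-4 class; the element-
wise rotation-vs-complement agreement is exposed as the
`complement_overlap` diagnostic, about 0.5 at rank 83.)

## Phantom and activity budget

The breast is a half-ellipsoid with semi-axes (40, 40, 40) mm — volume
(2/3)π·40³ = 134.0 mL — voxelized at 0.5 mm (0.125 mm³ voxels), with a
one-voxel skin shell, a glandular core (0.6 of the semi-axes), a seeded
recursive bifurcating duct tree (labels only), and a spherical lesion of
3–8 mm diameter centred on the axis at half depth. Tissues carry no
attenuation or composition; they matter only through specific activity.

The budget follows the usual bookkeeping: a 20 mCi systemic dose scaled by
the breast-to-body volume ratio (134 mL / 80 L) gives 33.5 µCi; over a
600 s acquisition that is ≈7.44×10⁸ emissions ("circa 750 million").
Activity is uniform per voxel across all breast tissues, with the lesion at
TBR (default 10) times the background rate, normalised so the grand total
is exact. The resulting background rate is ≈1.14 Bq per voxel (the nominal
figure of 1.15 Bq is not exactly derivable from the stated inputs; we
report the computed value).

## Forward model

Monte Carlo particle transport is replaced by an analytic linear model: the
detector image of one slice is the slice activity, inverted through the
aperture centre and scaled by `b/a`, convolved with the mask pattern scaled
by `m(z)`. All resampling is area-weighted (exact pixel-overlap integrals);
nearest-neighbour sampling is excluded because the magnified hole is
comparable to the detector pitch. Near-field obliquity multiplies the
summed image by `cosⁿθ` (default n = 3) measured from the source-plane
centre. Detection is per-pixel Poisson; the 1 mm Gaussian detector position
response is applied to the expected intensity before sampling so counts
stay integer (mean statistics are identical to blurring after sampling).
Energy windowing and crystal physics collapse into the detected-count
budget. The fraction of emissions forming the image is the geometric
efficiency: `min(mask, detector)` solid angle × open fraction — so a mask
of equal open fraction but four times the area collects four times the
counts, which is the mosaic's sensitivity advantage over the plain base
pattern.

The forward model is validated against an independent per-ray oracle
(source point → mask-plane crossing → detector, integrated by
sub-sampling) to a relative L2 error below 2% on a 10×10-element mask with
an extended source, together with exact linearity, shift-equivariance
(object shift Δ moves the image by −(b/a)Δ) and support checks.

## Near-field correction

Oblique near-field illumination superimposes a smooth `cosⁿθ` envelope on
the shadow texture; decoding a modulated projection loses contrast.
`analytic` mode divides by the known envelope (exact in simulation);
`envelope` mode divides by a heavily smoothed copy of the projection
(kernel far above the element-shadow scale; geometry-free, for external
data). Both renormalise to preserve the projection mean and cannot create
negative values. On the simulator, correcting a point-source projection
before reconstruction roughly doubles the reconstructed point's
contrast-to-background ratio; only the direction of that improvement is a
claim, not the magnitude.

## Reconstruction

Each slice is estimated independently from the single projection by MLEM
with that slice's magnified mask shadow as PSF — multiplicative EM updates
with strictly positive uniform initialisation (MLEM preserves zeros), an
epsilon guard of 1e−12 in the ratio, and linear zero-padded FFT
convolutions. Two system models are supported: the *valid-support* model
(estimate grid = detector − PSF + 1; constant sensitivity) and the
*truncated-detector* model (estimate grid chosen freely, forward =
crop(conv), adjoint = pad + correlate, spatially varying sensitivity;
pixels whose shadow never reaches the detector are held at zero). Both are
verified per-iteration (max relative deviation < 1e−6) against explicit
dense system-matrix MLEM on 8×8 toys, and against a direct constrained
optimiser of the Poisson likelihood; the likelihood is checked
non-decreasing and the truth is a fixed point of exact data.

The mask/antimask technique reconstructs the projection twice — once with
the mask shadow, once with the rotated shadow — and subtracts the antimask
volume from the mask volume after the final iteration, clipping at zero
(both branches remain accessible). Because the rotated pattern of a
3-mod-4 MURA has no coding gain, the antimask branch can only absorb the
smooth multiplexing background, and the subtraction removes that
background while the coded object survives. An alternative update that
keeps the mask in the forward model and backprojects with the rotated
pattern (the form the printed update equations suggest) is available as
`antimask_update="mismatched"`; it behaves like a correlation-style
anti-decode at low iteration counts but has no EM convergence guarantee
and is not the default.

The mosaic's shadow is periodic with one base period `p·hole·m(z)`, so a
truncated acquisition leaves ghost "partial copies" of the object at
±one-period offsets. `fold_partial_copies` tiles the slice into
period-sized cells around the centre and sums them (exact total
conservation; optional coverage weights turn the sum into a mean). The
ghosts are a property of the unresolved ambiguity: on this simulator they
are strong early in the EM trajectory (≈15% of a point-source peak at 5
iterations, at exactly the predicted offsets) and are resolved by the
matched linear decode at convergence, so folding reliably raises a
point-source peak but adds little to a converged lesion slice (see
Limitations).

Iteration count defaults to 200 in the library, the reference protocol's
value. The *study* default is 50: reconstruction cost scales linearly in
iterations, and beyond ~100 iterations the background-suppressed
difference image's annulus becomes exactly zero, which makes ratio metrics
degenerate (reported as infinite contrast with a flag).

## Image-quality metrics

CBR = (mean over a lesion-sized disk − mean over a concentric annulus at
2–4 lesion radii, clipped to the breast support) / annulus mean, on the
lesion-depth slice, with ROIs derived from the known phantom geometry
(sub-pixel lesion radii are clamped to 0.8 px so the disk is never empty).
MSE is the mean squared difference to the ground-truth activity slice
resampled to the reconstruction grid and scaled to the reconstruction's
total intensity; PSNR = 10·log₁₀(peak²/MSE) with peak the (scaled)
reference maximum, so PSNR is invariant to the common scale.

## Reduced-scale study configuration

The default `RunConfig` keeps the reference distances, breast, TBR, dose
and acquisition time, and scales the mask/detector so a full study runs in
minutes on one CPU: rank 19 mask with 3 mm elements (19 ≡ 3 mod 4, two
resolution elements across the 8 mm lesion, integer 57 px partial-copy
period), 664 mm detector at 4 mm pitch, reconstruction field 664 mm,
detected budget 10⁷ counts for the mosaic system (other masks receive
counts in proportion to their own geometric efficiency), 50 MLEM
iterations, analytic NFC. The full-scale rank-83 / 1 mm-hole / 1 mm-pitch
system is reachable purely through configuration. The non-mosaic
comparison uses the rank-19 base pattern with the same hole size — the
mosaic extension simply omitted — so it has half the side and a quarter of
the open area and counts.

## What the simulations do and do not show

The synthetic study emulates count-limited single-view acquisition,
depth-dependent magnification, near-field modulation and Poisson noise. It
does **not** emulate scatter, septal penetration, attenuation in tissue,
backscatter, detector energy response, or anthropomorphic tissue-uptake
heterogeneity, and the desk-scale mask has a ~9 mm object-plane resolution
element against the full system's 1.33 mm. Passing tests therefore
establish internal correctness of the algorithms and the *direction* of
effects on this simulator, not clinical detectability.

Three documented divergences from the reference behaviour remain, all
rooted in the same structure. Under matched linear-deconvolution decoding,
(1) the mask/antimask difference images are background-suppressed
(near-sparse), so their ROI-mean CBR is inflated and their total-matched
MSE deflated relative to the background-retaining mask-only image —
technique orderings that interleave the two families only partially
reproduce; (2) image-quality-vs-lesion-size trends for the difference
technique are dominated by the shrinking lesion-region error rather than
by reconstruction noise, inverting the expected MSE/PSNR trend while the
CBR trend (monotone decrease from 8 to 3 mm) does reproduce; (3) a
converged matched decode resolves the partial-copy ambiguity, so folding
helps point sources and early-iteration images but not the converged
lesion slice. A periodic-correlation decoder — under which a non-mosaic
mask fails catastrophically and ghost copies persist — would reproduce the
reference orderings, but linear decoding is the deliberate design choice
here: it is the physically correct model of the simulated acquisition and
is the variant whose estimator properties (likelihood monotonicity, oracle
equivalence, count conservation) can be guaranteed and tested.

## Numerical details

* Area-overlap resampling matrices are separable and exact; the default
  output grid is the smallest centred grid covering the input extent
  (aligned grids resample bit-exactly).
* FFT convolutions use scipy's `fftconvolve` (zero-padded to the linear
  size); cyclic wraparound never enters the decode.
* Degenerate inputs: all-zero PSFs, negative counts/activities, non-prime
  ranks, out-of-range slices, lesions that do not fit, zero body volume
  and empty phantoms are rejected with specific messages; an all-zero
  projection yields the zero (still constant) estimate, which is the ML
  limit.
* Determinism: every stochastic stage draws from `numpy` Generators seeded
  from a single study seed via `SeedSequence.spawn`; a study rerun with
  the same config reproduces its JSON report byte-for-byte.
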