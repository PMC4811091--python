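# Methods

## Problem

Compressed-sensing MRI reconstructs an image x from a randomly
undersampled k-space acquisition

    y = U x + e,

where U is the composition of the unitary 2-D discrete Fourier
transform with a binary sampling mask (acceleration factor R means a
fraction 1/R of samples is kept), and e is complex white Gaussian
noise on the kept samples. Writing W for the inverse sparsifying
transform and Q = U W, reconstruction is posed as the l1-regularized
least-squares problem

    w* = argmin_w  ||y - Q w||_2^2 + lambda ||w||_1,    x* = W w*.

All images live on the 8-bit display scale [0, 255]; PSNR uses peak
255 throughout.

## Solvers

The iterative shrinkage-thresholding update is

    w <- Gamma_{2 lambda / J}( w + (2/J)(a - A w) ),
    a = Q^H y,  A = Q^H Q,

with the shrinkage operator Gamma_b(z) = sgn(z)(|z| - min(b/2, |z|))
(soft thresholding with dead zone b/2) and a step constant
J >= 2 lambda_max(Q^H Q). Under unitary FFT normalization U^H U is an
orthogonal projector, so for orthonormal wavelets lambda_max = 1 and
J = 2 is tight; for biorthogonal wavelets lambda_max is estimated by
power iteration and J is inflated by 5%. With a valid J the update is
a majorization-minimization step, so the cost trace is non-increasing
(asserted in the tests). FISTA adds the standard Nesterov momentum
sequence t_{n+1} = (1 + sqrt(1 + 4 t_n^2))/2 over the same shrinkage
step and is included purely as a baseline.

The composite solver interleaves, per iteration:

1. a Landweber data-consistency step in image space,
   r = x + (2/J) Re U^H (y - U x);
2. a fresh uniform random circular shift of r (cycle spinning);
3. the exponential wavelet transform (below) with k rounds;
4. soft thresholding of the exponential-domain coefficients;
5. the exact inverse transform and the inverse shift.

For an orthonormal wavelet, no shift and no exponentiation the loop
body is algebraically the linear ISTA update (unit-tested). The image
estimate is kept real (magnitude images), and the initialization is
the magnitude of the zero-filled reconstruction clipped to [0, 255].

## Exponential wavelet transform

One round maps wavelet coefficients w through

    v = |w| / max|w|  in [0, 1],    w <- sgn(w) (e^v - 1)/(e - 1),

and k rounds iterate this, each recording its normalization maximum
for exact inversion. The scalar map is increasing and convex on
[0, 1] and fixes 0 and 1, so large-magnitude coefficients are
enhanced relative to small ones while magnitude ranks and signs are
preserved; the Gini sparsity index of the coefficient magnitudes can
only grow (a convex increasing map fixing 0 is Lorenz-dominating).

Two design points matter and were genuinely open:

* **Signs are carried through the normalization.** The shrinkage
  operator contains sgn(z), which is meaningful only on a signed
  domain, and "thresholding toward zero" must mean toward a zero
  wavelet coefficient. A signed affine min-max normalization instead
  anchors the domain's zero at the most negative coefficient;
  thresholding then drags every coefficient toward that extreme and
  the reconstruction collapses (we measured ~4-5 dB PSNR versus
  ~23 dB for plain ISTA at acceleration 5). Magnitude normalization
  with sign restoration is the reading under which the method works.
* **The normalization is anchored at zero** (divide by the global
  maximum magnitude) rather than min-max on magnitudes: with a
  nonzero minimum, the smallest-magnitude coefficient maps exactly to
  zero and its sign is irrecoverable, breaking exact inversion.

* **The threshold is expressed on the raw coefficient scale and
  pushed through the same normalize+exp chain** (`ewt_scalar`). The
  dead zone is then the same set of raw coefficients as ISTA's for
  every k, while coefficients above it lose far less than ISTA's
  uniform lambda/J subtraction — harsher on small coefficients,
  gentler on large ones, a firm-thresholding-like profile. A
  threshold fixed in exponential-domain units instead grows its dead
  zone like (e-1)^k and destroys the image.

Inversion clips magnitudes to [0, 1] before the log map; shrinkage
only moves magnitudes toward zero inside the valid range, so the clip
removes floating-point overshoot only.

Because the inverse is exact to ~1e-9, increasing k monotonically
sharpens the shrinkage profile and the PSNR-versus-k curve rises and
saturates (typically flat beyond k ~ 6-8). An interior maximum, as
reported for implementations whose inversion error accumulates with
k, does not arise here; the k-sweep driver records an `interior_max`
flag so a boundary argmax is visible for review rather than silently
accepted or failed.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| lambda | 0.01 * max\|Q^H y\| | fidelity/sparsity trade-off; scale-adaptive so thresholds are commensurate across images ("coefficient normalization"); overridable |
| J | 2 (orthonormal), 2*1.05*power-iteration (biorthogonal) | majorizer constant; unit projector norm makes 2 tight |
| k | 6 | exponentiation rounds; curve saturates near here |
| wavelet | bior4.4, 5 levels | best performer in the wavelet comparison |
| max_iter | 100 | fixed iteration budget; tol=0 disables early stop |
| acceleration | 5 | kept fraction 0.2 |
| noise sigma | 0.01 | per real/imag component on kept k-space samples; whether the source convention is on a [0,1] or 8-bit scale is ambiguous, so it is exposed as a free parameter |

## Synthetic phantoms

Clinical images are not distributed, so experiments run on generated
phantoms (power-of-two sizes so multi-level periodized wavelet
decompositions are exact, which also makes circular shifts commute
with the transform):

* `shepp_logan`: the classical piecewise-constant head phantom,
  resampled and rescaled to [0, 255];
* `piecewise_texture` (default): elliptical tissue compartments with
  partial-volume-smoothed boundaries (edge width ~min(H,W)/96), a
  smooth multiplicative +/-15% bias field emulating coil-sensitivity
  inhomogeneity, and seeded band-limited texture (correlation length
  ~2 px) inside tissue. The default texture amplitude is 80 gray
  levels (~30% local contrast): texture whose detail coefficients sit
  inside the solvers' default dead zone (~lambda/J, about 15 gray
  units in coefficient scale) would be deleted identically by every
  method, and the fixture would not test textured-tissue
  reconstruction at all.

What the phantoms do not emulate: coherent anatomy (sulci, vessels),
Rician noise statistics of magnitude images, partial Fourier or
multi-coil acquisition. Passing orderings on these phantoms show the
mechanism works under controlled piecewise-smooth + texture + bias
conditions, not that the specific dB values transfer to clinical data.

## Sampling schemes and experiment design

Three mask schemes share the invariants "kept fraction within 10% of
1/R" and "DC always kept": variable-density random phase-encode rows
(Gaussian density, sigma = H/4), pseudo-radial spokes, and uniform
random samples; all hit their target count exactly (rows or samples
trimmed/topped up at random). Masks are DC-centered; operators apply
fftshift at the boundary.

The solver comparison, shift study and k-sweep run on the default row
scheme. The wavelet comparison defaults to radial masks: under row
undersampling the across-seed PSNR spread (~13 dB; some row draws
leave unrecoverable stripe aliasing) is an order of magnitude larger
than the ~0.5 dB wavelet effect, so a row-mask wavelet comparison
measures mask luck; radial masks hold the per-seed spread near 0.1 dB
and resolve the transform effect. Under radial masks db1 (Haar) is
consistently the worst wavelet on the textured phantom; under row
masks it is often the most robust to stripe aliasing — an instructive
interaction between sampling geometry and basis choice.

Problem sizes: unit tests use 64x64 phantoms; the ordering
experiments and the acceptance script use 128x128 with 100
iterations and small seed panels (5 seeds for solver ordering, 10
for the shift study, 3 for the sweeps), which resolves the reported
orderings while keeping full runs to a few minutes.

## Numerical choices

* Unitary FFT normalization everywhere; operator norms are
  scale-free and the adjoint identity holds to ~1e-15.
* Periodized (circular) DWT boundary handling: perfect reconstruction
  for all six supported wavelets and exact commutation with circular
  shifts.
* Degenerate inputs: constant coefficient sets normalize to zero with
  a unit-range guard; sgn(0) = 0; PSNR of identical images is +inf.
* Metrics clip both images to [0, 255] before comparison (8-bit peak
  convention; solver overshoot would otherwise make PSNR
  incomparable across methods).
* Determinism: every stochastic component (phantom texture, mask,
  noise, shifts) is seeded independently; reruns are bit-identical,
  and solver results carry their full config and shift log.

## Known limitations

* Single-coil, Cartesian-grid simulation only; no gridding,
  SENSE/GRAPPA, or non-Cartesian trajectories.
* The biorthogonal case uses the forward DWT as a surrogate for the
  true adjoint in a = Q^H y (standard CS-MRI practice); cost
  monotonicity is only guaranteed for orthonormal wavelets.
* The cost trace of the composite solver is evaluated with the
  linear-wavelet l1 norm so curves are comparable across solvers; it
  is not the objective the nonlinear iteration descends.
* Absolute PSNR values depend strongly on the mask draw under row
  undersampling; orderings are therefore always reported as means
  over seed panels.
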