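# Methods

## The problem and the model

Confocal Raman microscopy of plant tissue sections produces hyperspectral
images: a grid of pixels, each carrying a Raman spectrum over a wavenumber
axis. Because plant cell walls are multicomponent nanocomposites (cellulose
microfibrils in a matrix of hemicelluloses, pectins and lignin), individual
bands overlap heavily and univariate band integration is often ambiguous.
Spectral unmixing instead describes the whole image with a bilinear model

    D = C S,        D: n_pixels x m,  C: n_pixels x p,  S: p x m

where the rows of `S` are *endmember* spectra (approximations of pure
component signatures) and the columns of `C` are their per-pixel abundance
maps. All solvers in this package operate on this model with non-negativity
as the central constraint. Pixels are stored row-major; the wavenumber axis
ascending; the bilinear factors follow the dimension convention above
throughout (some presentations of the model state other orientations;
this package fixes one and converts at the boundary).

## Solvers

**VCA** (vertex component analysis) assumes every pixel lies in the simplex
spanned by the endmembers and that each component has at least one pure
pixel. The data are projected onto a signal subspace — onto the top-`p`
right singular subspace with projective scaling when the estimated SNR
exceeds `15 + 10 log10(p)` dB, otherwise mean-centered onto `p-1`
dimensions with an appended constant coordinate — and vertices are found
sequentially: a seeded random direction is orthogonalized against the span
of the vertices found so far and the pixel with the largest |projection| is
selected (ties broken toward the lowest pixel index; a duplicate selection
redraws the direction, at most 100 times). Endmember spectra are the
selected pixels' raw spectra. Abundances are per-pixel non-negative least
squares followed by renormalization to unit row sum (`nnls_closure`,
default) or equality-constrained least squares (`closure_only`). Rows
summing to zero receive a uniform `1/p` row and are flagged.

**NMF** minimizes the squared Euclidean cost with the classic
multiplicative updates, which keep both factors non-negative and make the
cost non-increasing at every iteration. Missing entries are handled by a
boolean mask (True = observed): numerators and denominators of the updates
are computed over observed entries only. Factors are initialized from a
seeded uniform(0,1) draw scaled by `sqrt(mean(D)/p)`. Because the problem
is non-convex, several seeded restarts are run and the best final cost
kept; restarts first run a burn-in (`iterations/10` by default), after
which only the `keep_best` (default 2) most promising trajectories continue
to the full budget. A continued trajectory is identical to an uninterrupted
run (the RNG is used only at initialization), so the monotone-descent
guarantee applies to the whole trace. The default budget of 100,000
iterations reflects how slowly multiplicative updates converge on imaging
data; the desk-scale benchmarks in this repository use 4,000–16,000
iterations with an early stop at 1e-9 relative cost change, which the
recovery benchmarks show is sufficient at their problem sizes. At report
time `S` rows are scaled to unit maximum with `C` rescaled inversely
(the product is unchanged).

**MCR-ALS** alternates exact non-negative least squares in both directions:
per pixel against the current spectra, per channel against the current
abundances. The NNLS subproblems are solved exactly (active-set enumeration
over all 2^p sign patterns with KKT verification, vectorized over pixels or
channels, QR-based subset solves; `p <= 12`), never by clipping a
least-squares solution. After each spectral step the rows of `S` are scaled
to unit Euclidean norm and `C` rescaled inversely. Convergence is tracked
by the lack of fit against a reference matrix: the rank-`p` truncated-SVD
reconstruction of the data when `pca_filter` is on, the raw data otherwise;
the iterate with the best LOF is kept and iteration stops when the relative
LOF change drops below `tol` (default 0.1%, a conventional stopping rule)
or after `max_iter` (default 50). Results always additionally report the
LOF against the raw data so filtered and unfiltered runs are comparable.
Initialization defaults to the (seeded) VCA endmembers, making the pipeline
deterministic end to end; a determinant-based purest-variable selection and
user-provided spectra are alternatives. A component whose abundance or
spectrum collapses to zero is re-seeded once from the largest-residual
pixel; a second collapse is an error.

## Model statistics

For residuals `E = D_ref - C S`:

    LOF (%) = 100 * sqrt( sum(E^2) / sum(D_ref^2) )
    r^2 (%) = 100 * ( 1 - sum(E^2) / sum(D_ref^2) )

Both are computed from the same residual matrix, so
`r^2 = 100 - LOF^2/100` holds identically; the package verifies this
identity against published LOF/r^2 pairs for spruce and Arabidopsis
unmixing models. Endmembers are compared by Pearson correlation of their
raw spectra (affine invariance makes pre-normalization unnecessary) and
matched across methods by the permutation maximizing total spectral
correlation — exhaustive for `p <= 8`, with abundance-map correlation as
tie-break, then lowest index; beyond 8 a greedy assignment with a warning.
Rank selection support is a singular-value scree whose suggested rank
counts values above `3 x median(trailing half)`, floored at `1e-8` of the
leading value to handle exactly low-rank data; this is a heuristic for
map-like matrices (pixels >> channels), not a test statistic.

## Synthetic scenes

No real spruce/Arabidopsis maps are distributed, so a generator produces
ground-truthed stand-ins with the statistical structure the analysis
assumes: non-negative bilinear mixtures plus a smooth component-dependent
background, signal-dependent noise and occasional cosmic-ray spikes.

* **Component library.** Seven components built from Gaussian (and
  optionally Lorentzian) bands at the standard plant cell wall positions:
  lignin (1600, 1660, 1140, 1270 cm^-1), a coniferyl-type lignin with a
  1634 cm^-1 shoulder, cellulose (1121, 1095, 380 cm^-1), an
  orientation-enhanced cellulose (intensity redistributed into 1095 and
  the 370–550 cm^-1 region, as under polarization parallel to the
  microfibrils), pectin (855 cm^-1 glycosidic band), protein/lipid (1666,
  1450, 1005 cm^-1) and water (a low, very broad OH-bending/librational
  contribution). Band heights and widths (12–30 cm^-1 FWHM) are free
  modelling parameters chosen for realistic overlap, not claims about any
  particular instrument; spectra are unit-maximum normalized.
* **Layouts.** `spruce`: tiled square tracheid cells — lignin-rich cell
  corners and compound middle lamella, an orientation-enhanced S1 ring, a
  lignin+cellulose S2 body, water-filled lumina. `arabidopsis`: a
  lignified-xylem zone with coniferyl-enriched cell corners near the
  cambium, a pectin-rich primary-wall (cambium/phloem) zone with
  protein/lipid deposits, and lumina. `simplex`: abundances uniform on the
  simplex with `k` planted pure pixels. `lowvar_water`: nearly
  one-dimensional plant material with a weak water component (amplitude
  0.06 of the plant scale) confined to a small lumen — spectrally distinct
  (|r| < 0.3 to the other components) but below 1% of image variance.
* **Truth invariants.** Abundance rows sum to one exactly; one pure pixel
  per component is planted by default (the pure-pixel assumption VCA
  needs; switchable off); region masks, true spectra and abundances,
  background and spike positions are stored with the scene.
* **Noise and background.** Noise is additive Gaussian with variance
  proportional to the local deterministic signal (a shot-noise surrogate
  for CCD detection), calibrated so that the realized RMS signal-to-noise
  equals the requested `snr`; counts are floored at zero as on a detector.
  The background is a per-pixel cubic polynomial whose amplitude is the
  abundance-weighted sum of per-component `baseline_gain` values —
  different chemical components drag different backgrounds, which is what
  makes the baseline-subtraction experiments informative. Spike counts are
  a Binomial(n_pixels*m, spike_rate) draw with amplitudes 8–20x the image
  maximum.
* **Default axis.** 300–1800 cm^-1 in 4 cm^-1 steps (376 channels),
  matching the fingerprint window used for such maps and a realistic
  spectral resolution; benchmark grids are 36x36–60x60 pixels. These are
  the package's desk-scale defaults; real instrument maps are larger.

What passing tests on these scenes do **not** show: performance on real
tissue (real spectra are not sums of a handful of analytic bands; real
backgrounds are not exact cubics; real noise has structured components such
as CCD readout stripes), robustness to wavenumber miscalibration, or
behavior when the pure-pixel assumption fails badly.

## Pre-processing

* **Crop**: channels with `lo <= wavenumber <= hi` (inclusive), default
  300–1800 cm^-1.
* **Despike**: an entry is flagged iff its residual against the median of
  its spatial-spectral neighborhood (radius 1 pixel, 2 channels; the entry
  itself excluded; mirror padding spatially, NaN padding spectrally so a
  boundary channel never neighbors its own reflection) exceeds
  `threshold` (default 8) robust scales. The robust scale is 1.4826 x MAD
  floored at a quarter of the neighborhood maximum and at 1% of the mean
  image intensity — cosmic rays tower over everything nearby, while band
  intensities at sharp tissue boundaries and shot-noise tails in
  near-empty regions do not. Flagged entries are repaired by linear
  interpolation along the spectral axis, and the pass repeats (up to 5
  times) until no new flags appear, so adjacent spikes cannot mask each
  other. The instrument software's exact criterion is undisclosed; this is
  a documented dialect of the same neighborhood idea.
* **Baseline**: per-spectrum iterative peak-excluding polynomial fit
  (default order 3): fit by least squares on a conditioned axis, replace
  points above the fit by the fit, repeat until no point moves by more
  than 1e-6 of the spectrum range (or 100 passes), subtract the final
  polynomial. The procedure is positively homogeneous
  (`baseline(a*x) = a*baseline(x)`). Whether the instrument's fit is
  per-spectrum global or node-anchored is undocumented; the global
  iterative variant is adopted as a dialect. Negative residual intensities
  are kept by default and clipped (with a mass report) only for NMF, which
  requires non-negative data.

## Numerical choices and degenerate inputs

* Batched NNLS: feasibility tolerance 1e-9 relative to the solution scale,
  dual-feasibility tolerance 1e-10 relative to the Gram/right-hand-side
  scale, candidate replacement only for relative objective improvements
  above 1e-12; columns that no enumerated active set satisfies fall back to
  a Lawson–Hanson solve. These tolerances keep fixed-point reconstructions
  at machine precision while remaining robust to near-degenerate ties.
* SVD sign convention: each singular vector's largest-|entry| component is
  made positive, making VCA equivariant under pixel permutations.
* Multiplicative updates guard denominators with epsilon 1e-12; zero rows
  or columns therefore decay but never divide by zero.
* All-zero pixels, constant spectra and constant abundance columns are
  flagged rather than silently producing NaNs (uniform abundance rows,
  zero correlation entries, zero-filled maps respectively).
* Determinism: every stochastic stage takes a seed; scene generation,
  VCA, NMF and the pipeline are bitwise reproducible for a fixed seed.

## Known limitations

* MCR-ALS converges slowly (geometric, ~5%/iteration) on dense mixtures
  without pure rows; the default 50 iterations target imaging data where
  VCA provides a good initialization.
* NMF identifiability on heavily overlapping spectra is limited by
  rotational ambiguity; best-of-restarts mitigates but does not remove it.
* The despike floors assume spikes far exceed local signal; spikes below
  ~2x their brightest neighbor are not flagged.
* The rank-scree heuristic assumes map-like aspect ratios; on square-ish
  pure-noise matrices the Marchenko–Pastur bulk defeats the trailing-half
  median floor.
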