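# Methods

This note documents the models, conventions, parameter choices and known
limitations of `livefish`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and unit conventions

Pixels are 0-based; a spot "at pixel (i, j)" is centered at the center of
that pixel; `x` runs along columns, `y` along rows; `nm = px ·
pixel_size_nm`.  All serialized physical quantities are in nm and seconds;
pixel-unit columns carry a `_px` suffix.  Defaults encode the target
acquisition geometry: 160 nm/pixel, 3 frames/s.

## Fractional Brownian motion generator

Chromatin-locus motion is modelled as 2D fractional Brownian motion with
the convention

    MSD_2D(t) = D_app · t^α,   two axes contributing equally,

so each axis is an independent fBm with one-step variance
`(D_app/2)·dt^α` and `D_app` carries units nm²/s^α.  Increments are drawn
*exactly* by Cholesky factorization of the Toeplitz covariance

    γ(k) = (σ²/2)(|k+1|^α − 2|k|^α + |k−1|^α),

which makes the generator usable as its own oracle: the sampled covariance
is correct to machine precision at every lag, not asymptotically.  The
O(n³) factorization restricts trajectories to ≤ 2048 positions — ample for
minutes-long acquisitions at 3 fps — and longer requests are rejected
rather than silently approximated.

`D_app` defaults to 10⁴ nm²/s^α (i.e. `MSD_2D(1 s) = 0.01 µm²`), a typical
magnitude for interphase chromatin loci; it is a simulation default, not a
fitted constant.

## Camera forward model

Spots are rendered as **pixel-integrated** Gaussians (error-function
quadrature over each pixel), not point samples: at 160 nm/px the PSF σ of
~1.3 px makes the difference measurable.  Pixel values follow

    counts = offset + gain · Poisson(signal + background) + N(0, read_noise),

clipped to uint16.  The EM gain is a plain multiplier; the EM-CCD
excess-noise factor, photobleaching, 3D defocus and nuclear-shaped
backgrounds are deliberately not modelled — the simulator exists to
validate the analysis chain, and these omissions mean passing tests bound
performance under ideal-camera assumptions, not under every real-world
pathology.  A `deterministic` mode replaces the noise by its expectation
(float image, no quantization) for exactness tests such as photon
conservation.

**Photon budget.**  The real photon counts per locus are not published, so
the default (`photons_per_spot = 330`, background 20 photons/px, gain 2,
read noise 2 counts) was calibrated with the package's own localization
module so that the empirical single-frame precision lands at ~26–27 nm per
axis, the reported scale for this kind of acquisition; the calibration is
recorded here and asserted (with a generous band) in the test suite.  The
resulting peak-pixel SNR is ≈ 7.

## Detection and localization

Band-pass = difference of Gaussians with defaults `low_sigma = 1 px`,
`high_sigma = 4 px`; candidates are local maxima above
`mean + 5·(1.4826·MAD)` of the filtered frame with minimum separation
`ceil(2·low_sigma)`.  The original acquisition software's kernel is not
available; these are declared defaults, standard for diffraction-limited
puncta at this pixel size, and configurable.

The Gaussian fit uses Levenberg–Marquardt least squares (tolerances 1e-8,
≤ 200 iterations per parameter), initialized from the candidate pixel, the
ROI-border median (background), peak-minus-background (amplitude) and the
band-pass low sigma (widths).  Acceptance filters: 0.3 px < σx, σy < 3 px,
center inside the 9×9 ROI, amplitude > 3× the robust border-noise SD;
edge-clipped ROIs are skipped.  Rejection counts are logged.  Rare noise
maxima that pass the detection threshold are removed by the amplitude
filter, which is why detection precision is quoted after the fit stage.
Localization is least-squares throughout (no Poisson MLE variant).

## Registration

The chromatic map is a quadratic polynomial per output axis.  Coordinates
are centered and scaled to [−1, 1] before fitting (raw second-order
monomials on a 512-px field are ill-conditioned); the normalization is
stored with the model and an exact affine-substitution expansion exposes
raw-basis coefficients for comparison with simulation ground truth.

Directionality: the physical distortion maps reference-channel coordinates
to moving-channel coordinates, and the analysis model maps moving →
reference.  `fit_warp(src, dst)` is therefore generic in direction; the
analysis pipeline fits moving → reference, whose quadratic approximation
of the inverse distortion is exact to well below 1 nm at realistic
distortion magnitudes (~1 px translation, 0.1% linear, 10⁻⁶ px⁻¹
quadratic terms).

Bead matching is mutual nearest neighbor after removing the median
inter-channel displacement (without this pre-alignment, a chromatic offset
comparable to the closest bead spacings cross-matches a few percent of
beads and visibly inflates the registration error).  Registration accuracy
is reported both in-sample and leave-one-out (hat-matrix identity, no
refit loop); the cross-validated number is the honest accuracy on new
points and is the one to quote.  With one-sided bead noise σ the expected
LOO r.m.s. per axis is `σ·√(1 + 6/n)`; with both channels noisy it
approaches `σ√2` as n grows.  The reference channel is by convention the
far-red one.

## Distances

Pairing is per-frame mutual nearest neighbor with a 1.5 µm default cap
(beyond the largest separations of interest); the pooled summary (over
frames × loci) is what headline mean ± SD numbers refer to, and per-locus
grouping is available for independence-aware analysis.  Histogram default:
50-nm bins, 0–1200 nm.  For coincident loci the measured distance is
Rayleigh with per-axis scale `σ_eff² = σ_ch1² + σ_ch2² + σ_reg,axis²`,
giving mean `σ_eff·√(π/2)` — the quantitative anchor for dual-tag
controls.  Summaries are computed on whatever pairs are passed in, so
censored (≤ cap) and uncensored variants are both available to the caller.

## Dynamics

Linking is greedy per-frame mutual nearest neighbor, closest link first
with deterministic tie-breaks, `max_disp = 800 nm/frame` and `max_gap = 2`
frames by default (generous for sub-diffusive loci at 3 fps).

MSD is time-averaged per trajectory over all ordered pairs at each lag,
gaps excluded pairwise, lags up to half the trajectory span by default.
The localization-error correction subtracts a constant estimated from a
dual-tag control: the difference coordinate of the two colors cancels the
true motion, its MSD plateaus at twice the per-channel error MSD, and half
the plateau (averaged over lags 1–10) is the per-channel constant — equal
to `4σ²` for per-axis noise σ in both channels.  The equal-channel-error
assumption is documented and tested: a one-sided noise budget biases the
constant by a factor of 2.  Negative corrected values at small lags are
excluded from log-log fits and logged.

Power-law fits are ordinary least squares of log MSD on log τ over
0.33–10 s by default, per trajectory, with the ensemble exponent reported
as the unweighted mean ± SE across loci (the ensemble-averaged-MSD fit is
also available; the two can differ slightly because time-averaged MSDs of
short tracks fluctuate at long lags, which also imparts a small downward
bias of order 0.01 on per-track exponents at 200-frame lengths).

The velocity ACF uses `v(t) = (r(t+δ) − r(t))/δ` and equal-weight ensemble
averaging of `C_v(τ)` with normalization by the ensemble's own `C_v(0)`.
For fBm the closed form `C_v(τ)/C_v(0) = (|u+1|^α − 2|u|^α + |u−1|^α)/2`,
`u = τ/δ`, predicts the negative dip `2^{α−1} − 1` at `τ = δ` and
δ-independence on the rescaled axis; both are used as oracles.  δ is a
required parameter (no universal default is meaningful).

## Pipeline

A single seed is expanded into independent per-stage streams
(`numpy.random.SeedSequence.spawn`), recorded in the manifest; identical
(config, seed) runs produce byte-identical artifacts, verified by SHA-256
in the manifest.  Stages read only their predecessors' serialized outputs,
so any stage can be re-run in isolation.

## Problem sizes used in tests and benchmarks

The test-suite and benchmark ensembles (e.g. 5–10k short fBm trajectories
for covariance oracles, 10⁵ pairs for the Rayleigh control, 31/15
trajectories of 200 frames for exponent recovery, ≤ 10 spots per 128×128
frame for detection metrics) are the package's chosen verification sizes:
large enough that Monte-Carlo standard errors are small against the
asserted tolerances, small enough to keep the whole suite fast.  Exponent
recovery at these ensemble sizes has an intrinsic seed-to-seed spread of
~0.02 (SD of the ensemble mean), which the quoted tolerances accommodate.

## Known limitations

No 3D localization or astigmatism; no drift correction over time (bead
calibration treated as static); no motion-blur within exposures; no
hidden-state motion classification or confinement-radius models; the
simulator's camera and background are idealized as described above.
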