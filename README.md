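# livefish

Quantitative analysis of two-color live-cell genomic-locus imaging.

CRISPR/dCas9-based live-cell FISH tags endogenous genomic loci with
fluorescent ribonucleoprotein complexes, producing movies of
diffraction-limited nuclear puncta in one or more color channels.  Turning
those movies into biology — how far is an enhancer from its target gene,
how sub-diffusive is a chromatin segment — requires a chain of quantitative
steps well below the optical resolution limit.  `livefish` implements that
chain for microscopists and chromatin biophysicists:

1. **Spot detection** — local maxima of band-pass (difference-of-Gaussians)
   filtered, background-subtracted frames.
2. **Sub-pixel localization** — non-linear least-squares fit of an
   elliptical 2D Gaussian, `A·exp(−(x−x₀)²/2σx² − (y−y₀)²/2σy²) + B`,
   reaching ~27 nm per-axis precision at realistic photon budgets.
3. **Chromatic registration** — a second-order polynomial warp
   `x' = Σ cₖ·mₖ(x, y)` over the monomials `(1, x, y, x², xy, y²)`,
   calibrated on multicolor fiducial beads, with leave-one-out
   cross-validated accuracy reporting.
4. **Two-color distances** — per-frame mutual-nearest-neighbor pairing and
   Rayleigh-aware distance statistics (for coincident loci the measured 2D
   distance has mean `σ_eff·√(π/2)`).
5. **Chromatin dynamics** — trajectory linking; time-averaged MSD with the
   localization-error correction `MSD_corr(τ) = MSD_obs(τ) − MSD_loc_error`
   where the constant is estimated from a locus tagged simultaneously in
   two colors; power-law fits `MSD_2D(τ) = D_app·τ^α`; and the velocity
   autocorrelation `C_v(τ)` of `v(t) = (r(t+δ) − r(t))/δ`, whose negative
   dip (`2^{α−1} − 1` for fractional Brownian motion) and collapse on the
   rescaled axis `τ/δ` diagnose anti-persistent, self-similar motion.
6. **Synthetic data** — an exact (Cholesky) fractional-Brownian-motion
   generator and a physically explicit camera model (integrated-Gaussian
   PSF, Poisson shot noise, EM gain, read noise, quadratic chromatic warp),
   so every stage of the chain is testable against known ground truth.

## Worked example

Run a fully synthetic two-channel experiment — one dual-tagged sub-diffusive
locus (α = 0.5, `MSD_2D(1 s) = 10⁴ nm²`), a 100-bead calibration field with
10 nm localization noise per channel, a random chromatic warp — and read the
headline numbers off the manifest:

```python
from livefish import RunConfig, run_pipeline

cfg = RunConfig.from_dict({
    "seed": 11,
    "sim": {"image_shape": [96, 96], "n_frames": 40},
    "loci": [{"alpha": 0.5, "d_app": 1e4, "channels": [1, 2],
              "origin": [48 * 160.0, 48 * 160.0]}],
    "beads": {"n_beads": 100, "loc_noise_nm": 10.0, "noise_ref_nm": 10.0},
})
m = run_pipeline(cfg, "demo_run")
```

This prints (via the snippet in the repository's test/demo code):

```
registration: n=100 beads, LOO rms = 14.5 / 13.8 nm per axis, 20.0 nm 2D
dual-tag control: n=40 measurements, mean 2D distance = 47.2 nm (SD 25.0 nm), 100% within 200 nm
```

Reading these numbers: with 10 nm bead noise in *each* channel the
cross-validated registration error per axis approaches the theoretical
noise floor `σ√2 ≈ 14.1 nm`, and the dual-tag control — the same locus
imaged in both colors — shows a mean apparent 2D distance consistent with
the Rayleigh prediction for the combined localization (~27 nm/axis/color)
and registration errors, even though the true separation is exactly zero.
The run directory additionally contains the movies (TIFF), localization
and trajectory tables (CSV), the fitted warp with QC (JSON), MSD and
velocity-ACF tables, and a manifest with SHA-256 hashes of every artifact;
identical `(config, seed)` runs are byte-identical.

The same stages are scriptable from the shell:

```sh
livefish run --config cfg.yaml --out demo_run
livefish detect --tiff demo_run/movie_ch1.tif --out locs.csv
livefish register --ref beads_ch1.csv --mov beads_ch2.csv --out warp.json
livefish dynamics --locs demo_run/localizations_ch1.csv --out-prefix dyn
```

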