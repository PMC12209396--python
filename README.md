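# glandfrac

Pixel-wise **glandular fraction (GF)** estimation for raw ("for-processing")
mammography by Poisson maximum likelihood, with an analytic digital
breast-phantom projector for validation.

Breast density — the proportion of fibroglandular tissue — is both a cancer
risk factor and a masking factor, and regulators now require a quantitative
density estimate alongside the qualitative BI-RADS category. `glandfrac`
estimates, at every detector pixel, the fraction of the ray's path through
the breast that crosses glandular tissue, `GF = t_g / t_breast`, directly
from raw count images. Summing the glandular path lengths over pixels gives
the volume glandular fraction (VGF). Because a microcalcification is a
strong local attenuator, it appears as a GF *excess* in the output map, and
the package also quantifies the contrast-to-noise ratio (CNR) gain this
provides over the raw image.

## The model

A detector pixel measures Poisson counts with expectation

```
Ie = I0 · exp(−μ t) + Sc
```

where `I0` is the flat field, `t` the total traversal length through
compression paddles and breast, and `Sc` the modeled scatter. Estimation is
two maximum-likelihood steps, each a one-parameter Newton–Raphson per pixel:

1. **Scatter removal** — maximize `f(μ) = Im ln Ie − Ie` over the net
   attenuation `μ`; the scatter-corrected image is `Iq = I0 exp(−μ t)`.
   `Sc` comes from a thickness-driven scatter-to-primary ratio (SPR) table:
   `Sc = SPR/(1+SPR) · Im`. With an anti-scatter grid only the remnant
   (~25%) scatter is modeled; this step is optional there.
2. **Glandular fraction** — maximize `g(m1) = Iq ln Ie1 − Ie1` with
   `Ie1 = I0 exp(−μ1 t)` and the four-material composition

   ```
   μ1 = μ_l·j + μ_s·k + μ_a·(1 − k − m1 − j) + μ_g·m1
   ```

   (`j`, `k` the known Lexan-paddle and skin path fractions). The
   paddle-free glandular fraction is `m = m1 · t_total / t_breast`, and
   `VGF = Σ m·t_breast / Σ t_breast`.

The tissue attenuation values `μ_a`, `μ_g` are taken at the beam's
**effective energy** — the monochromatic energy whose mixture attenuation
reproduces the polychromatic beam's equivalent attenuation for a reference
path — which keeps the count-loss error of the single-energy model below 1%
across 2–9 cm breasts.

The validation data come from the package's own projector: a
half-cylindrical compressed breast (skin layers, adipose body, denser
glandular half-cylinder, Lexan paddles, optional 1 mm hydroxyapatite
deposits) ray-traced analytically in cone-beam geometry, with multiplicative
SPR scatter and Poisson counts. Every simulated image carries its exact
per-pixel ground truth.

## Worked example

```python
from glandfrac import ProjectionGeometry, apply_asg, build_phantom, \
    compute_vgf, simulate_projection
from glandfrac.evaluate import study_spectrum
from glandfrac.gf import estimate_gf_from_sim

geom = ProjectionGeometry()                # 70 cm SDD, 1 mm pixels
phantom = build_phantom(thickness=4.0, gf_target=0.3)
img = simulate_projection(phantom, geom, study_spectrum("W/Al"),
                          counts_per_pixel_flatfield=30000, seed=0)
img = apply_asg(img, removal_fraction=0.75, seed=1)

est = estimate_gf_from_sim(img, ref_glandular_fraction=0.3)
interior = img.paths.glandular_interior(erode_px=2) & est.mask
print(est.meta["e_eff"], est.m[interior].mean(),
      compute_vgf(est, img.paths.t_breast).vgf)
```

prints (see `examples/01_simulate_and_estimate.py`)

```
working effective energy : 21.27 keV
mean GF over glandular interior : 0.2786 (truth 0.2782)
per-pixel error : bias +0.03 pp, RMSE 2.40 pp
volume glandular fraction : 0.1581
```

The estimated mean GF matches the traced ground truth to a few hundredths
of a percentage point; the 2.4-point per-pixel RMSE is the Poisson noise
floor at 30 000 flat-field counts per pixel. The VGF is lower than the
interior GF because the glandular cylinder occupies only part of the breast
volume.

The `examples/` directory holds one short script per capability (scatter
removal, effective energy, microcalcification CNR, display-mapping
estimation), and the `glandfrac` CLI exposes `simulate`, `scatter-correct`,
`estimate-gf`, `vgf`, `cnr` and `experiment` subcommands for shell use;
every run writes a replayable manifest.

## Clinical-style input

`glandfrac.io.read_raw_dicom` reads raw monochrome DICOM mammograms,
extracting compressed thickness, kVp and anode/filter from the header with
documented fallbacks and per-field provenance; `estimate_i0_from_background`
recovers the flat field from unattenuated columns, and `make_breast_mask`
restricts estimation to rays that traverse tissue only. Non-breast
structures (e.g. pectoral muscle) are excluded via a user-supplied mask.
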