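# Methods

## Estimation model

Each detector pixel is treated independently. The measured raw counts `Im`
are Poisson with expectation `Ie = I0 e^(−μt) + Sc`, where `t` is the total
traversal length through paddles and breast (slant-corrected per pixel) and
`Sc` is modeled scatter. Two one-parameter maximum-likelihood problems are
solved per pixel by Newton–Raphson on the score:

* scatter removal: `f(μ) = Im ln Ie − Ie`, output `Iq = I0 e^(−μt)`;
* glandular fraction: `g(m1) = Iq ln Ie1 − Ie1`, `Ie1 = I0 e^(−μ1 t)`, with
  `μ1 = μ_l j + μ_s k + μ_a (1−k−m1−j) + μ_g m1`, then
  `m = m1 · t_total/t_breast`.

Both likelihoods share the form `N ln(A e^(−bθ) + S) − (A e^(−bθ) + S)`,
whose stationary point has the closed form `θ* = −ln((N−S)/A)/b`. The
solver starts from the floored closed form (floor: 1 count for the scatter
step) and polishes by Newton–Raphson; the iteration is the general
mechanism and is verified to find the analytic root from arbitrary starts.
Numerical safeguards: Newton steps are taken only where the log-likelihood
is locally concave (elsewhere a damped uphill step is used), steps are
clipped to ±2, a step is halved while it would decrease the likelihood
(with a roundoff-scaled acceptance slack of `1e-9·|f|`), and convergence is
declared when the undamped Newton step falls below `1e-10` (≤50
iterations). Pixels with `Im = 0` are censored; pixels with `Im ≤ Sc` carry
no physical primary signal and are flagged and excluded; `m1 < 0`
("sub-adipose", brighter than pure fat) is allowed and flagged, and `m` is
kept unclipped in the raw raster — clipping to [0, 1] happens only in the
display/VGF view, with a count of clipped pixels reported.

## Scatter model

Generation side: `scatter = SPR(t_breast) × primary`, with SPR a monotone,
linearly interpolated table in breast thickness (0.30 at 2 cm rising to
1.00 at 9 cm, the published gridless mammography range at these energies).
The SPR map may be low-pass filtered (Gaussian, default σ = 1 cm) to mimic
scatter's spatial diffuseness; in the flat interior this changes nothing,
so the estimation-side model stays consistent away from the breast edge.
An anti-scatter grid is modeled as scaling the scatter expectation to a
remnant fraction (default 25%) and re-sampling the Poisson counts.

Estimation side: `Sc = s/(1+s) · Im` with `s = g · SPR(t_breast)`, `g` the
grid's scatter transmission (1 without a grid). This is the scatter
estimate consistent with the measured totals under the multiplicative
model. For grid acquisitions the pipeline still runs the scatter step with
the remnant `s` by default (`scatter_mode="model"`): the remnant is known
and leaving it unmodeled would bias `m` upward of 5 points at the bundled
SPR levels. `scatter_mode="skip"` reproduces the conventional treatment of
feeding a grid image directly to the GF step, which is adequate when the
remnant scatter is small.

A consequence of the idealized multiplicative model worth knowing: the
gridless correction is the exact rescale `Iq = Im/(1+s)`, so scattered
counts effectively contribute signal and the gridless branch is slightly
*less* noisy than the grid branch here. In real systems scatter carries
essentially no primary information and the ordering reverses; error
comparisons between the two branches on this simulator should not be read
as statements about hardware.

## Spectrum and effective energy

The tube model is Kramers bremsstrahlung photon fluence,
`N(E) ∝ (kVp/E − 1)`, hardened by self-absorption along an effective
tungsten path inside the anode (default 9 µm — calibrated so the W/Al
28 kV beam's effective energies across 2–9 cm breasts span ≈20.7–22.3 keV,
the range reported for clinical-style mammography beams) and by the
external filter (Al or Ag; the Ag K edge at 25.514 keV is carried in the
attenuation table as a bracketing node pair). Measured spectra can be
supplied as two-column text files instead. The study beams are W/Al 28 kV
restricted to 14–28 keV in 2 keV bins (eight bins) and W/Ag 34 kV +
0.05 mm Ag. The W/Ag beam's half-maximum core (≈19–25.5 keV) is clearly
narrower than the W/Al beam's, though its above-edge tail makes the plain
fluence-weighted SD comparable; "narrower" in this package means FWHM.

The effective energy of a beam for a path solves
`μ_mix(E) = −ln(T_poly)/t` by linear interpolation of the
composition-averaged attenuation over the spectrum support (piecewise
linear in the table nodes, so the solve is exact for the tabulated model).
In the estimation pipeline the working energy is, by default, the
model-predicted effective energy of a reference path: known compressed
thickness, nominal paddles and skin, and an assumed interior composition
(`ref_glandular_fraction`, default 0.5 for clinical use; simulation studies
pass the phantom's nominal composition, mirroring how the original study
derived per-phantom effective energies from matched simulations). This
model-matched route is deliberately preferred over solving the *measured*
equivalent attenuation against an assumed composition curve: the latter
confounds composition with energy — its energy error is ≈4 keV per unit of
composition error, and the GF estimate shifts ≈0.18 per keV — whereas the
model route's sensitivity is an order of magnitude smaller (≈0.3 keV per
30 points of composition error). Both routes are implemented
(`e_eff_mode="model" | "data"`), and a single energy is used per
acquisition, not per pixel.

## Phantom and projector

Half-cylindrical compressed breast: flat face on the chest-wall edge,
radius 7.5 cm, thickness `T` ∈ 2–9 cm along the beam; two 1.45 mm skin
layers (entry/exit slabs); a glandular half-cylinder of radius 5 cm and
height `gf_target × (T − 2·t_skin)` centered mid-interior (configurable
axial offset); two 2.5 mm Lexan paddles of 8 cm lateral radius (so
detector columns beside the breast see the unattenuated flat field);
optional cylindrical hydroxyapatite deposits (1 mm diameter × 0.5 mm
height) inside the glandular volume. Per-ray ground truth
`m_true = t_g/t_breast` counts skin inside `t_breast` but not in `t_g`, so
a "20%" phantom's per-ray truth is `0.2·(T−0.29)/T`; evaluation therefore
compares to the per-pixel truth, and thickness trends are assessed on the
bias.

The point source sits on the axis through the chest-wall edge midpoint at
70 cm; the detector is 20×15 cm at 1 mm pitch (pixel centers at
`(i+0.5)·pitch`), air gap 1.5 cm. Because every boundary is a z-plane or a
vertical cylinder, all intercepts are closed-form, including cone-beam
obliquity (slab components scale with sec θ); the tracer is verified
against a root-finding ray-marching oracle to 1e−9 cm. The flat field
carries inverse-square/obliquity falloff (cos³θ, switchable). Expected
flat-field counts default to 30 000 per pixel (≈10⁹ over the detector, the
study's fluence scale); `poisson=False` gives expectation-mode images with
`measured = primary + scatter` exactly, and a fixed seed makes sampling
bit-reproducible.

## What the simulator does and does not emulate

It reproduces: polychromatic Beer–Lambert primaries with exact path
geometry, thickness-driven multiplicative scatter, grid remnants, Poisson
statistics, and deposit attenuation. It omits: photon-history transport
(coherent/incoherent angular distributions, scatter spatial kernels beyond
the SPR map), detector scintillation/readout and MTF, focal-spot blur,
breast-edge thinning (all rays either traverse the full stack or are
masked), and anatomical texture. Passing error bounds here therefore
demonstrates the estimator's correctness and noise behavior under its own
forward model with idealized scatter; on Monte Carlo or clinical data,
residual scatter-model mismatch and within-tissue beam hardening add
systematic error, so the published error levels are upper envelopes for
this replay and the package's measured errors are expected to be smaller.
The one Monte Carlo systematic the replay does retain, in attenuated form,
is beam hardening: in expectation mode the bias of the mean GF estimate
decreases monotonically with thickness, and the narrower W/Ag beam both
reduces it and (through higher transmitted counts at 34 kV) lowers the
noise contribution at 9 cm.

## Evaluation conventions

Error statistics are computed on the glandular-shadow interior: pixels
whose rays cross the glandular slab end to end, eroded by 2 pixels to drop
partial-volume edges; errors are in percentage points of GF, per
configuration and pixel-pooled across the grid (both reported). The
location study uses distinct sub-seeds per placement — the projector is
exactly offset-invariant, so with a shared seed the comparison would be
degenerate. CNR uses signal ROI = the deposit's projected footprint and
background ROI = a 2–5 mm annulus restricted to the glandular interior and
clear of all footprints; improvements compare absolute CNRs because the GF
image inverts contrast polarity. The CNR gain of the GF image in this
noise-limited setting comes from the log-domain transform: a deposit
transmitting `e^(−x)` yields a GF-image CNR larger than the raw-image CNR
by the factor `x/(1−e^(−x))` (≈1.3–1.5 for a 0.5 mm hydroxyapatite chord
at these energies), independent of counts to first order.

Display mapping is a monotone binned-median lookup (256 uniform bins,
running-maximum isotonization, linear interpolation between bin centers) —
the weakest assumption sufficient for a vendor transform known only to be
monotone.

## Attenuation data

Per-material linear attenuation tables (10–45 keV, 0.5 keV grid) are
bundled as plain text, generated from elemental mass attenuation
coefficients (NIST-style values on the standard 10–50 keV grid, log-log
interpolated) combined by mass-fraction mixture rule with bulk densities:
ICRU-44 adipose (0.95 g/cm³), Hammerstein-composition fibroglandular
(1.04), ICRP skin (1.09), polycarbonate (1.20), water, hydroxyapatite
(3.18), aluminum, silver (with K edge). `scripts/make_attenuation_tables.py`
regenerates them. Interpolation is linear in energy with no extrapolation.
Spot checks: adipose 0.540/cm and glandular 0.781/cm at 20 keV, water
0.81 cm²/g — consistent with standard references to ~1%.

## Problem sizes

The bundled studies run the full 8×3 grid at the native 200×150-pixel
detector with three seeds per branch; the acceptance replay completes in a
few seconds on one CPU, so no scale reduction is applied anywhere.

## Known limitations

Absolute GF accuracy rests on the reference composition assumed for the
effective energy (≈0.8 points of GF per 30 points of composition error via
the model route) and on the SPR table matching the system; relative,
pixel-to-pixel contrast is insensitive to both. Marginal rays through the
curved breast edge are masked, not thickness-corrected, so the method
covers the interior only. Clinical error cannot be quantified here (truth
unknown); the DICOM path extracts acquisition metadata with explicit
provenance so that such studies can be run when raw data are available.
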