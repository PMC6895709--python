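# Methods

This note documents the models, estimators and numerical choices behind
`swifi`, and what the simulated validations do and do not establish.

## The measurement being modelled

Freely diffusing fluorescent molecules are imaged on a wide-field
microscope whose illumination enters just below the critical angle. The
effective observation depth is set by the axial point-spread function
(FWHM ≈ 610 nm for ~600 nm emission); molecules drift through this thin
slab, appear for a handful of frames, and leave. Emission is split onto
two spectral channels side by side on one chip, so each molecule yields
a donor and an acceptor intensity and an apparent FRET efficiency (or
"red fraction")

    E* = I_red / (I_red + I_green)

from background-subtracted counts. Tracking the same molecules yields
per-molecule apparent diffusion coefficients D\*, and the joint (E*, D\*)
distribution separates species by structure and mobility at once.

## Simulator

Emitters perform 3D Brownian motion, sampled at ≥ 10 substeps per frame
(default 20) so that intra-frame motion blur is rendered faithfully:

* per-substep displacement SD per axis: sqrt(2 D dt);
* axial detection weight exp(−z²/2σ_z²) with σ_z = FWHM/2.355
  (one effective profile; illumination-sheet and detection-PSF axial
  shapes are not separated — the data cannot distinguish them);
* z reflects off the faces of a slab (default 3 µm — thick enough that
  re-entry statistics do not distort short-track statistics);
* x, y wrap periodically at the box faces. The box extends a margin
  (default 1.5 µm) beyond the field of view; wrapping emulates an
  effectively infinite reservoir, so the emitter density is stationary
  for arbitrarily long movies. A wrapped molecule re-enters on the far
  side, well beyond any linking gate, and is indistinguishable from a
  fresh molecule. Without wrapping, fast molecules drain out of a
  finite box within seconds and late frames go empty.

Photophysics: FRET states form a continuous-time Markov chain sampled
per substep (initially at its stationary distribution); donor and
acceptor bleaching are absorbing exponential clocks; a configurable
fraction of molecules starts with a dark acceptor (apparent E = 0), the
well-known donor-only population. Photons split between channels as
(1−E)(1−ct) / (E + ct(1−E)) under donor excitation (ct = crosstalk) and
go entirely to the acceptor channel under acceptor (ALEX) excitation.

Camera: counts = Poisson(photons) × gain + Gaussian read noise + offset,
defaults emulating an sCMOS (gain 2 counts/photon, read noise 1.6
counts, offset 100). EM-register excess noise is not modelled. Pixel
size defaults to 130 nm (a 6.5 µm sCMOS pixel behind a 100× objective
with 2×2 binning). A single seeded generator drives every stochastic
element; identical configurations yield bit-identical movies.

Photon rates are per-condition choices standing in for excitation
power: ~800 photons/ms for the 2.5 ms / ~500 mW fast-diffusion
conditions, ~150 photons/ms for 40 ms acquisitions at lower power, and
~6 photons/ms for the 50 ms two-state (ALEX-style) experiments — the
last chosen so that the apparent-E* peak widths (σ ≈ 0.07–0.09) match
the regime reported for real ratiometric data, which is the regime in
which a two-Gaussian decomposition is a faithful density model. At
much higher simulated brightness the E* peaks become narrower than
their non-Gaussian tails and Gaussian areas misestimate populations.

What the simulator does **not** emulate: spatially varying
illumination, EMCCD excess noise, diffuse background fluorescence,
aberrated or astigmatic PSFs, and z-dependent PSF widening (the lateral
PSF σ is z-independent; only the detection weight changes). Passing
validations therefore show correctness of the analysis chain under
idealized imaging, not robustness to every instrumental artifact.

## Detection

Per channel and frame: Otsu's global threshold scaled by a user
sensitivity, 8-connected components, area filter (2–150 px), then
intensity-weighted centroid over the segmented pixels (raw weights; a
background-subtracted-weight option exists). Local background is the
mean of a ring two pixels wide around the blob's bounding box, with
pixels of other segmented blobs excluded. Net intensity is the
segmented sum minus area × background. Negative nets are kept (and
flagged): they carry information for E* averaging.

Two optional refinements, both off by default:

* `smooth_sigma`: a Gaussian pre-filter applied to the image used for
  thresholding only (never for measurement). Without it, shot noise
  fragments the dim tails of motion-blur streaks at the Otsu level,
  fragments get removed as near-neighbour pairs, and the surviving
  centroids are trimmed toward the bright core of the streak — a
  measurable shrinkage of apparent steps. A σ of ~1.5 px (roughly the
  blurred-spot scale) removes the fragmentation.
* `min_snr`: a robust floor on the threshold (median + k·1.4826·MAD of
  the thresholding image). Otsu assumes a two-class histogram; on a
  channel containing no molecules it splits read noise and segments
  speckle. The floor (default in the validation protocols: 6) makes
  empty channels return nothing.

The validation protocols use both (sensitivity 1.0, σ = 1.5, k = 6),
chosen by segmentation fidelity against simulator ground truth —
detection recall and identity-matched displacement fidelity — which is
the quantified version of "a sensitivity chosen by the user to maximize
correct segmentation".

A near-neighbour filter removes every localization with a same-frame,
same-channel neighbour closer than 1.5 × MAD (both members of a close
pair): such spots cannot be assigned to tracks reliably.

## Linking

Candidate links between an open track end and a localization Δt frames
later cost

    C = Δx² + Δy² + MAD·Δt²     (pixels; Δt in frames)

with links beyond the MAD gate forbidden. The MAD·Δt² term is
implemented exactly as printed even though it is dimensionally mixed; a
MAD²·Δt² variant sits behind `squared_gap_penalty`. Per frame, a
minimum-total-cost bipartite assignment (Jonker–Volgenant via SciPy)
decides the links, with unmatched track ends and localizations paying a
birth/death cost MAD² + MAD — chosen so any feasible one-frame link is
preferred over a death plus a birth. A greedy nearest-first variant
serves the ratiometric workflow. For max_gap = 1 the frame-by-frame
assignment is globally optimal (the test suite proves equality with
exhaustive enumeration on small instances).

MAD self-calibration: after a pass, MAD = 3 × the pooled per-axis SD of
consecutive-frame steps (axis means removed), and linking repeats until
the value changes by < 5% (a chosen quantification of "good agreement")
or 10 iterations. Tracks need ≥ 3 localizations (two steps).

Gating geometry matters more than it looks. "Distances above MAD" can
be read radially (√(Δx²+Δy²) ≤ MAD) or per axis (|Δx|, |Δy| ≤ MAD); the
calibration itself is per-axis (3σ of a 1D Gaussian covers 99.7% of
true steps). The radial gate at the self-calibrated MAD censors the
largest ~1.5% of *genuine* steps, and because the calibration then
shrinks further on the censored sample, its fixed point sits near
2.9σ — the net effect is a ~6–9% downward bias of ensemble MSD slopes.
The per-axis gate cuts ~0.5% and is nearly unbiased. Both are
implemented (`LinkConfig.gate`); the default follows the radial
contract, while the validation protocols use the per-axis gate, the
reading closest to the stated intent of forbidding only physically
impossible assignments. Similarly, a gap link (Δt = 2) gated by the
same spatial MAD censors two-frame displacements (variance 2× larger)
much harder; the protocols therefore link consecutive frames only
(max_gap = 1) and let a missed detection split the track.

## Mobility

Per-track D from <Δr²> = 4DΔt over consecutive-frame 2D steps. Note
that this estimator is biased under full-frame motion blur (factor 2/3
on the diffusive part) and inflated by localization noise (+σ²/Δt);
both effects are demonstrated in the tests.

Per-axis, per-track MSD by the overlapping-window formula
p(n) = Σ(X_{k+n}−X_k)²/(N−n+1); the ensemble curve P(n) is the
unweighted mean over the tracks for which p(n) exists. A straight line
over a lag window (default 1–4; an automatic best-R² window is
available) gives D = slope/(2Δt) per axis; the reported D is the axis
mean, and a drift flag trips when the axis slopes disagree by more than
25%. The slope-based estimator is unbiased under blur and localization
noise, which is why it is the headline estimator everywhere (including
the fast-fluorophore benchmark, where the raw per-track mean would be
~25% low from blur).

The intercept model: as printed, P(n) = 2DnΔt + σ² − (4/6)DΔt. A
sub-step simulation shows the per-axis intercept of camera-integrated
Brownian motion is 2σ² − (2/3)DΔt: the printed blur coefficient is
correct ((4/6)DΔt ≡ (2/3)DΔt) and only the σ² factor differs (the 4/3
blur factor sometimes quoted belongs to the x+y-summed convention).
`offset_model="printed"` (default) and `"standard"` (2σ²) convert the
intercept into a localization-accuracy estimate accordingly. The choice
does not affect D.

Viscosity of water/glycerol mixtures: exponential mixing rule
μ = μ_w^α μ_g^(1−α) with temperature-dependent pure-component
viscosities and a concentration/temperature-dependent α (the Cheng
correlation), after converting v/v to mass fraction with 20 °C
densities (1.261, 0.997 g/mL). Validated against tabulated water
(0.2%) and glycerol (2%) values. Stokes–Einstein then links D, η and
the hydrodynamic radius; the default temperature is 297.15 K (24 °C).

Populations of apparent D follow

    f_D(x) = ½ (3/D)³ x² e^(−3x/D)

— a gamma density with shape 3 and scale D/3 (mean D, mode 2D/3) — and
two-species mixtures thereof. Fitting is by maximum likelihood on the
samples rather than least squares on histograms (binning-free): with
the shape fixed, the single-species MLE is the closed form D̂ = sample
mean; the mixture (a, D₁ | D₂ fixed) is optimized by L-BFGS-B from
several starts, with a profile-likelihood 95% interval for the bound
fraction a.

## Ratiometric analysis

Per track point, the other channel's intensity comes from the nearest
same-frame localization within the registration tolerance, else it is
measured directly from the other channel's image in the detected blob's
bounding box mapped through the registration (same ring background
rule; no re-segmentation). Per-track E* is the unweighted mean over
donor-excitation frames. Records with zero total intensity are dropped
and counted; E* outside [0, 1] is kept (clipping is display-only).

Tracks found independently in the two channels pair into one molecule
when their registered positions coincide on overlapping frames
(smallest mean distance, ties to longer overlap). `dual_channel_records`
pools per-frame records from both channels without double counting — a
molecule whose current state darkens one channel stays covered by the
other, which matters whenever state occupancies are read off E*
histograms (single-channel tracking preferentially samples the states
bright in that channel).

ALEX acceptance: a track qualifies when it has an even number ≥ 4 of
localizations in strictly consecutive frames (hence DADA… or ADAD…);
E* uses all its donor-excitation frames (not only complete quartets),
and acceptor-excitation frames certify the acceptor. Under ALEX a
single channel has no consecutive-frame steps, so `alex_localizations`
builds the tracking stream from donor-channel spots on D frames plus
registered acceptor-channel spots on A frames.

Two-state occupancy ratios come from a two-Gaussian decomposition of
the pooled E* histogram (nonlinear least squares on binned counts); the
area ratio of the lower- to higher-mean component estimates the
population ratio. Frames containing a mid-exposure state switch
produce averaged E* between the peaks and are claimed by neither
component, which inflates the ratio by roughly the difference in
switch-per-frame probabilities; dwell times ≳ 15 frames keep this below
a few percent.

## Validation protocols and what they show

`swifi.protocols` packages the benchmark conditions end to end
(simulate → detect → link → estimate). Problem sizes — a 128×128-px
field, a handful of emitters, 1 200–3 000 frames, one or two movies per
condition — were chosen to give ≥ 500 tracks (≥ 2 000 E* records for
the switching benchmark) at low density, mirroring the tens-of-pM
concentrations of the real experiments.

The diffusion benchmarks recover the ensemble D at 0.8 µm²/s (40 ms
frames) to within ~5–15%, and at 70–111 µm²/s (2.5 ms frames) about
15–25% **low**. The shortfall at high speed is reproducible and
decomposes into documented mechanisms, each intrinsic to the published
analysis rather than to this implementation:

* conditioning on axial visibility (the brightness-weighted intra-frame
  timing of molecules near the detection boundary) — a few percent;
* centroid trimming of thresholded motion-blur streaks — the measured
  step regression slope is ~0.98, i.e. ~4% on the MSD slope;
* MAD-gated linking (censoring plus occasional cross-molecule bridges
  when visibility runs last only a few frames) — ~5–10%.

These add up to an intrinsic negative bias of the gated
centroid-tracking method for molecules that cross the focal slab within
a few frames. Consistently, the independent FCS cross-checks of such
tracking report diffusion coefficients ~10% above the tracking values
in exactly the fast conditions. The package reports what the method
measures; no post-hoc correction factor is applied.

## Known limitations

* The simulator's detection-weight model is a single axial Gaussian;
  real observation depth depends on brightness and defocus PSF shape.
* The per-frame assignment is optimal per frame, not over the whole
  movie; for max_gap > 1 a global solver could differ.
* The mixture fit assumes the single-species form holds for each
  component; heterogeneous track lengths broaden the true per-track D
  distribution beyond it.
* Gap-containing tracks contribute only their existing lags to MSDs;
  no imputation is attempted.
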