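# swifi

Tracking and ratiometric analysis of single fluorescent molecules
diffusing freely in solution, imaged on a two-channel wide-field
microscope — plus a full synthetic-movie simulator so every stage of
the analysis can be validated against known ground truth.

## Who this is for

Single-molecule fluorescence labs that image fast-diffusing molecules
under thin oblique (near-critical-angle) illumination instead of
tethering them to a surface. Each molecule is visible for only a
handful of frames as it drifts through the ~0.6 µm axial detection
profile; the analysis must detect motion-blurred spots, assemble them
into tracks, and turn tracks into diffusion coefficients and
donor/acceptor intensity ratios.

## What it computes

* **Detection** — per-frame Otsu segmentation (user sensitivity, area
  filter 2–150 px), intensity-weighted centroids, ring-background
  subtracted net intensities.
* **Linking** — per-frame minimum-cost assignment with the cost
  `C = Δx² + Δy² + MAD·Δt²`, links beyond the maximum allowed distance
  (MAD) forbidden, and MAD self-calibrated as 3× the per-axis step
  standard deviation, iterated to convergence. A greedy near-neighbour
  variant supports the ratiometric workflow.
* **Mobility** — per-track apparent D from `⟨Δr²⟩ = 4DΔt`; per-axis
  MSD curves `p(n) = Σ(X_{k+n}−X_k)²/(N−n+1)`; the ensemble curve
  `P(n) = (1/M)Σp(n) = 2DnΔt + σ² − (4/6)DΔt` fitted over ≥ 3 lags;
  Stokes–Einstein radii `R_h = k_B T/(6πηD)` with an empirical
  water/glycerol viscosity correlation; and maximum-likelihood fits of
  the apparent-D densities
  `f_D(x) = ½(3/D)³x²e^(−3x/D)` (single species) and their two-species
  mixture with one coefficient held fixed.
* **Ratiometric** — per-frame `E* = I_red/(I_red+I_green)` along
  tracks, cross-channel intensity inference at registered positions,
  dual-channel track pairing, ALEX (alternating-excitation) track
  filtering (even ≥ 4 localizations, DADA/ADAD), E*–D* bivariate
  histograms, and two-Gaussian population decompositions.
* **Side models** — the FCS autocorrelation
  `G(τ) = (1/n)(1+τ/τ_d)⁻¹(1+τ/(SP²τ_d))^(−1/2)(1+Te^(−τ/τ_t)/(1−T))`
  and the anisotropy relative bound fraction
  `RBF = (AN_c − AN_free)/(AN_bound − AN_free)`.
* **Simulation** — 3D Brownian emitters in a periodic box with an
  axial Gaussian detection profile, substep-resolved motion blur,
  FRET-state switching, dark acceptors, bleaching, ALEX schedules and
  an sCMOS-style camera model, written as two-channel TIFF stacks with
  complete ground truth.

## Worked example

Simulate a movie of dual-labelled dsDNA diffusing at 6 µm²/s, run the
pipeline, and read off the diffusion estimate:

```python
from swifi import (SimulationConfig, PhotophysicsModel, simulate_movie,
                   DetectionConfig, detect_movie, LinkConfig,
                   iterate_linking, ensemble_msd)

cfg = SimulationConfig(n_emitters_mean=10, fov_px=(128, 128),
                       d_um2_s=(6.0,), frame_time_ms=20.0,
                       n_frames=600, seed=7)
movie, truth = simulate_movie(
    cfg, photophysics=PhotophysicsModel(photon_rate_per_ms=300.0,
                                        e_states=(0.45,)))

locs = detect_movie(movie, DetectionConfig(smooth_sigma=1.5, min_snr=6.0),
                    channels=("donor",))
res = iterate_linking(locs, initial_mad=10.0,
                      config=LinkConfig(max_gap=1, gate="per_axis"))
ens = ensemble_msd(res.tracks, frame_time_s=0.020, pixel_size_um=0.130)
print(f"tracks: {res.tracks.track_id.nunique()}, "
      f"MAD: {res.mad:.2f} px")
print(ens.summary())
```

prints

```
tracks: 338, MAD: 8.71 px
Ensemble MSD fit
  lags used        : [1, 2, 3, 4]
  D (x, y)         : 4.703, 5.957 um^2/s
  D (mean)         : 5.33 um^2/s
  sigma (loc.)     : 0.0 nm [printed offset model]
  drift flag       : False
```

The converged MAD (8.7 px ≈ 3× the per-axis step SD including
localization noise) is the self-calibrated linking gate; the ensemble
MSD slope over lags 1–4 recovers D ≈ 5.3 µm²/s for a ground truth of 6
(tracking of gated, thresholded centroids reads somewhat low — the
bias budget is quantified in `docs/methods.md`). The motion-blur term
can push the fitted intercept below zero, in which case the
localization-accuracy estimate clamps at 0. The same objects expose
per-track tables, E* records and histograms for the ratiometric
workflow.

A command-line interface mirrors the library:

```bash
swifi simulate --config sim.yaml --out movie.tif --truth truth.csv
swifi detect movie.tif --out locs.csv
swifi track locs.csv --mode optimal --mad-init 10 --out tracks.csv
swifi fret tracks.csv movie.tif --locs locs.csv --out fret.csv
swifi mobility tracks.csv --pixel-size-nm 130 --frame-time-ms 20 \
      --fit two --d2 39 --out mob.json
swifi fcs curve.csv --out fit.json
swifi run movie.tif --config run.yaml --out results/
```

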