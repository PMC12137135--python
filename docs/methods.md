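# Methods

## Problem

During vascular-targeted photodynamic therapy (PDT), reactive-oxygen
generation consumes tissue oxygen and damages tumor vasculature.
Ultrasound-guided photoacoustic imaging (US-PAI) can watch this happen in
real time: interleaved 750/850 nm photoacoustic frames are spectrally
unmixed into oxy-/deoxyhemoglobin maps, giving per-pixel oxygen saturation
(StO2, %) and total hemoglobin (HbT, arbitrary units) over a treated tumor
cross-section.  `paoximetry` implements the full analysis chain for such
recordings — unmixing, noise masking, ROI kinetics, endpoint detection and
milestone difference maps — together with a synthetic tumor phantom that
generates realistic recordings with known ground truth.

## Spectral unmixing

Per pixel, the two-wavelength measurement m = (m750, m850) is modeled as
m = E c with E the 2x2 matrix of molar extinction coefficients of HbO/HbD
(literature values packaged in `data/hemoglobin_extinction.csv`: 750 nm —
HbO 518, HbD 1405.24; 850 nm — HbO 1058, HbD 691.32 cm^-1 M^-1) and
c = (c_HbO, c_HbD) >= 0.  The non-negative least-squares problem is solved
in closed form: if the unconstrained 2x2 solution is non-negative it is
exact; otherwise the minimizer lies on an axis of the feasible quadrant, so
both single-chromophore projections (and the origin) are compared by
residual.  An iterative NNLS solver handles >2 wavelengths.  StO2 is a ratio,
hence invariant to overall gain; HbT inherits the arbitrary photoacoustic
amplitude scale.

The noise floor is the pooled mean HbT over the two 20x20-pixel top-corner
patches of every frame (tissue-free regions above the skin line); one
threshold per recording.  Pixels below it are zeroed in both channels and
flagged in a boolean mask, which — not the stored 0 — is the authoritative
no-signal marker.

## ROI kinetics

The tumor-ROI mean StO2 per frame excludes masked (zero) pixels, so vanishing
vessels leave the mean rather than dragging it to zero.  The trace is
median-filtered (order 15, sliding window with truncated — never
zero-padded — edge windows; zero padding would bias the 100 % baseline
downward at the recording edges) and normalized by 100 / (mean over the 5-min
pre-light baseline), making the baseline exactly 100 %.

The depletion rate is the mean of per-index ordinary-least-squares moving
slopes (window 15 samples ~ 1 min at 4-s frames, matching the filter scale;
the window is configurable) over the first 5 min of light, in normalized-%
per minute.  The end of active PDT is the time of the global minimum of the
normalized trace over the light interval, ties broken earliest; a monotone
decline returns light-off.  A "plateau" rule (first sustained non-decrease)
is available as an alternative endpoint definition.  Group rates are compared
with one-way ANOVA plus Tukey's HSD (alpha = 0.05) via scipy/statsmodels.

The Severinghaus dissociation curve S = 100 (23400/(p^3 + 150 p) + 1)^-1
links pO2 (mmHg) to saturation; its inverse is the closed-form real root of
the corresponding depressed cubic and round-trips to 1e-6 mmHg.

## Difference maps

Delta-StO2 maps subtract the saturation image at one milestone from another
on the intersection of the two validity masks (pixels valid at only one
milestone are excluded rather than treated as change from/to zero, which
would fabricate +-100 % swings at the noise floor).  Negative = deoxygenation,
positive = reoxygenation.  A 3x3 median filter (nearest-edge replication) is
provided for display only.  For asymmetric-dose experiments the ROI splits
into lateral halves about its own centroid column (image-midline split
available), partitioning the ROI exactly.

## Synthetic phantom

The phantom emulates a treated murine tumor cross-section: an elliptical ROI
(~7-9 mm across at 0.1 mm/px), a blob-textured baseline HbT field, a smooth
heterogeneous baseline saturation field (mean 70 %, SD 8), and per-pixel
saturation dynamics

    dS/dt = -k_consume * Phi(x) * P(t) * S/100        (photochemical sink)
            + v(t) * (S0(x) - S)                       (vasodilation reflow)
            - k_shutdown * w(t) * S                    (vascular shutdown)
            + r(x) * k_recovery * 1(t > t_trough)      (reperfusion, capped at S0)

integrated by explicit Euler at the 4-s frame period and clipped to
[0, 100].  Phi(x) sums fiber contributions (uniform for in-plane fibers,
linear lateral gradients for left/right fibers, enabling the asymmetric
150/50 mW/cm^2 layout).  P(t) = exp(-k_bleach Phi_mean t) is photosensitizer
availability; w(t) ramps with *accumulated photodynamic dose*
(integral of Phi_mean P dt, full shutdown at 2400 mW min/cm^2) rather than
elapsed time, so a high fluence rate shuts vessels sooner and harder — this,
together with the deficit-proportional vasodilation reflow, reproduces the
oxygen-conservation effect in which the low-fluence-rate arm ends less
deoxygenated than the high-rate arm despite its longer effective exposure.
Shutdown persists after light-off but spares the programmed recovering
region r(x) (a ~1 mm rim band plus a small upper-quadrant interior patch,
~48 % of the ROI), whose vasculature retains function and reperfuses at a
constant capped rate after the programmed trough.  Without photosensitizer
(k_consume = 0, the light-only arm) there is no photodynamic action:
consumption, shutdown and recovery are all inactive and S stays at S0, so
the control trace is flat by construction.

Default rate constants (k_consume 0.035 % cm^2 mW^-1 min^-1, k_bleach
4.2e-4 cm^2 mW^-1 min^-1, vasodilation 0.45 min^-1 peaking 2 min into light,
k_shutdown 0.024 min^-1, reperfusion 6.0 %/min) were calibrated once so the
high-fluence-rate (HFR, 400 mW/cm^2) bulk trace reproduces the reported
qualitative morphology: a sharp drop within the first minute of light, a
brief vasodilation shoulder near the 7-min mark of the recording, a trough
near the 12-min mark (7 min into the 15-min light dose) followed by partial
rim reoxygenation, and a deeper overall trough than the low-rate arm (LFR,
100 mW/cm^2), whose decline lasts until light-off.  For cases without a
programmed trough, reperfusion begins 60 s after light-off.

Frames are rendered as img_l = gain_l (eps_HbO(l) c_HbO + eps_HbD(l) c_HbD)
plus additive Gaussian noise with SD equal to `noise_sd` (default 1 %) of
the mean in-tumor signal per channel — consistent with the heavy per-frame
averaging (20-pulse persistence) of the emulated instrument.  Background
outside the tumor is noise only.  All randomness flows from a single spec
seed; identical specs render bit-identical stacks.

### Endpoint-detection identifiability

A sliding median of order 15 maps any V-shaped minimum onto an exactly flat
plateau roughly half a window wide (sliding the window exchanges two
above-median tail samples, leaving the median element unchanged), so the
argmin-with-earliest-tie endpoint detector resolves a trough only up to that
plateau, with its start set by the fall/rise slope ratio at the kink.
Recovering the trough time to about one frame therefore requires a trough
whose fall is several times steeper than its rise and trace noise small
relative to the per-frame slope.  The phantom defaults satisfy both; on data
with a shallow or symmetric trough, or heavier noise, endpoint estimates
should be trusted only to about half the filter window (~30 s here).

### What the phantom does not model

No acoustic propagation, speckle, depth-dependent light fluence, or motion;
noise is additive Gaussian per channel, uncorrelated across pixels and
frames; chromophores are limited to HbO/HbD (no photosensitizer absorption).
Passing tests therefore validate the analysis chain's correctness and its
statistical behavior under realistic heterogeneity and noise — not
robustness to beamforming artifacts, fluence gradients or breathing motion
in real recordings.

## Numerical choices and degenerate inputs

- Unmixing ties between the two axis projections resolve to the HbO axis;
  in practice ties have measure zero.
- Frames with no valid ROI pixel propagate as NaN and are skipped (never
  imputed) by the filter, normalization and slope estimators.
- The explicit-Euler step is validated against the summed first-order rate
  constants (consumption at peak fluence, vasodilation, shutdown); the
  capped reperfusion climb is excluded since it cannot overshoot.  A too
  large frame period raises an error suggesting a stable one.
- Baseline normalization refuses empty or non-positive baselines; ANOVA
  refuses groups with fewer than two subjects.
- A one-column ROI still splits laterally, with a warning and one empty
  half.

## Problem sizes

Simulated studies use 128x128 grids with a 30-min protocol at 4-s frames
(451 frames); statistical recovery checks use 20 replicate phantoms per
treatment arm.  Unit tests exercise the same code paths on 64-96 px grids.
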