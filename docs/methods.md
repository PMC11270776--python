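# Methods

This note documents the models behind `aortaflow`, the defaults and why
they were chosen, the numerical decisions that affect results, and what
the synthetic data do and do not establish about real acquisitions.

## Flow pulse model

The central object is a one-cycle volumetric flow waveform Q(t) (m³/s)
with period T. The generic abdominal-aortic pulse is a triphasic template:
three raised-cosine lobes with fixed relative timings — systolic forward
over 0–35% of the cycle, early-diastolic reversal over 35–60%, a small
late forward lobe over 60–80%, zero flow afterwards. Lobe boundaries
touch zero exactly, so any pulse with a reversal has exactly two interior
sign changes (the triphasic signature). Defaults: peak flow 5 L/min,
reversal amplitude 25% of peak, late-lobe amplitude 12% of peak, heart
rate 63.5 beats/min. Peak and rate are the population-level inlet
conditions used when no patient-specific Doppler is available; the
reversal and late-lobe fractions are set once to typical infrarenal
waveform proportions and are not data-fitted. The 200-sample default grid
places the systolic peak exactly on a sample, so the sampled maximum
equals the nominal peak.

## Pulsed-wave Doppler extraction

The spectrogram (intensity over velocity bin × time column) is smoothed
with a 3×3 mean filter (edge replication), then each column's velocity is
the intensity-weighted median of the bin centers: the smallest bin at
which the cumulative weight reaches half the column total, with weights
max(intensity − floor, 0). The median is used because it is robust to
outlier bins; the floor default is 10% of the column maximum, which
removes a uniform noise floor without biasing the ridge. Columns with no
weight are filled by linear interpolation in time.

The trace is low-pass filtered with a zero-phase (forward–backward)
2nd-order Butterworth. Default cutoff 20 Hz: zero phase preserves
systolic timing, and 20 Hz keeps ~19 harmonics of a 63.5 bpm heart —
measurably gentler on the systolic peak than a 15 Hz cutoff while still
suppressing trace jitter. Cardiac cycles are split at the systolic foot,
defined as the sub-sample 10%-amplitude crossing of the upstroke before
each detected peak. A plain windowed minimum is ambiguous here: the late
diastolic plateau of an aortic waveform is near zero flow, so the
minimum lands anywhere in the plateau and misaligns the ensemble; the
upstroke crossing is phase-consistent across beats. Cycles are truncated
to the shortest beat, point-wise averaged, and interpolated with
shape-preserving pchip onto a uniform grid spanning the mean beat period.
Flow follows as Q = v·πr², assuming a symmetric profile and circular
cross-section; the spectrogram's velocity axis is taken as already
angle-corrected by the scanner.

A known systematic of this estimator chain: because the 3×3 filter also
averages *adjacent time columns*, the traced velocity is biased at
waveform extrema by an amount that grows with the square of the column
spacing (curvature × spacing²). Round-trip verification therefore uses
the finest spectral line rate of the study design (79 Hz); at coarser
rates the same pipeline shows a visibly larger peak-flattening bias that
is a property of the discretized data, not of the implementation.

## Color-Doppler extraction

Segmentation is a star-Kalman tracker: from a seed point, N=32 uniformly
spaced rays search for the strongest outward intensity drop (sub-pixel,
parabolic refinement of the gradient peak) within a gate of ±5 px around
the per-ray Kalman prediction; each ray's radius follows a scalar
constant-radius Kalman filter (process/measurement variance 0.1/1.0 px²),
and the center is re-anchored each frame to the boundary centroid with
0.5 damping. A frame that loses the edge on more than half its rays
raises a tracking-lost error by default; with `coast_on_loss` the
prediction is held instead — needed for diastolic frames that drop out
entirely. Tracking starts at the frame with the most Doppler signal and
proceeds forward and backward, mirroring a manual selection on a
well-perfused frame. Contours can be smoothed over frames by a
Gaussian-weighted average (σ in frames; σ=∞ gives the rigid mean
contour, the default in the end-to-end pipeline since the synthetic
lumen does not pulsate).

Decoding matches each in-contour pixel to the nearest color-scale entry
(Euclidean color distance; tolerance one half of the scale's minimum
inter-entry distance). Missing in-lumen pixels are filled spatially by
2-D linear interpolation, anchored by zero-velocity points on the wall
(no-slip) so rim dropout interpolates toward zero instead of
extrapolating interior values outward; frames with no decoded pixel are
filled per-pixel linearly over time. When the wall-filter threshold of
the acquisition is known (it is a scanner setting, carried as sequence
metadata), interpolated pixels are additionally clipped to ±threshold —
an undecoded in-lumen pixel is *censored* at that level, not missing at
random. The validity mask always separates decoded from interpolated
pixels.

Calibration multiplies all fields by a single factor matching the CD
cycle-mean flow to the PWD cycle-mean (peak matching is available as an
option). The CD cycle-mean is computed by a periodic trapezoid over cycle
phase, not a plain frame average: CD frames are not phase-locked to the
heartbeat, and at 7–23 Hz a raw average of an incomplete cycle is biased
by several percent. Cycle averaging groups frames into
ceil(period/frame-interval) phase bins (an epsilon guards frames sitting
exactly on bin edges when the frame grid is commensurate with the cycle)
and reports the mean member phase per bin.

Limitations inherited from the modality and deliberately not corrected:
no beam-to-flow angle dependence, no wall-filter spectral model. Under
diastolic dropout at 10% of the peak velocity, the calibrated
mean-velocity trace recovers the truth to within a few percent of the
*peak* velocity; expressed relative to the small cycle-mean of a
reversing waveform the same error is several times larger, which is the
honest reading of how poorly CD constrains diastole.

## Q-flow MRI extraction

The FFE magnitude image (dark lumen on bright background) is segmented
by the same star-Kalman tracker applied to its complement. Velocities
decode as v = phase fraction × VENC inside the contour. The fields are
upsampled bilinearly (default factor 4) and smoothed with a 3×3 mean
filter, both in *coverage-normalized* form (normalized convolution): the
velocity and a lumen-coverage weight are filtered identically and the
ratio taken, so mixing with the zeroed exterior does not dilute near-wall
velocities. The border condition — velocity falling smoothly to zero at
the wall — is imposed by multiplying with the sub-pixel lumen coverage,
which ramps from 1 to 0 across one fine pixel at the contour; the flow
integral keeps these partial-volume boundary contributions. This scheme
replaced a zero-band-plus-interpolated-ring variant that deleted real
near-wall flow: for flat (plug-like and high-Womersley) profiles the
integral error dropped by roughly an order of magnitude.

Per-frame flow is the area integral Σ v·(pixel area). The 30-point cyclic
flow sequence is low-pass filtered in the Fourier domain, keeping 80% of
the frame-rate Nyquist band: at 30 frames/cycle any time-domain kernel
wide enough to smooth (e.g. a width-3 moving average) also attenuates
the physiological harmonics 5–10 that carry the systolic peak, distorting
the pulse far more than it denoises; the band-limited filter removes
only top-band noise. The pulse is then pchip-interpolated onto a uniform
one-period grid. An optional frame-to-frame unwrap step (adding ±2·VENC
where consecutive frames jump by more than one VENC) is provided but off
by default, since VENC is assumed chosen to prevent aliasing.

Accuracy floor: with ~10 pixels per radius, the raster itself cannot
resolve the thin near-wall layer of a high-Womersley profile (thickness
~R/α, below one pixel at α≈13), so even an exact decoder differs from
the analytic pulse at the level of the round-trip bound. The parabolic
profile, which the raster resolves well, recovers to well under 2%
nRMSE; this is the configuration used for round-trip verification.

## Generic profiles and the Womersley model

Plug, parabolic and power-law profiles are closed forms normalized to
integrate exactly to Q(t); power-law exponent n=2 reproduces the
parabola. The Womersley model decomposes Q(t) by DFT into a mean plus
complex harmonics (computed directly on the pulse's native uniform grid
when possible — resampling through linear interpolation measurably
attenuates harmonics). Harmonic k has Womersley number
α_k = R√(kωρ/μ) and velocity kernel
[1 − J₀(Λs)/J₀(Λ)] / [1 − 2J₁(Λ)/(ΛJ₀(Λ))] with Λ = i^{3/2}α_k, whose
cross-sectional mean is one, so each harmonic of the profile carries
exactly its harmonic of the flow. The steady component is assigned the
Poiseuille parabola. Defaults: blood density 1060 kg/m³, Newtonian
viscosity 0.004 Pa·s, 10 harmonics (16 for the synthetic ground truth,
where the harmonic truncation of the triphasic template must stay below
the round-trip tolerances; at 10 harmonics the template's reconstruction
error is ~1% of the mean-|Q| scale, at 16 about a third of that).

## Flow characterization

Pulses are first rotated so t=0 is the systolic foot: the minimum within
0.3T before the global maximum, ties resolving to the last occurrence
(the start of the upstroke), and never inside reverse flow — if the
tentative foot has Q<0 the origin advances to the up-crossing. Phases
are delimited by sub-sample zero-crossings (linear interpolation; a run
of exact zeros between opposite signs yields one crossing at its first
zero sample): systole spans [0, first down-crossing], the reversal phase
extends to the next up-crossing or the cycle end. This reading makes the
degeneracy exact by construction: a pulse without a second (up-)
zero-crossing has SF = FF, RF = BF and SRratio = FBratio identically. A
pulse without any reverse flow has no down-crossing; its systolic time
must be supplied manually and the reverse-flow descriptors (max/min
ratio, RF, SRratio, FBratio) are NaN, while BF is reported as 0.
Integration is trapezoidal on a 2048-point resampling of the cycle;
percentual parameter differences are 100·(test−ref)/ref with NaN
propagation and a warning (not an error) on zero references.

## Comparison metrics

Point-wise percent difference and nRMSE both normalize by the *mean* of
the reference over the evaluated support, not the local value. With the
proximal-exclusion rule (drop points within one diameter of the inlet,
axial coordinate measured from the inlet plane) the normalizing mean is
recomputed over the included points — the post-exclusion choice keeps
numerator and denominator on the same support. Waveform comparisons
against ground truth first align the two cycles by circular
cross-correlation (with parabolic sub-sample refinement of the
correlation peak), because the trigger point of an extracted cycle — the
systolic foot inside a zero-flow plateau — is arbitrary relative to the
generator's time origin.

## Hemodynamic surrogates

Wall shear stress for a straight tube comes analytically from the
Womersley model: τ_w = 4μQ̄/(πR³) for the steady part plus the
Bessel-kernel gradient per harmonic, signed positive for forward flow.
TAWSS and OSI are trapezoidal in time; OSI is defined as 0 where TAWSS
is 0 and clipped to [0, 0.5]. The Carreau law
μ = μ∞ + (μ0−μ∞)[1+(λγ̇)²]^{(n−1)/2} uses standard literature blood
constants (μ0=0.056 Pa·s, μ∞=0.00345 Pa·s, λ=3.313 s, n=0.3568); it is
exposed as a viscosity function only — the analytic Womersley solution
requires a Newtonian viscosity, a documented divergence from a full CFD
treatment. Note the slow approach to the infinite-shear plateau at
blood's n≈0.36: 1% closeness needs λγ̇ ~ 10⁵–10⁶.

The 3-element Windkessel integrates C·dPc/dt = Q − (Pc−P_out)/Rp with
classical RK4 at ≥200 steps/cycle from Pc(0)=P_out, returning the last
of n cycles (transient discarded). The fit to a systolic/diastolic
pressure pair iterates two decoupled corrections: total resistance
(holding the initial Zc/Rp ratio) is corrected through the exact
periodic-state identity mean P = P_out + (Zc+Rp)·Q̄ to cancel the
mid-pressure error, and compliance is scaled by the achieved/target
pulse-pressure ratio. Each evaluation simulates long enough for the RC
transient to settle (≥6 time constants, capped at 80 cycles) — fitting
against an unconverged transient is the classic divergence mode of this
scheme. An init already within tolerance is returned unchanged;
non-convergence raises an error carrying the last iterate.

## What the synthetic data establish — and what they don't

The generators reproduce the *statistical structure* of the three
acquisitions: PWD as a Gaussian spectral ridge (broadening sd, uniform
noise floor, per-beat period jitter) at 20–79 Hz line rates; CD as
indexed-color frames with an explicit symmetric two-branch
(color, velocity) scale, ~0.2 mm pixels, 7–23 Hz rates, and diastolic
dropout below a threshold; MRI as FFE/PCA pairs at ~30 frames/cycle and
~R/10 pixels with direct VENC phase encoding and an anti-aliased rim.
All randomness flows from explicit seeds; identical inputs are
bit-for-bit reproducible.

They do **not** model ultrasound physics (speckle, beamforming, wall
filters, angle dependence), scanner file formats, intra-beat waveform
variability (only period jitter), vessel-wall motion, through-plane
misalignment, or MRI partial-volume averaging within a pixel (pixels are
point samples of the true field). Passing round trips therefore
demonstrate the correctness and numerical quality of the extraction
algorithms under the stated acquisition geometry and noise — not
clinical accuracy on real scans, where modality-level measurement
uncertainties (several percent in MRI flow quantification alone)
dominate.

## Problem sizes

Defaults used by the test suite and the acceptance script: 10 mm vessel
radius; PWD at 79 Hz, 512 velocity bins, 4–5 beats; CD at 15 Hz with
R/40 pixels and a 64-level scale; MRI at 30 frames with R/10 pixels and
4× upsampling; 20 replicates for the noisy-recovery check; 2048-point
quadrature for flow descriptors; 8192 samples for the TAWSS/OSI closed
forms. These sizes keep every check comfortably converged relative to
its tolerance.
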