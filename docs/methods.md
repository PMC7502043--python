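# Methods

`mtprep` models a contrast-free 3D cardiac magnetization-transfer-ratio (MTR)
examination end to end: the spin physics of the MT-prepared gated sequence, a
motion-corrected Cartesian reconstruction chain, and the quantitative image
metrics used to read the maps.  This note records the models, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Two-pool Bloch-McConnell model

Tissue is described by two exchanging proton pools: mobile water (free pool A,
relaxation times `T1A`, `T2A`) and macromolecular protons (bound pool B) whose
transverse magnetization decays within tens of microseconds and is therefore
eliminated from the state.  The state vector is `[MxA, MyA, MzA, MzB]` with
unit total equilibrium, `M0A = 1 - PSR`, `M0B = PSR`, where the pool size
ratio `PSR = M0B / (M0A + M0B)` is the quantity scar imaging is after (it
falls when protein-rich myocytes die).  Exchange enters as pseudo-first-order
rates `R*M0B` (A→B) and `R*M0A` (B→A).

Off-resonance irradiation at offset ΔF with amplitude ω1(t) drives the free
pool through the standard rotating-frame Bloch terms and saturates the bound
pool directly at rate

    R_RFB(t) = pi * |omega1(t)|^2 * G(delta_eff),

with `G` the super-Lorentzian absorption lineshape of semisolid matter and
`delta_eff = ΔF + B0` the effective offset (a global B0 error shifts the
tissue's resonance under the pulse, and also supplies the free-precession
frequency everywhere else in the sequence).  One sign in the printed
longitudinal free-pool equation of the source model breaks the antisymmetry
of the RF rotation generator; we implement the antisymmetric (norm-preserving)
form.

**Propagation.**  Within each RF sample interval (default dt = 50 µs,
capped at 100 µs) the system is linear with constant coefficients and is
propagated *exactly* by the matrix exponential of the augmented 5×5 system
(the relaxation drive rides in the fifth column).  This is the
piecewise-constant interval scheme standard for shaped-pulse MT simulation;
the accuracy limit is the piecewise-constant assumption on ω1, not the
integrator.  A full MT pulse (~410 intervals) collapses into one cached 5×5
propagator per (waveform, tissue, effective offset), which is what makes the
parameter sweeps run in seconds.

**Lineshape.**  `G(Δ)` is evaluated by adaptive quadrature with the
magic-angle singularity declared to the integrator.  On resonance the
super-Lorentzian diverges, so below |Δ| = 1 kHz values are cubic-spline
interpolated from evaluations at ±1, ±1.5 and ±2 kHz — the standard
extrapolation in quantitative-MT work.  `T2B` is fixed at 14 µs; `T1B` is not
identifiable from MTR data and is set to the conventional 1.0 s (both
configurable).

**MT preparation.**  A train of Hann-apodized symmetric sinc pulses
(default 20 × 20.48 ms, bandwidth 270 Hz, so time-bandwidth product 5.53)
separated by 1.5 ms gaps in which ideal 3D spoilers zero the free-pool
transverse magnetization.  The waveform is normalized so that ∫|ω1|dt equals
the nominal flip angle — note this is an *absolute-area* convention; for this
waveform the signed-area flip is ~0.8× the nominal value, which matters when
comparing absolute MTR levels against scanner calibrations (see
"Known limitations").

**Imaging modules.**  Readout pulses are instantaneous single-pool rotations
of the free pool (no exchange during the short excitation); between pulses
the full relaxation/exchange/precession propagator applies.  SPGR: constant
flip (default 15°, TR/TE 3.8/1.6 ms), ideal spoiling at the end of each TR.
bSSFP: default 70°, TR/TE 3.2/1.4 ms, 180° RF phase cycling, and a linear
flip-angle ramp over the 14 start-up pulses (the exact catalyzation scheme of
the source sequence is unspecified; the ramp is a common choice and is
switchable).  No RF-spoiling phase schedule and no slice/gradient profile are
simulated.  The echo signal is |MxyA| at TE after the pulse at
`echo_index` (default 15 — the first profile after the start-up pulses, which
samples the k-space centre).

**Sequence timing.**  Per heartbeat: MT preparation (for the MT-weighted
acquisition) → imaging train → free relaxation for the rest of the RR
interval; the reported signal is from the fifth simulated heartbeat, by which
the beat-to-beat cycle is in pseudo steady state (<0.5 % change to beat 6).
MTR = 100·(1 − S_MT/S_REF).

### Operating point and sensitivity caveats

At the nominal human protocol (800°, 3 kHz, n = 20) this model yields
myocardial MTR around 55 % (SPGR) — a deeper saturation level than the ~37-40 %
measured in vivo with the same nominal settings.  The absolute level depends
on the exact pulse shape, apodization and flip-angle calibration, none of
which are fully published; at an equivalent power of ~500° the model
reproduces both the in-vivo MTR level and the small published
exchange-rate sensitivity.  Consequences, all verified by the sweep suite:
relative sensitivities (B0 robustness of SPGR, banding behaviour of bSSFP,
PSR dominance and near-linearity over PSR 5-15 %) are robust to this
calibration, while absolute sensitivity ranges grow with the saturation depth
(T1 and exchange-rate ranges in particular).  We deliberately do not tune the
pulse power to match reported ranges.

Because the measured echo is early in the readout train, the bSSFP stop-band
null in the *transient* signal is shallow (~0.6× the on-resonance signal)
even though its location is exactly at 1/(2TR); steady-state treatments show
much deeper nulls.

## Reconstruction chain

Raw data model: 3D Cartesian segmented acquisition; each heartbeat acquires
`profiles_per_beat` readout lines at phase-encode positions (line, partition)
chosen centre-out along a golden-angle-rotated spiral-like ordering (a
simplified stand-in for variable-density Cartesian spiral-profile trajectories
that keeps their two load-bearing properties: the k-space centre is sampled
every beat, and beats interleave).  Axis convention: image axes
(x, y, z) = (left-right, foot-head, readout); k-space DC at matrix centre,
k in cycles/mm.

* **Translational correction** (beat-to-beat): navigator-derived displacement
  d = (d_LR, d_FH) per heartbeat is compensated in k-space by the Fourier
  shift theorem, `K_cor = K_acq · exp(2iπ k·d)` over the phase-encode plane.
  Navigator registration is normalized cross-correlation over integer shifts
  with a 3-point parabolic sub-pixel refinement.
* **Respiratory binning**: equal-population quantile bins (3-5) on the FH
  trace, growing the bin count if any bin exceeds the 3.5 mm width cap; the
  reference bin is the one centred nearest zero displacement
  (end-expiration).  The quantile strategy is our choice; only the count and
  width cap are prescribed.
* **CG-SENSE** per bin: conjugate gradients on the normal equations of the
  masked multi-coil Fourier encoding; stopping at relative residual 1e-6 or
  30 iterations (both configurable), residual history kept in provenance.
* **GMD**: the motion-compensated generalized matrix description solves
  `min_x Σ_b ||M_b F S W_b x − k_b||²` jointly over bins, where `W_b` warps
  the reference-bin volume to bin b.  `W_b` is a sparse trilinear
  interpolation matrix and its adjoint is the exact matrix transpose
  ("splatting"), the standard GMD practice — not an inverse warp.  Non-rigid
  registration itself is out of scope: the fields come from a plug-in
  (`fields_provider(bins)`), with the phantom's ground truth as the default
  provider in the synthetic experiments.
* **MT/REF co-registration**: exhaustive integer + parabolic sub-voxel 3D
  translation maximizing NCC, applied by Fourier shift; near-ties in the
  correlation (e.g. along an invariant axis) resolve to the smallest shift.

## Analysis metrics

* **MTR map**: voxel-wise on co-registered volumes; voxels whose reference
  intensity falls below 5 % (configurable) of the 99th-percentile reference
  maximum are invalid rather than divided; values clipped to ±100 % with the
  clip count recorded.
* **Smoothing**: per-slice 2D Gaussian, kernel 5 px, σ 3 px.  That kernel is
  heavily truncated (it is nearly a box); we renormalize the truncated
  weights and use normalized convolution so invalid voxels neither leak in
  nor get invented.
* **Scar**: threshold = remote mean − 2·SD on the (smoothed) MTR map within
  the myocardium mask; overlap = 100·|ref ∩ scar|/|ref|.  The printed
  false-positive formula in the source is its own complement (it would read
  ~100 % when almost nothing is mislabelled); the default implements the
  evident intent 100·|remote ∩ scar|/|remote| and the literal form sits
  behind a flag.
* **AHA-16**: 6+6+4 angular sectors over basal/mid/apical slabs, measured
  counterclockwise from the centre→RV-insertion ray, boundaries to the lower
  id; per-segment mean/SD, spatial variation 100·SD/mean, and intersegment
  variation of the segment means.
* **Contrast ratio** is myocardium/blood (reported values are ~2.5 with
  myocardial MTR the larger).
* **Vessel sharpness**: at each centerline point, two opposite in-plane
  profiles perpendicular to the local tangent (length 3× nominal vessel
  diameter, 0.5-voxel steps, linear interpolation); per side the edge
  gradient is the maximum absolute finite difference per voxel-step;
  VS = 100 · mean(side gradients)/centre intensity, averaged along the
  vessel.  An ideal unit tube on zero background scores exactly 100; Gibbs
  overshoot in reconstructed images can push it above 100, so VS is a
  *relative* sharpness index, meaningful between reconstructions of the same
  data.
* **CNR** = (mean blood − mean myocardium)/SD(lung ROI), SD with n−1.

## Synthetic phantoms and what they show

The **agar phantom** places one cylinder per concentration with a documented
heuristic map (PSR = 0.012·c%, T2 shortening with c, T1 ≈ 2.5 s, R = 50 Hz);
only the monotone concentration→MTR ordering is relied upon, never absolute
agar values.  The **cardiac phantom** is a short-axis LV annulus with blood
pool, an infarct sector of reduced PSR (default 8 % vs 15 %), two tubular
veins with exported centerlines, and lung/liver/pectoral blocks; blood PSR
(3 %) was chosen once so the blood/myocardium MTR contrast lands near the
reported ~2.5.  The acquisition simulator evaluates one Bloch run per unique
tissue (pseudo-steady-state signal reused for every heartbeat — the real
sequence likewise discards approach-to-steady-state beats), warps the volume
by the respiratory model per beat, applies smooth analytic RSS-normalized
coil maps, samples the beat's trajectory and adds seeded complex Gaussian
noise.  The respiratory model is a sinusoidal FH/LR translation plus an
optional smooth spatial gain that makes the motion genuinely non-rigid while
keeping the deformation Jacobian positive.

What passing these experiments shows: the algebra and geometry of the whole
chain are correct, motion correction recovers what it should, and the scar
pipeline finds a PSR-reduced sector at realistic SNR.  What they do not show:
performance on real anatomy (no torso realism, no B1 maps, no flow), real
navigator estimation (traces are emitted by the generator), or real non-rigid
registration (ground-truth fields stand in, so GMD results are upper bounds).

## Problem sizes and determinism

Default synthetic experiments use 48³-96² grids, 4-8 coils, 3-5 bins and
10-30 CG iterations, sized so the full suite and the acceptance run complete
in minutes on a single core; all randomness flows from one integer seed per
run (generator default 1234).  CSV outputs carry a provenance header and are
byte-identical across reruns with the same config and seed.
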