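# mtprep

Contrast-free assessment of myocardial scar is an attractive alternative to
late gadolinium enhancement: magnetization transfer (MT) probes the
macromolecular proton pool directly, and infarcted tissue — where
protein-rich myocytes have died — shows a reduced magnetization transfer
ratio (MTR) without any injected agent.  `mtprep` is a Python toolkit for the
3D free-breathing cardiac MTR method built on that idea.  It is written for
MR physicists and image-analysis researchers who want to simulate, prototype
or stress-test the method without a scanner:

* **`mtprep.bloch`** — a two-pool Bloch-McConnell simulator of the MT-prepared
  gated sequence.  The state `[MxA, MyA, MzA, MzB]` evolves under
  `dM/dt = A·M + b` with exchange `R`, pool-size ratio
  `PSR = M0B/(M0A+M0B)`, and bound-pool saturation
  `R_RFB = π|ω1|²G(ΔF+B0)` with a super-Lorentzian lineshape `G`; each
  piecewise-constant RF interval (dt ≈ 50 µs) is solved exactly by matrix
  exponential.  Spoiled (SPGR) and balanced (bSSFP) readouts, echo picked at
  the k-space-centre profile of the pseudo-steady-state heartbeat.
* **`mtprep.recon`** — segmented Cartesian reconstruction with beat-to-beat
  translational correction (`K_cor = K_acq·e^{2iπk·d}`), respiratory
  binning, per-bin CG-SENSE, and motion-compensated GMD
  (`min_x Σ_b ||M_b F S W_b x − k_b||²`) with plug-in motion fields.
* **`mtprep.analysis`** — MTR maps with validity floor, Gaussian smoothing,
  remote mean−2σ scar thresholding with overlap/false-positive scoring,
  AHA 16-segment statistics, blood/myocardium contrast ratio, vessel
  sharpness along a centerline, and lung-noise CNR.
* **`mtprep.phantom`** — digital agar-vial and short-axis cardiac phantoms
  (infarct sector of reduced PSR, cardiac veins, respiratory motion model)
  plus a full k-space acquisition simulator with ground truth for everything
  downstream.
* **`mtprep.workflows` / `mtprep` CLI** — sweep-table regeneration and an
  end-to-end phantom-to-metrics demo.

## Worked example

```python
from mtprep import (MYOCARDIUM, ImagingModule, MTPreparation,
                    SimulationProtocol, compute_mtr, make_sinc_pulse,
                    simulate_sequence)

pulse = make_sinc_pulse(flip_deg=800, duration=20.48e-3, bandwidth=270,
                        dt=50e-6, offset_hz=3000)
prep = MTPreparation(pulse=pulse, n_pulses=20, gap=1.5e-3)
imaging = ImagingModule("spgr", tr=3.8e-3, te=1.6e-3, flip_deg=15)
protocol = SimulationProtocol(heart_rate=65)

s_mt = simulate_sequence(MYOCARDIUM, prep, imaging, protocol)
s_ref = simulate_sequence(MYOCARDIUM, None, imaging, protocol)
print(f"{s_mt:.5f} {s_ref:.5f} {compute_mtr(s_mt, s_ref):.2f}")
```

prints

```
0.04009 0.09021 55.55
```

— the saturation train removes 55 % of the signal from myocardium-like
tissue (T1/T2 = 1100/55 ms, PSR 15 %, R = 50 Hz) at this operating point.
The scripts in `examples/` walk through the other capabilities one at a time
(B0 robustness of SPGR vs the ±156 Hz bSSFP stop bands, parameter
sensitivity, the agar MTR ladder, translational vs GMD motion correction, and
scar segmentation at SNR 30); each prints the numbers it computes and a line
on how to read them.

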