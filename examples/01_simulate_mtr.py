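"""Simulate one MT-prepared / reference signal pair and compute the MTR.

Myocardium-like tissue (T1/T2 = 1100/55 ms, bound-pool fraction 15 %,
exchange 50 Hz) is driven through the gated sequence: 20 Sinc saturation
pulses (800 deg, 3 kHz off-resonance) before an SPGR readout each heartbeat,
signal taken at the k-space-centre echo of the fifth heartbeat.
"""

from mtprep import (
    ImagingModule,
    MTPreparation,
    SimulationProtocol,
    MYOCARDIUM,
    compute_mtr,
    make_sinc_pulse,
    simulate_sequence,
)

pulse = make_sinc_pulse(flip_deg=800, duration=20.48e-3, bandwidth=270,
                        dt=50e-6, offset_hz=3000)
prep = MTPreparation(pulse=pulse, n_pulses=20, gap=1.5e-3)
imaging = ImagingModule("spgr", tr=3.8e-3, te=1.6e-3, flip_deg=15)
protocol = SimulationProtocol(heart_rate=65)

s_mt = simulate_sequence(MYOCARDIUM, prep, imaging, protocol)
s_ref = simulate_sequence(MYOCARDIUM, None, imaging, protocol)
mtr = compute_mtr(s_mt, s_ref)

print(f"MT-prepared signal : {s_mt:.5f}")
print(f"reference signal   : {s_ref:.5f}")
print(f"MTR                : {mtr:.2f} %")
print("The saturation train transfers magnetization out of the free water")
print("pool through the bound pool, lowering the MT-prepared signal; the MTR")
print("is the percent signal loss and scales with the bound-pool fraction.")
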