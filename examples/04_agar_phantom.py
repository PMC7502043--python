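"""MTR ladder across agar concentrations.

Agar gels are the standard MT calibration object: more agar means a larger
macromolecular (bound) pool.  The digital vial phantom maps concentration to
two-pool parameters and the simulated MTR must increase monotonically with
concentration.
"""

from mtprep import ImagingModule, MTPreparation, SimulationProtocol, compute_mtr, make_sinc_pulse, simulate_sequence
from mtprep.phantom import make_agar_phantom

phantom = make_agar_phantom(concentrations=(1.0, 2.0, 2.5, 5.0))
prep = MTPreparation(pulse=make_sinc_pulse(800, 20.48e-3, 270, 50e-6, 3000))
imaging = ImagingModule("spgr", 3.8e-3, 1.6e-3, 15)
protocol = SimulationProtocol()

print("agar %   PSR    MTR %")
for name, lab in phantom.label_names.items():
    if lab == 0:
        continue
    tissue = phantom.tissues[lab]
    s_mt = simulate_sequence(tissue, prep, imaging, protocol)
    s_ref = simulate_sequence(tissue, None, imaging, protocol)
    conc = name.removeprefix("vial_").removesuffix("pct")
    print(f"{conc:>5s}   {tissue.psr:.3f}  {compute_mtr(s_mt, s_ref):5.1f}")
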