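"""Contrast-free scar detection on the cardiac phantom.

The infarct sector carries a reduced bound-pool fraction (8 % vs 15 %), so
its MTR drops.  At SNR 30 the map is Gaussian-filtered and thresholded at
remote mean - 2 SD; the detected scar is scored against the ground-truth
sector (overlap, false positives, Dice).
"""

import numpy as np

from mtprep import ImagingModule, MTPreparation, SimulationProtocol, make_sinc_pulse, simulate_sequence
from mtprep.analysis import (
    dice,
    false_positive_percent,
    mtr_map,
    overlap_percent,
    scar_threshold_segmentation,
    smooth_map,
)
from mtprep.phantom import make_cardiac_phantom

rng = np.random.default_rng(11)
phantom = make_cardiac_phantom(shape=(96, 96, 8), voxel_size=(1.5, 1.5, 4.0))
# animal-study protocol: 10 pulses, 720 deg, 1.5 kHz off-resonance
prep = MTPreparation(
    pulse=make_sinc_pulse(720, 20.48e-3, 270, 50e-6, 1500), n_pulses=10
)
imaging = ImagingModule("spgr", 3.8e-3, 1.6e-3, 15)
protocol = SimulationProtocol()

signals = {
    lab: (simulate_sequence(t, prep, imaging, protocol),
          simulate_sequence(t, None, imaging, protocol))
    for lab, t in phantom.tissues.items()
}
mt = phantom.signal_volume({l: s[0] for l, s in signals.items()})
ref = phantom.signal_volume({l: s[1] for l, s in signals.items()})
sd = signals[1][1] / 30.0  # SNR 30 on the myocardial reference signal
noisy = lambda v: np.abs(
    v + sd * (rng.standard_normal(v.shape) + 1j * rng.standard_normal(v.shape))
    / np.sqrt(2)
)

m = smooth_map(mtr_map(noisy(mt), noisy(ref), voxel_size=phantom.voxel_size))
myo = phantom.mask("myocardium") | phantom.mask("scar")
remote = phantom.mask("myocardium")
scar, threshold = scar_threshold_segmentation(m, myo, remote)
truth = phantom.mask("scar")

print(f"remote MTR  : {m.values[remote & m.valid].mean():.1f} %")
print(f"scar MTR    : {m.values[truth & m.valid].mean():.1f} %")
print(f"threshold   : {threshold:.1f} %  (remote mean - 2 SD)")
print(f"overlap     : {overlap_percent(scar, truth):.1f} % of true scar detected")
print(f"false pos   : {false_positive_percent(scar, remote):.1f} % of remote mislabelled")
print(f"Dice        : {dice(scar, truth):.3f}")
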