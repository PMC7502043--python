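"""Translational vs non-rigid (GMD) motion-corrected reconstruction.

Simulates a free-breathing segmented acquisition of the cardiac phantom with
a sinusoidal respiratory translation plus a non-rigid component, then
reconstructs three ways: uncorrected, beat-to-beat translational (k-space
phase shift), and respiratory-binned GMD with the ground-truth motion fields.
Prints the image error and the cardiac-vein sharpness for each.
"""

import numpy as np

from mtprep import ImagingModule, MTPreparation, make_sinc_pulse
from mtprep.analysis import vessel_sharpness
from mtprep.phantom import (
    AcquisitionSpec,
    MotionModel,
    ground_truth_bin_fields,
    make_cardiac_phantom,
    simulate_acquisition,
)
from mtprep.recon import cg_sense, pool_beats
from mtprep.workflows import gmd_reconstruction_pipeline, translational_reconstruction

phantom = make_cardiac_phantom(shape=(48, 48, 8), voxel_size=(2.0, 2.0, 4.0))
prep = MTPreparation(pulse=make_sinc_pulse(800, 20.48e-3, 270, 50e-6, 3000))
imaging = ImagingModule("spgr", 3.8e-3, 1.6e-3, 15)
motion = MotionModel(period=4.0, amplitude_fh=6.0, amplitude_lr=1.5,
                     nonrigid_amplitude=3.0, nonrigid_scale=60.0)
acq = AcquisitionSpec(profiles_per_beat=64, n_coils=4, noise_sd=2e-4)

sim = simulate_acquisition(phantom, acq, prep, imaging, motion=motion)
truth = sim.truth_mt
nrmse = lambda img: np.linalg.norm(np.abs(img) - truth) / np.linalg.norm(truth)
veins = np.concatenate(list(phantom.centerlines.values()))

data, mask = pool_beats(sim.kspace)
img_unc = cg_sense(data, sim.coils, mask, voxel_size=phantom.voxel_size)
img_tr = translational_reconstruction(sim.kspace, sim.trace, sim.coils)
img_gmd, bins = gmd_reconstruction_pipeline(
    sim.kspace, sim.trace, sim.coils, n_bins=3,
    fields_provider=lambda b: ground_truth_bin_fields(
        sim.motion, sim.beat_times, b, phantom.shape, phantom.voxel_size
    ),
)

for name, img in (("uncorrected", img_unc.volume),
                  ("translational", img_tr.volume),
                  ("gmd (non-rigid)", img_gmd.volume)):
    print(f"{name:16s}: NRMSE = {nrmse(img):.3f}, "
          f"vein sharpness = {vessel_sharpness(np.abs(img), veins):6.1f} %")
print(f"({bins.n_bins} respiratory bins; lower NRMSE means better motion "
      "compensation. Sharpness is comparable between the two corrected images "
      "-- ghosting in the uncorrected one can fake sharp gradients.)")
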