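"""Specific-ventilation mapping on the digital phantom.

Simulates the oxygen-enhanced 140-frame series at SNR 40 for a phantom
with known per-voxel SV, estimates the SV map by template matching, and
compares the recovered map against the ground truth.
"""

import numpy as np

import lungmap as lm

phantom = lm.make_phantom(sv_mean=0.20, seed=7)
schedule = lm.default_schedule()
series = lm.simulate_sv_series(phantom, schedule, enhancement=0.12,
                               snr=40, seed=2)

sv_map = lm.estimate_sv_map(series, schedule, phantom.lung_mask, min_corr=0.5)
summary = lm.sv_summary(sv_map)

truth = phantom.sv_true[sv_map.valid_mask]
rel_err = np.abs(sv_map.sv[sv_map.valid_mask] - truth) / truth

print(f"lung voxels: {sv_map.qc['n_lung_voxels']}, "
      f"valid estimates: {sv_map.qc['n_valid']} "
      f"(flat: {sv_map.qc['n_excluded_flat']}, "
      f"low correlation: {sv_map.qc['n_excluded_low_correlation']})")
print(f"mean SV: {summary['mean_sv']:.3f} "
      f"(ground truth {phantom.sv_true[phantom.lung_mask].mean():.3f})")
print(f"relative dispersion of SV: {summary['rd_sv']:.3f}")
print(f"median |relative error| at SNR 40: {100 * np.median(rel_err):.1f}%")

# The estimator assigns each voxel the SV candidate (50 log-spaced values
# on [0.01, 10]) whose model washin/washout time course best correlates
# with the voxel's signal; correlation is amplitude- and offset-invariant,
# so no relaxivity calibration is needed.
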