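"""Image-based lung clearance index from an SV map.

Builds the SV histogram of an estimated map, constructs the composite
whole-lung washout curve, and finds the number of lung turnovers needed to
clear a tracer to 1/40 of its initial concentration.
"""

import numpy as np

import lungmap as lm
from lungmap.metrics import composite_washout

phantom = lm.make_phantom(sv_mean=0.20, seed=7)
schedule = lm.default_schedule()
series = lm.simulate_sv_series(phantom, schedule, snr=40, seed=2)
sv_map = lm.estimate_sv_map(series, schedule, phantom.lung_mask)

bins, weights = lm.sv_histogram(sv_map)
print(f"SV histogram: {bins.size} occupied grid values, "
      f"range [{bins.min():.3f}, {bins.max():.3f}]")

for n in (0, 5, 10, 20):
    print(f"  composite concentration after {n:>2d} breaths: "
          f"{composite_washout(bins, weights, n):.4f}")

res_msv = lm.image_lci(bins, weights, frc=phantom.frc)
res_vt = lm.image_lci(bins, weights, frc=phantom.frc,
                      tidal_volume=phantom.tidal_volume)
print(f"\n1/40 crossing at n_crit = {res_msv.n_crit:.2f} breaths")
print(f"LCI (mean-SV turnover, {res_msv.turnover_per_breath:.3f}/breath): "
      f"{res_msv.lci:.2f}")
print(f"LCI (VT/FRC turnover, {res_vt.turnover_per_breath:.3f}/breath): "
      f"{res_vt.lci:.2f}")

homog = lm.image_lci([float(np.sum(weights * bins))], [1.0], frc=phantom.frc)
print(f"homogeneous lung at the same mean SV would give LCI {homog.lci:.2f}")

# Heterogeneity slows the composite tail: the measured LCI exceeds the
# homogeneous-lung value at the same mean SV, and that excess is exactly
# what the index is designed to detect.
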