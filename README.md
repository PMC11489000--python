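# lungmap

Regional lung function from functional MRI of a single sagittal slice:
specific-ventilation mapping from oxygen-enhanced image time series,
arterial-spin-labelling (ASL) perfusion quantification, proton-density
mapping with in-field phantom calibration, an image-based lung clearance
index, spatial heterogeneity metrics, and the cohort statistics layer that
compares them across groups and exposures — all validated end-to-end on a
digital lung phantom with known ground truth.

The package is aimed at pulmonary-imaging researchers who work with
proton-based (non-hyperpolarised) functional lung MRI and want a tested,
reproducible reimplementation of this analysis chain, plus a forward
simulator for protocol design and power exploration when acquired human
data cannot be shared.

## The measurements

**Specific ventilation (SV)** is the regional tidal volume change over the
end-expiratory volume, SV = ΔV/V₀. After a step change in inspired O₂, a
lung unit's alveolar O₂ fraction follows the dilution recursion

    f(n+1) = (f(n) + SV · f_insp) / (1 + SV),

retaining a fraction 1/(1+SV) of resident gas per breath — so the signal
time course of each voxel over an alternating air/100%-O₂ protocol (20-breath
cycles repeated three times, 20 extra breaths on the first O₂ cycle, 140
breaths/images total) is a fingerprint of its SV. Dissolved O₂ shortens T1
and raises the inversion-recovery signal; each voxel is assigned the SV
candidate (50 log-spaced values on [0.01, 10]) whose model time course
maximises the Pearson correlation with the voxel's course. Correlation is
amplitude- and offset-invariant, so no relaxivity calibration is needed.

**Perfusion (Q)** comes from a FAIRER-style ASL pair acquired with an
inversion delay of 80% of one R–R interval: the selective−nonselective
difference carries the blood delivered to the slice during one cardiac
cycle. After coil-heterogeneity correction and calibration against a
chest-surface reference phantom of known density, delivered blood per mL
lung per cycle times heart rate gives Q in mL/min/mL. Conduit vessels are
removed with a threshold of 35% of the maximum delivered blood.

**Density** is mapped from a dual-echo acquisition (TE = 0.82/1.8 ms)
assuming monoexponential T2* decay: S0 = S₁(S₁/S₂)^(TE₁/(TE₂−TE₁)),
calibrated by the reference phantom to mL H₂O/cm³. Acquiring with both the
body and torso coils yields the coil sensitivity profile used by the ASL
stage.

**Summaries.** Each map is reduced to its spatial mean and relative
dispersion (RD = SD/mean). The SV histogram additionally yields an
image-based lung clearance index (LCI): each SV bin decays as (1+SV)^(−n)
in breath number, the frequency-weighted composite washout is solved for
its 1/40 crossing, and the crossing is converted from breaths to lung
turnovers.

**Statistics.** Pre/post contrasts use paired t-tests; between-cohort
contrasts use independent t-tests gated by Levene's test (pooled if
variances look equal, Welch otherwise); Spearman/Pearson screens run across
variables with pairwise deletion; and an exact noncentral-t power solver
reproduces post-hoc sample-size calculations.

## Worked example

```python
import numpy as np
import lungmap as lm

phantom  = lm.make_phantom(sv_mean=0.20, seed=7)     # known ground truth
schedule = lm.default_schedule()                      # 140-breath protocol
series   = lm.simulate_sv_series(phantom, schedule, snr=40, seed=2)

sv_map  = lm.estimate_sv_map(series, schedule, phantom.lung_mask)
summary = lm.sv_summary(sv_map)
rel_err = (np.abs(sv_map.sv - phantom.sv_true) / phantom.sv_true)[sv_map.valid_mask]
print(summary, float(np.median(rel_err)))
```

prints

```
{'mean_sv': 0.2033..., 'rd_sv': 0.3161..., 'n_voxels': 1467}  0.0824...
```

i.e. at SNR 40 the estimated map recovers the phantom's mean SV of 0.20
with a median per-voxel error of ~8%, and a spatial heterogeneity
(RD ≈ 0.32) matching what the phantom was built with. The other
capabilities — ASL quantification, density/coil mapping, the image-based
LCI, cohort statistics, and the one-call cohort pipeline — each have a
short narrative script in `examples/`; the full pipeline is also available
from the shell:

```sh
lungmap all --config cohort.yaml --seed 1 --out run/
```

which writes per-subject summaries, the group-comparison report,
exposure-response correlations, QC JSON, and a log (plus NIfTI maps on
request), bit-identically reproducible from config + seed.

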