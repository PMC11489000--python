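# Methods

This note documents the models implemented in `lungmap`, the assumptions
behind the digital phantom, the parameters that matter, the numerical
choices, and what validation on synthetic data does and does not show.

## Gas dilution model and SV estimation

A lung unit at end-expiratory volume V₀ taking a tidal breath SV·V₀ of gas
at inspired O₂ fraction f_insp mixes it with resident gas at fraction f:

    f ← (f + SV · f_insp) / (1 + SV).

This single-compartment, perfect-mixing recursion (no dead-space or
multi-compartment kinetics — an explicit non-goal) makes the per-breath
retention of resident gas 1/(1+SV), so after a step change the alveolar
fraction approaches the new level geometrically, and the breath count to
any plateau fraction is monotone decreasing in SV.

The breathing protocol alternates room air (F_IO₂ = 0.21) and 100% O₂ in
20-breath cycles repeated three times, with 20 extra breaths appended to
the first O₂ cycle to resolve slowly equilibrating units: 140 breaths, one
image per breath at the end-expiratory pause. The protocol starts with the
air block (the baseline); the alternative O₂-first ordering would only
relabel the template family and does not change the estimator.

Signal model: dissolved O₂ shortens T1, raising the inversion-recovery
signal. The simulator uses a linear fractional-enhancement model,
S = S_air·(1 + e·(f−0.21)/0.79) with default enhancement e = 0.12 (within
reported oxygen-enhancement magnitudes at 1.5 T). The exact relaxivity
constant is irrelevant to the estimator because template matching uses
Pearson correlation, which is invariant to per-voxel amplitude and offset;
the property is enforced by tests.

The estimator assigns each voxel the candidate from a 50-point log-spaced
grid on [0.01, 10] (covering physiologic through pathologic SV) whose
z-normalised model time course maximises the correlation with the voxel's
course. Ties break toward the smaller SV (deterministic). Voxels with flat
time courses are excluded and counted; voxels whose best correlation falls
below `min_corr` (default 0.5) are excluded from the valid mask rather than
assigned arbitrary values — vessels and background bleed land here. Large
vessels are *not* otherwise removed from SV maps; their influence on the
summaries is small and the QC reports the counts. On noiseless on-grid
phantoms recovery is exact by construction; at SNR 40 the median absolute
relative error is ~8% on the default phantom, roughly half of which is grid
quantisation (half a grid step is ~7% in relative terms).

Registration: an optional integer-pixel phase-correlation alignment of
each frame to the series median is provided for real data. Phantom series
are emitted aligned, so the pipeline default leaves it off; shifts are
logged and circular, making the operation exactly invertible and
idempotent.

## ASL perfusion

The nonselective image carries static tissue magnetisation; the selective
image additionally carries blood delivered to the slice during the
preceding cardiac cycle (inversion delay 80% of one R–R interval). The
difference, divided by the coil sensitivity field and by the
signal-per-mL-water derived from the in-field reference phantom (known
density × voxel volume), gives delivered blood in mL per mL lung per
cycle; multiplying by heart rate gives Q in mL/min/mL. The absolute
quantification chain is thus closed entirely by the in-field reference —
no assumed blood T1 or inversion efficiency enters — which also makes the
simulator round trip exact (≤1e−6 relative, noiseless).

Conduit vessels are removed where delivered blood strictly exceeds 35% of
the per-image maximum (after coil correction; correction precedes
quantification). Boundary voxels exactly at the threshold are retained. A
uniform delivered map is degenerate under this rule — every voxel would be
removed — so uniform maps are left untouched with a warning: large vessels
are definitionally outliers. Negative subtraction values (noise) are
retained in summaries; zero-clipping would bias mean Q upward. The QC
records the negative fraction and removal counts. At SNR 40 the filter
removes noise-elevated parenchymal voxels beyond the constructed vessels
(reported in QC); this mirrors threshold behaviour on acquired data. A
side effect worth knowing: because the threshold truncates only the upper
noise tail, mean Q on noisy maps is biased modestly downward (of order
10% at the default SNR, larger for low-perfusion subjects whose delivered
signal is small relative to the fixed tissue-scaled noise); the noiseless
round trip is exact, and the per-subject removal counts in the QC flag
when this is happening.

## Density and the coil field

Dual-echo signals S(TE) = S0·exp(−TE/T2*) give the closed forms
T2* = (TE₂−TE₁)/ln(S₁/S₂) and S0 = S₁·(S₁/S₂)^(TE₁/(TE₂−TE₁)). Voxels
with non-decaying signal (S₁ ≤ S₂, possible under noise) have no admissible
T2* and are flagged NaN rather than clamped. S0 is calibrated to mL H₂O/cm³
by the median S0 over the reference ROI (median is robust to ROI edge
voxels) divided by the known density; any global gain cancels.

The coil sensitivity is the torso/body S0 ratio over the lung + reference
support. Because the support is irregular and the field is sloped, plain
smoothing biases edges; the estimator therefore fits a second-order 2D
polynomial trend (the natural surface-coil falloff model) and smooths only
the residual with a Gaussian (default scale 5 voxels, exposed in config)
by normalised convolution, then normalises to median 1 over the support.
On the phantom's quadratic 1.0–2.5× ramp the recovery is exact to
numerical precision; the smoothing scale matters only for noise.

## Image-based LCI

From the SV histogram (the discrete grid values actually present, weighted
by voxel frequency), each bin clears as (1+SV)^(−n) and the composite
whole-lung washout is the weighted sum. The crossing of 1/40 of the
initial concentration is found by monotone bracketing and Brent's method
to |Δn| < 1e−6 — fractional breath counts, since integer stepping would
quantise the index by whole turnovers. Zero-SV bins never clear and would
make the index infinite; they are excluded with their weight redistributed,
a warning, and the excluded weight reported.

Converting breaths to lung turnovers is the one genuinely open design
point. Two conversions are implemented: turnover = VT/FRC when tidal
volume is available (the physiological definition of a turnover), and the
volume-weighted mean SV of the map (the aggregate ΔV/V₀ per breath) as the
fallback. On simulated cohorts the mean-SV conversion reproduces the
expected scale and group ordering of the index (controls near 5, more
heterogeneous/higher-SV lungs above), whereas the VT/FRC conversion
inverts the ordering (it divides a fixed turnover into a breath count that
grows as SV falls); the pipeline therefore reports the mean-SV conversion
as `lci` and the VT/FRC variant as `lci_vt`. For a homogeneous lung the
mean-SV conversion has the closed form LCI = s·ln40/ln(1+s), which tends
to ln 40 ≈ 3.689 as s→0 and anchors the numerical tests. Heterogeneity at
fixed mean SV always raises the index (convexity of the compartment decays)
— the property that makes it informative. The metric is an image-derived
analogue, not a replacement for hardware multiple-breath-washout LCI.

## Statistics

Paired t-tests for within-cohort pre/post contrasts; independent t-tests
for between-cohort contrasts with a Levene gate (classical mean-centred
Levene, matching the named test in standard statistical packages; p > 0.05
pools variances, otherwise Welch). The method label on every result
records which path ran. Degenerate paired inputs are explicit: all-zero
differences give (t=0, p=1); identical nonzero differences are flagged and
reported at the machine floor. Correlation screens (Spearman or Pearson)
use pairwise-complete deletion with per-test n. Raw p-values are reported,
matching common practice for exploratory screens of this size; a
Benjamini–Hochberg column is available as a clearly labelled extension.

The power solver finds the smallest per-group n whose exact two-sample
two-sided t-test power (noncentral t with nc = d√(n/2), df = 2n−2) reaches
the target, by doubling then bisection; a closed-form normal approximation
is available for comparison and agrees to within one subject at small
effect sizes. At d = 0.009, α = 0.05, power = 0.80 the requirement is
193,800 per group — the quantitative basis for declaring such an effect
physiologically null at any feasible cohort size.

## The digital phantom and synthetic cohort

Each synthetic subject is a single sagittal slice: an elliptical lung,
2–4 elliptical conduit vessels (delivered blood 5× the parenchymal mean,
safely above the 35% threshold), a chest-surface reference ROI of known
density outside the lung, and a smooth quadratic coil ramp (2.5× anterior
falling to 1.0× posterior). SV and Q fields are lognormal transforms of
Gaussian-smoothed random fields — positive, spatially correlated, with the
requested mean exactly and relative dispersion approximately; the
parenchymal Q tail is capped below the vessel filter threshold so the
filter isolates vessels by construction. Noise is additive zero-mean
Gaussian at a configurable SNR (mean lung signal / noise SD); Rician
behaviour is negligible at parenchymal SNR and Gaussian noise keeps the
oracles closed-form. Default SNR 40.

The cohort generator samples per-subject scalars at the study's
conditions: 6 controls (imaged once) and 14 exposed subjects (pre and
post); mean SV 0.15 ± 0.05 (controls) and 0.20 ± 0.07 (exposed); mean Q
1.40–1.46 ± 0.6–0.76 mL/min/mL; within-image RD targets 0.31 (SV) and
0.60 (Q); heart rate 68 ± 10.5 bpm rising 3.2 ± 4 bpm after exposure; BMI
24.6 ± 4 kg/m²; and a BMI-dependent perfusion change with slope
−0.06 mL/min/mL per kg/m² and residual SD 0.25, giving a population
BMI–ΔQ correlation near −0.7. Analyses take the lung mask and reference
ROI as given (the role of manual segmentation) and never consult the
ground-truth functional fields.

What the phantom does **not** emulate: k-space acquisition and its
artefacts, cardiac/respiratory motion and deformable misregistration,
multi-slice 3D geometry, transit delays, dead space, and between-session
physiological drift. Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the stated forward
models — not robustness to every failure mode of acquired data.

## Reproducibility and problem sizes

Every simulator is a pure function of (phantom, parameters, seed);
pipeline runs derive per-subject seeds from the master seed by stable
SeedSequence spawning indexed by cohort row, so outputs are bit-identical
across reruns and invariant to execution order, and the resolved config
(with its hash) is written next to the outputs. The default problem sizes
— 64×64 grids (matching the dual-echo acquisition matrix), 140-frame
series, 20-subject cohorts, 500–1000 replicates for the Monte-Carlo
checks — keep the full test suite and the acceptance script in the
tens-of-seconds range on one CPU while exercising every code path at the
study's actual cohort scale.
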