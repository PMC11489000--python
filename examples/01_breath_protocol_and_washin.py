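"""The oxygen washin protocol and the gas dilution recursion.

Builds the 140-breath alternating air / 100% O2 schedule and traces the
alveolar O2 fraction of lung units with different specific ventilation (SV)
through the first O2 cycle: faster-ventilating units approach the inspired
fraction in fewer breaths, which is the contrast mechanism behind SV
mapping.
"""

import numpy as np

import lungmap as lm

schedule = lm.default_schedule(breath_rate=12)
print(f"protocol length: {len(schedule)} breaths (one image per breath)")
print(f"air breaths: {np.sum(schedule.fio2 == 0.21)}, "
      f"O2 breaths: {np.sum(schedule.fio2 == 1.0)}")

print("\nbreaths to reach 63% of the new O2 plateau (first O2 cycle):")
for sv in (0.05, 0.1, 0.2, 0.4):
    f = 0.21
    for n, f_insp in enumerate(schedule.fio2[20:60], start=1):
        f = lm.gas_step(f, f_insp, sv)
        if (f - 0.21) / 0.79 >= 1 - 1 / np.e:
            print(f"  SV = {sv:.2f}: {n} breaths "
                  f"(per-breath retention 1/(1+SV) = {1/(1+sv):.3f})")
            break

# Each breath replaces a fraction SV/(1+SV) of resident gas, so the breath
# count to any plateau fraction falls as SV rises - the time course of each
# image voxel is therefore a fingerprint of its local SV.
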