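"""dEELV vs dEELI across a post-lavage recruitment PEEP sequence.

Generates the D31-D37 steps (PEEP 0, 25, 20, 15, 10, 5, 0) of a lavaged
phantom, computes quadrant end-expiratory air-volume changes from CT and
end-expiratory impedance changes from EIT between consecutive steps, and
normalizes both by their highest-PEEP regional sums before comparing.
"""
import numpy as np

import eitdect as e
from eitdect.grids import QUADRANTS

spec = e.PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(2.0, 2.0, 2.0), noise_sd_hu=20)
steps = [s for s in e.protocol_steps(66) if s.mode == "lavage"]
data = e.generate_protocol(spec, weight_kg=66, seed=6, steps=steps)

# quadrant labels restricted to the body interior so ambient air does not
# inflate the normalizing regional sums
quad_mask = e.phantom.generator_quadrant_mask(spec).restrict(e.body_mask(data[0].ct_exp))
eit_mask = e.eit_quadrant_mask(grid_size=32)

ct_levels, eit_levels, peeps = [], [], []
for sd in data:
    vols = e.region_air_volume(sd.ct_exp, quad_mask).region_ml
    ct_levels.append(np.array([vols[q] for q in QUADRANTS]))
    eit_levels.append(e.eit_analysis.end_expiratory_levels(sd.eit, eit_mask))
    peeps.append(sd.step.peep_cmH2O)

hi = int(np.argmax(peeps))
d_eelv, d_eeli = [], []
for a, b in zip(range(len(peeps) - 1), range(1, len(peeps))):
    d_eelv.append(e.normalize_to_highest_peep(ct_levels[b] - ct_levels[a], ct_levels[hi]))
    d_eeli.append(e.normalize_to_highest_peep(eit_levels[b] - eit_levels[a], eit_levels[hi]))

x, y = np.concatenate(d_eelv), np.concatenate(d_eeli)
r = e.pearson_r(x, y)
bias, lo, hi_loa = e.bland_altman(x, y)
goodness = np.mean([e.quadrant_goodness(a, b) for a, b in zip(d_eelv, d_eeli)])

print(f"pairs compared      : {len(d_eelv)} consecutive PEEP steps x 4 quadrants")
print(f"Pearson r           : {r:.3f}")
print(f"Bland-Altman        : bias {bias:+.2f}%, LoA [{lo:+.2f}, {hi_loa:+.2f}]%")
print(f"mean goodness score : {goodness:.2f} (mean |dpct|, lower is better)")
# Regional impedance change tracks regional air-volume change because both
# are driven by the same recruitment of the dorsal (dependent) lung.
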