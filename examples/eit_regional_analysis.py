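"""Regional EIT analysis of a one-lung-ventilation recording.

Synthesizes the EIT frame series of a right-sided one-lung step, segments
breaths from the global impedance waveform, forms the tidal image, and
reports quadrant percentages, the ventilated-side call and the NCCF against
the ventilator volume curve.
"""
import eitdect as e
from eitdect.grids import QUADRANTS

spec = e.PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(2.0, 2.0, 2.0), noise_sd_hu=0)
step = {s.step_id: s for s in e.protocol_steps(66, ventilated_side="right")}["D21"]
_, _, truth = e.generate_ct_pair(spec, step, seed=2)

series = e.generate_eit_series(truth, n_breaths=5, seed=3)  # default 1% pixel noise
wave = e.global_waveform(series)
seg = e.detect_breaths(wave, series.frame_rate_hz)
tidal = e.tidal_image(series, seg)
mask = e.eit_quadrant_mask(grid_size=32)
pct = e.regional_percentages(tidal, mask)
left, right = e.side_shares(pct)
vent = e.generate_ventilator_waveform(tv_ml=truth.tv_total_ml, n_breaths=5)
r, lag = e.nccf(wave, vent["volume_ml"].to_numpy(), frame_rate_hz=50.0)

print(f"breaths detected : {seg.n_breaths}")
print("quadrant %       : " + "  ".join(f"{q}={pct[q]:5.1f}" for q in QUADRANTS))
print(f"side shares      : left {left:.1f}%  right {right:.1f}%")
print(f"side call        : {e.detect_ventilated_side(left, right)} (truth: {truth.ventilated_side})")
print(f"NCCF vs ventilator: r={r:.4f} at lag {lag:.2f} s")
# Nearly all tidal intensity falls on the ventilated right side, so the
# >65% share rule identifies it; the waveforms share one breath shape (r ~ 1).
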