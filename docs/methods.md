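# Methods

## Problem and model

Electrical impedance tomography (EIT) reports *relative* regional impedance
changes; to use it quantitatively one must show that its regional signal
tracks regional air volume. The reference here is differential breath-hold
CT: paired end-inspiratory and end-expiratory volumes, converted voxel-wise
to air content. This package implements that validation chain and a
synthetic phantom with exact ground truth to exercise it.

**Densitometry.** Air content is assumed linear in CT density:
`f(HU) = clamp(−HU/1000, 0, 1)`. The anchors are physical (air ≈ −1000 HU,
water/tissue ≈ 0 HU); values below −1000 HU are clamped to 1.0 (they occur
only through noise or calibration drift) and values at or above 0 HU hold
no air. Regional air volume is the sum of voxel air fractions times the
voxel volume, accumulated in mm³ and reported in ml. Tidal volume (TV) is
end-inspiratory minus end-expiratory regional air volume; regional TV may
legitimately be negative (air redistribution between regions) and is
reported signed, never clipped.

**Belt registration.** The belt electrodes are segmented as connected
components above a metal threshold (default 2000 HU; the markers are
≈3000 HU) and reduced to world-space centroids. Ordering is anatomical:
starting from the first electrode counterclockwise past the ventral
midline, winding counterclockwise viewed from cranial. The ordered set is
registered to an ideal reference ring (n equidistant points on the unit
circle) by the closed-form least-squares similarity transform
(rotation + isotropic scale + translation; reflections rejected). The
transformed reference frame defines the belt plane, a slab of configurable
thickness (default 120 mm) and the two quadrant-splitting planes through
the ring centre. The same splitting planes, mapped into EIT pixel space,
label the EIT image, so CT and EIT regional values share one segmentation.

A genuinely open design point: the least-squares residual *cannot* select
the cyclic electrode correspondence for an equidistant belt. The
cross-covariance between the reference ring and any cyclic shift of an
equi-angular point set differs only by a rotation, so every shift achieves
the identical residual and noise would break the tie arbitrarily, rotating
the quadrant axes in 360°/n steps. The fit therefore trusts the
anatomically anchored ordering by default (`max_offset=0`); a windowed or
exhaustive search over offsets and windings remains available for
irregular belts, with fits whose belt normal opposes the ordered ring's
winding normal rejected as flipped solutions. The reported RMS residual
measures belt-shape mismatch (an elliptical thorax vs the circular
reference, ≈4 mm for the default phantom), not registration failure.

**Quadrant conventions.** World frame: +x patient-left, +y ventral,
+z cranial, millimetres. Labels: VL/VR/DL/DR (codes 1–4, 0 unclassified),
always ordered (VL, VR, DL, DR) in 4-vectors. Boundary points (signed
distance exactly 0 to a splitting plane) go to the left/ventral side, a
deterministic tie-break that is immaterial on real grids where voxel
centres avoid the planes. EIT pixel grids put ventral in the first rows
and patient-left in the later columns.

**EIT analysis.** The global waveform is the per-frame pixel sum. Breaths
are segmented as waveform maxima (end-inspiration) and minima
(end-expiration) subject to a minimum separation (1.5 s) and prominence
(25 % of the global range); boundary minima are recovered so recordings
starting at end-expiration yield complete breaths. The tidal image is the
mean over complete breaths of end-inspiratory minus preceding
end-expiratory frame — averaging over all breaths of a step reduces noise
and matches how stable tidal images are displayed clinically. Quadrant
percentages divide quadrant sums of the tidal image by the four-quadrant
total (×100); negative pixels are retained so percentages stay unbiased.
The ventilated side is called when one side's share exceeds a threshold
(default 65 %; there is no canonical rule, and the threshold is a
parameter). ΔEELI is the change in mean end-expiratory quadrant levels
between two recordings, signed later-minus-earlier (positive =
recruitment). The NCCF z-normalizes both curves on their overlap and
maximizes the Pearson correlation over integer-frame lags within ±2 s;
a positive lag means the second curve trails the first, and curves at
different rates are linearly resampled first.

**ΔEELV and normalization.** ΔEELV is computed from end-expiratory CT
scans at different PEEP settings as quadrant air-volume differences
between consecutive steps of the sequence (all-pairs pairing is available
as an option). Both ΔEELV and ΔEELI are normalized by the sum of the four
regional values at the highest PEEP setting of the sequence, ×100, which
makes the two modalities' arbitrary units comparable as percentages.

**Comparison statistics.** Pearson correlation and the paired/one-sample
t-tests go through scipy.stats; Bland–Altman reports the mean difference
and bias ± 1.96 SD limits; the goodness score is the mean absolute
difference of paired four-quadrant vectors (lower is better, 0 = identical
distributions). No multiple-testing correction is applied (α = 0.05
per test).

## The phantom: what it emulates and what it does not

The phantom is an ellipsoidal soft-tissue thorax (semi-axes 42 × 34 ×
44 mm) containing two ellipsoidal lungs (13 × 20 × 36 mm, centred at
x = ±18 mm, y = z = 0), on a 128³ grid of 0.75 mm isotropic voxels by
default — i.e. a scaled-down thorax at the CT protocol's native voxel
pitch. Air fractions are piecewise constant per quadrant and phase, so
every regional quantity has a closed-form truth (each lung is bisected
exactly by the ventral/dorsal plane and lies wholly on one side of the
sagittal plane). Lung voxels carry `HU = −1000·f` plus Gaussian noise
(default 20 HU); tissue is +40 HU; 16 electrode markers (2.25 mm radius,
3000 HU) sit equidistant *in angle* on the body surface in the belt plane,
plus two parasternal indicator markers slightly cranial of the ring,
excluded from the fit by default.

Nominal protocol tidal volumes are real-animal values (ml/kg × body
weight, e.g. 792 ml at 12 ml/kg and 66 kg); the realized air-fraction
swing is nominal TV divided by a reference total capacity of 80 ml/kg.
CT, EIT and spirometry therefore stay mutually consistent at phantom
scale, and all correlation-based analyses are scale-invariant. Healthy
expiratory aeration rises with PEEP (0.28–0.32 + 0.008/cmH₂O,
ventral>dorsal by 0.04); one-lung steps double the ventilated side's
swing and freeze the contralateral side at 0.15 expiratory fraction; the
lavage sequence fixes ventral fractions at 0.35 and moves the dorsal
expiratory fraction sigmoidally with PEEP from 0.05 (PEEP 0) to 0.55
(PEEP 25) — a qualitative model of gravity-dependent recruitment with the
swing distributed proportionally to regional aeration.

The matched EIT series deposits one Gaussian blob per quadrant (σ = N/10,
confined to its quadrant of the default 32×32 grid, unit sum), scaled by
`gain·(EELV_q + TV_q·s(t))` with a single global gain (1 intensity unit
per ml) and the shared breath shape `s`; per-pixel Gaussian noise defaults
to 1 % of the peak per-pixel tidal amplitude. Ventilator curves are
constant-flow volume-controlled: linear rise over one third of the cycle
(I:E = 1:2), exponential decay (τ = Tₑ/5) rescaled to reach zero at
end-expiration, amplitude exactly TV; pressure follows a one-compartment
model (PEEP + V/C + R·flow, C = 50 ml/cmH₂O, R = 10 cmH₂O·s/l).

Not emulated: diaphragm motion and caudal tidal displacement (so the
12-cm belt slab contains the whole phantom lung and belt-restricted TV ≈
whole-lung TV), metal streak artifacts (the CT input is assumed
artifact-free, as after virtual-monochromatic reconstruction),
cardiogenic oscillations, electrode-contact failures, and any
bioimpedance physics — EIT frames are synthesized at the image level, not
reconstructed from voltages. Passing tests therefore demonstrate that the
*pipeline* recovers known regional ventilation faithfully under realistic
noise; they say nothing about EIT's physical validity in vivo.

## Synthetic study replication

`run_study_replication` simulates a cohort (default 13 animals; weights ~
N(66, 3²) kg clipped to 61–70; 10 right- and 3 left-sided one-lung
intubations) through the 18-step protocol and pools 234 conditions. Per
animal, electrodes are detected once and the fitted quadrant mask —
restricted to the body interior so ambient air does not bias regional
sums — is reused across steps. The replication grid is 64³ at 1.5 mm
(identical 96-mm geometry to the native phantom), which keeps the full
cohort at roughly 20 s while leaving discretization error near 1 %.
Reported: TV spirometry-vs-CT and EIT-vs-belt-CT Pearson r, per-step NCCF
with a one-sample t-test against 0.9, one-lung side-call accuracy with a
paired left-right t-test, and the pooled recruitment ΔEELV-vs-ΔEELI
comparison (Pearson, Bland–Altman, goodness).

## Numerical choices and degenerate inputs

- Sums over voxels accumulate in float64 regardless of storage dtype
  (HU volumes are float32).
- All randomness flows from a single run seed through named substreams
  (`numpy.random.default_rng`); fixed seeds reproduce outputs
  bit-for-bit, including report files.
- Zero-variance curves are rejected by the NCCF and Pearson routines;
  constant waveforms segment to zero breaths with a warning; an
  unsegmentable series is a hard error for tidal images and ΔEELI.
- Degenerate t-tests (zero-variance differences) report t = 0, p = 1 when
  the differences are all zero and an infinite statistic with p = 0
  otherwise.
- A non-positive slab produces an all-unclassified mask with a warning;
  quadrant percentages are undefined (error) when the four-quadrant tidal
  total is ≤ 0.
- Lung segmentation (threshold −1000…−200 HU, components inside the
  filled body outline, size-gated at 50 % of the largest) is a
  convenience; every regional routine accepts an externally supplied mask.

## Known limitations

- The similarity fit assumes electrode identity is recoverable from
  anatomy (supine subject, known gantry orientation); a belt applied
  upside-down or heavily rotated would need the exhaustive search plus
  external disambiguation.
- Quadrant truth and mask agree exactly only because phantom lung centres
  avoid the splitting planes; real anatomy near the planes inherits the
  tie-break.
- The phantom's per-quadrant piecewise-constant aeration has no
  intra-quadrant gradients, so regional percentages are an easier target
  than in vivo; noise robustness claims should be read accordingly.
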