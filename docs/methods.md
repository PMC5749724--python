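# Methods

## Model

`cgmkin` implements the Conventional Gait Model as a direct, hierarchical
per-frame computation.  Nothing is optimized across frames: each frame's
segment frames are constructed proximal-to-distal from that frame's
markers plus constants derived once from the static trial.  This is what
makes the dynamic pass embarrassingly parallel and what fixes the
dependency structure of measurement error (a distal measurement cannot
move a proximal angle).

### Coordinates and conventions

All positions are lab-frame millimetres.  Every segment frame is
right-handed with x anterior, y toward the subject's left, z up/proximal.
Joint angles are Y–X–Z Cardan angles of the distal frame relative to the
proximal frame: α about the proximal y (flexion; pelvic tilt), β about
the rotated x (abduction; obliquity), γ about the final z (axial
rotation).  With M(i,j) the direction cosines between proximal axis i
and distal axis j,

    α = atan2(M(x,z), M(z,z))
    β = atan2(−M(y,z), √(M(y,x)² + M(y,y)²))
    γ = atan2(M(y,x), M(y,y))

Only two-argument arctangents are used.  The historical arcsine
formulation (α = asin(M(x,z)) at β = 0) is correct only up to 90° and
folds a 120° flexion to 60°; the test suite carries this as a negative
control.  β is restricted to (−90°, 90°) by the decomposition itself —
a genuine gimbal limit of any Cardan sequence, acceptable here because
joint abduction never approaches 90°.

Left-side β and γ are negated on output so adduction and internal
rotation are positive on both sides.  Angles are wrapped to (−180°, 180°].
Output order (23 channels) is fixed: pelvis XYZ; left/right hip, knee,
ankle XYZ; left/right foot progression.

### Joint centers

**Hip.**  Two regressions are available, selected by `hip_method` and
parameterized by an overridable `HipRegressionParams`:

- *Davis*: with LL the mean leg length, C = 0.115·LL − 15.3 mm,
  θ = 0.496 rad, β = 0.314 rad, AT the ASIS-trochanter distance
  (measured, or defaulted to 0.1288·LL − 48.56 mm), aa = IAD/2 and
  mr the marker radius, the displacement from the pelvis origin in
  pelvis coordinates is
  - anterior u = C·cosθ·sinβ − (AT + mr)·cosβ,
  - vertical w = −C·cosθ·cosβ − (AT + mr)·sinβ (always below the ASIS
    plane),
  - lateral aa − C·sinθ toward the respective side.
  The lateral term is written so that it points laterally (for adult
  anthropometry C·sinθ < aa, and each hip center lies on its own side
  of the midline).
- *Harrington*: with PW = |LASI − RASI|, PD = |midASIS − midPSIS|,
  anterior = −0.24·PD − 9.9, vertical = −0.16·PW − 0.04·LL − 7.1,
  lateral = 0.28·PD + 0.16·PW + 7.9 (mm, toward the respective side).
  The coefficient table is configuration: if it is absent the method
  errors rather than silently falling back to Davis.

**Knee and ankle.**  The chord function: given the proximal center P,
the lateral marker L, the wand marker W and the offset δ (width/2 +
marker radius), the joint center is the unique point in the plane of
(P, L, W) with |JC − L| = δ and a right angle at JC, on the opposite
side of the P–L line from the wand.  It is constructed as
JC = m + R(n̂, 2θ)·(P − m) with m = (P+L)/2, θ = arccos(δ/|P−L|) and
n̂ = unit((W−L) × (P−L)), and is tested against an independent
closed-form two-circle intersection.  δ ≥ |P−L| raises a "measurement
exceeds segment length" error naming the joint.  When `knee_method` is
`"medial"` and a medial knee marker is present in a frame, the knee
center is instead the KNE–KNM midpoint (per-frame detection; the chord
is the per-frame fallback).

**Foot.**  The foot frame takes its x axis from ankle-center→toe and
its y axis orthogonal to the tibia long axis.  With the foot's long
axis stored as x while the tibia's is z, the anatomical neutral (foot
perpendicular to shank) reads zero directly — this constitutes the
90° re-zeroing of the clinical dorsiflexion convention, which measures
from the long-axis-to-long-axis right angle.  Rotation of the foot
about its own long axis is unobservable from a single toe marker.

### Static calibration

The standing trial is averaged once per subject, sequentially (static
trials are short and the averaging step is cross-frame by nature):
the measured inter-ASIS distance (mean |LASI − RASI|), used when the
measurement set does not supply IAD; the resolved AT distances; and the
per-side ankle offsets — the arithmetic mean, in degrees, of the static
ankle flexion and rotation computed with offsets zero, subtracted from
every dynamic frame (the abduction component is never offset).  Frames
with any required marker missing are dropped from the averages.
Arithmetic averaging of angles is a declared convention: offsets are
near zero where it is used, so no circular-mean machinery is needed.
The calibration serializes to JSON so dynamic runs can skip
recalibration.

## Synthetic data

The generator emulates a lower-body Plug-in-Gait marker set (ASIS,
PSIS, thigh/shank wands, lateral knee/ankle, heel, toe per side) by
composing segment frames from prescribed joint-angle waveforms and
emitting markers from a placement template.  The template places the
lateral markers at width/2 + marker radius along the segment y axis and
the wands laterally at mid-segment *in the segment's frontal plane* —
the plane membership is what makes the chord construction invert the
template exactly.  Hip centers are placed with the same regression code
the engine uses.  The default subject carries the reference
anthropometry (LL 940 mm, KW 105 mm, AW 70 mm, template pelvis width
240 mm), so the percent presets map to round millimetre offsets
(5% of LL = 47 mm; 5% and 10% of KW = 5.25 and 10.5 mm).  Thigh and
shank lengths default to 0.52·LL and 0.44·LL (their sum is checked
against LL within 10%; leg length is measured ASIS-to-malleolus, so it
need not equal the sum of segment lengths).

Ground truth: pelvis, hip and knee truth are the program waveforms
themselves.  Ankle truth is expressed in the engine's projected foot
convention (see above), computed by a local mirror of the decomposition
— for pure ankle flexion the two coincide.  Noiseless round trips
recover the program to ~1e-9°, far inside the 1e-6° test tolerance.

What the generator does *not* emulate: soft-tissue artifact, marker
misplacement, occlusion patterns, physiological waveform realism, or
asymmetric anthropometry effects beyond what the measurement set
encodes.  Passing round-trip tests therefore demonstrate the internal
consistency and correct geometry of the implementation, not its
agreement with any laboratory's processed data.  `add_noise` provides
i.i.d. Gaussian marker noise for robustness checks only.

## Perturbation analysis

Offset vectors are ordered (LL, KW, AW, AT, IAD) in mm and applied
identically to both sides.  Grids are Cartesian products of
per-measurement value lists ("n values to the power of r measurements"),
with exact-duplicate vectors removed across combined grids and a
deterministic lexicographic order.  Presets: the fine grid (−5…+5 mm,
step 0.5, over LL/KW/AW → 21³ = 9261) and a doubling-increment coarse
grid ({0, ±10, ±20, ±40, ±80} mm → 9³ = 729; the exact doubling set is
configurable since several 9-value readings are possible).  Percent
presets generate ±p% of the baseline per measurement over all sign
combinations.

Every variant re-runs the static calibration (the ankle offsets depend
on the widths) and the full dynamic pass; the error series is
variant − baseline per channel and frame.  A variant that breaks a
chord precondition is flagged failed with the reason and the run
continues.  Summaries follow the structure of the standard reporting
tables: per window × joint × axis maxima combining sides and offset
signs; per-variant argmax joint and frame with modal-frame counts; and
per side × axis counts of which axis carries each joint's largest
error.  Ties break by the fixed order hip < knee < ankle, then
X < Y < Z, then the lowest frame index; frames are 0-based.

## Parallel execution

`plan_chunks` partitions [0, n) into contiguous ranges whose sizes
differ by at most one; `map_indexed`/`map_frames` run them on a
fork-based process pool.  Because every item is pure and results are
reassembled in plan order, outputs are bit-identical for every worker
count — the worker count is a throughput knob, never a numerical one.
Worker failures propagate with the item and range context.

## Numerical choices and invariances

- Chord residuals are validated to 1e-9 relative; orthonormality of
  segment frames to 1e-9; round trips asserted at 1e-6° (observed
  ~1e-9°).
- **Rigid motion**: hip/knee/ankle angles are invariant under any global
  rotation+translation of the markers.  Pelvis angles and foot
  progression are *lab-referenced by definition*; the options expose the
  lab frame and progression axis so these outputs co-rotate when the
  reference does, which is how the equivariance property is stated and
  tested.
- **Scale**: the model is dimensionally consistent — scaling marker
  positions, subject measurements and the regressions' millimetre
  intercepts (`HipRegressionParams.scaled(k)`) by a common factor leaves
  every angle unchanged.  The intercepts must scale because the
  regressions are affine in mm, not linear.
- Degenerate inputs (coincident/collinear markers, δ ≥ segment length,
  foot axis parallel to the tibia) raise typed geometry errors at the
  operation level; the frame orchestrator converts them to per-frame
  invalid flags with diagnostics, never silent zeros and never
  interpolation (inputs are assumed gap-filled upstream).

Test and acceptance problem sizes: static trials of 3–10 frames,
dynamic trials of 12–60 frames for unit tests and 500 frames for the
end-to-end squat; the chord oracle runs 1000 random configurations.
These sizes exercise every code path while keeping the default suite
fast; all tolerances above are independent of trial length.

## Known limitations

- Upper-body kinematics, kinetics, tibial torsion, flat-foot
  calibration, sole delta (accepted, unused) and gap filling are out of
  scope.
- Signs and offsets follow this package's declared conventions; they are
  consistent with the Kadaba/Grood–Suntay family but have not been
  byte-compared against any commercial implementation's output, and the
  static ankle-offset definition (mean static ankle flexion/rotation) is
  a declared convention rather than a reverse-engineered one.
- The C3D codec covers the 3-D point section (Intel format; float
  storage on write, float or scaled-integer on read); analog channels
  and event sections are ignored, and C3D stores float32, so C3D round
  trips carry ~1e-4 mm quantization where the text dialect is
  bit-exact.
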