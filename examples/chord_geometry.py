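"""The chord function: locating a joint center from two markers and a
measurement.

The knee (and ankle) joint center sits in the plane of the proximal
center, the lateral marker and the wand marker, at half the joint width
(plus the marker radius) from the lateral marker, with a right angle at
the joint center.  Run:  python examples/chord_geometry.py
"""

import numpy as np

import cgmkin as ck

P = np.array([0.0, 0.0, 10.0])   # proximal center (e.g. hip joint center)
L = np.array([0.0, 0.0, 0.0])    # lateral marker (e.g. KNE)
W = np.array([5.0, 0.0, 5.0])    # wand marker (e.g. THI)
delta = 6.0                      # offset: width/2 + marker radius

jc = ck.chord_joint_center(P, L, W, delta)
print(f"joint center: {jc}")
print(f"|JC - L| = {np.linalg.norm(jc - L):.6f}  (the offset, {delta})")
print(f"(JC-P).(JC-L) = {(jc - P) @ (jc - L):.2e}  (right angle at JC)")
print(f"|JC - P| = {np.linalg.norm(jc - P):.6f}  "
      f"(= sqrt(d^2 - delta^2) = {np.sqrt(100 - 36):.6f})")

# For the default subject the knee chord offset is KW/2 = 52.5 mm
meas = ck.default_subject().measurements
print(f"knee chord offset for KW = {meas.left_knee_width} mm: "
      f"{meas.left_knee_width / 2 + meas.marker_radius} mm")
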