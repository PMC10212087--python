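"""Predicted force ratio between old and young spheroids.

Under the sphere-between-plates Hertz model the contact force is linear
in the Young's modulus, so at any common indentation the force ratio of
two spheroids equals their modulus ratio: 680/260 ≈ 2.6 — the model's
account of why older spheroids push back ~2.5× harder.
"""

from spheromech import force_ratio, hertz_force

for delta_um in (10.0, 40.0, 80.0):
    f20 = hertz_force(680.0, 0.5, 212.5e-6, delta_um * 1e-6)
    f5 = hertz_force(260.0, 0.5, 212.5e-6, delta_um * 1e-6)
    ratio = force_ratio(680.0, 260.0, compression_m=delta_um * 1e-6)
    print(f"delta = {delta_um:5.1f} um:  F20 = {f20*1e6:6.3f} uN, "
          f"F5 = {f5*1e6:6.3f} uN, ratio = {ratio:.3f}")

# The ratio is independent of indentation depth: force scales as E for
# fixed geometry, so the 2.615 fold difference is purely the modulus ratio.
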