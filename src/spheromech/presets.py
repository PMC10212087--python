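"""Named presets for the two spheroid ages studied: day 5 and day 20.

Mechanical presets use the measured group means (size and modulus); the
actuation preset is the 1.1 V/step staircase to ~40 V producing 4.9 μm of
tip travel per step.  TEM presets carry the per-region cell/nucleus area
statistics and interstitial-space densities of the two ages.

The default cantilever stiffness is the Euler-Bernoulli value for the
printed geometry (L 1.6 mm, w 100 μm, t 15 μm) with a 4 GPa (SU-8-like)
flexure modulus: k = 3EI/L^3 ≈ 0.0824 N/m, which puts the μN-scale contact
forces of these spheroids into optically resolvable deflections (≈5-30 μm).
"""

from __future__ import annotations

from .specs import (
    ActuationProfile,
    CantileverSpec,
    SpheroidSpec,
    TemRegionPreset,
    build_actuation_profile,
)

#: 1.1 V/step from 0 to ~40 V, 4.9 μm per step at the tip (gain 4.9/1.1 μm/V).
ACTUATION: ActuationProfile = build_actuation_profile(
    volts_per_step=1.1, max_volts=40.0, gain=4.9 / 1.1
)

CANTILEVER = CantileverSpec(
    length=1.6e-3, width=100e-6, thickness=15e-6, material_modulus=4e9
)

#: Day-5 spheroids: 421 μm mean diameter, 260 Pa mean modulus.
DAY5_SPHEROID = SpheroidSpec(diameter_um=421.0, youngs_modulus_pa=260.0)
#: Day-20 spheroids: 457 μm mean diameter, 680 Pa mean modulus.
DAY20_SPHEROID = SpheroidSpec(diameter_um=457.0, youngs_modulus_pa=680.0)

SPHEROIDS = {"day5": DAY5_SPHEROID, "day20": DAY20_SPHEROID}

#: Reported spread (SD over n=6) of the measured moduli, for reporting only.
MODULUS_SD_PA = {"day5": 100.0, "day20": 150.0}
MODULUS_N = {"day5": 6, "day20": 6}

#: Per-region TEM morphology: (cell μm², nucleus μm², space density).
TEM_PRESETS: dict[str, dict[str, TemRegionPreset]] = {
    "day5": {
        "inner": TemRegionPreset("inner", 123.0, 53.0, 43.0, 19.0, 0.125, "beaded"),
        "outer": TemRegionPreset("outer", 126.0, 50.0, 41.0, 18.0, 0.140, "beaded"),
    },
    "day20": {
        "inner": TemRegionPreset("inner", 224.0, 106.0, 71.0, 43.0, 0.024, "uniform"),
        "outer": TemRegionPreset("outer", 164.0, 86.0, 46.0, 28.0, 0.105, "beaded"),
    },
}

#: Reported spread (SD over 3 spheroids) of the space densities, for reporting.
TEM_DENSITY_SD = {
    "day5": {"inner": 3.0, "outer": 2.4},
    "day20": {"inner": 0.9, "outer": 1.6},
}

PRESET_NAMES = ("day5", "day20")
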