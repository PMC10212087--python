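"""Instrument and sample specifications.

The microtweezer consists of two opposing force-sensing cantilevers driven
by a piezo actuator; a voltage staircase closes the tip-to-tip gap in equal
displacement increments.  A spheroid caught between the tips resists the
closure, bending the cantilevers; the bending (read optically) gives the
contact force, and a sphere-compression contact model gives the Young's
modulus.  These dataclasses carry the quantities that parameterize that
experiment.

Units: lengths in the dataclasses are carried in the unit named in the
field (μm for sample-scale lengths, m for cantilever geometry); mechanics
converts to SI once at its own boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._errors import ValidationError


@dataclass(frozen=True)
class ActuationProfile:
    """Commanded per-step tip motion derived from the piezo voltage staircase.

    Parameters
    ----------
    volts_per_step : float
        Voltage increment per actuation step (V).
    n_steps : int
        Number of actuation steps.
    gain : float
        Tip displacement per volt (μm/V).
    symmetric : bool
        If True (default) both tips move toward each other by
        ``per_step_displacement`` each step, so the commanded separation
        closes at twice the per-tip rate.
    """

    volts_per_step: float
    n_steps: int
    gain: float
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.volts_per_step <= 0 or self.gain <= 0:
            raise ValidationError("volts_per_step and gain must be positive")
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")

    @property
    def per_step_displacement(self) -> float:
        """Per-tip displacement per step (μm)."""
        return self.volts_per_step * self.gain

    def commanded_separations(self, initial_separation_um: float):
        """Commanded tip separation (μm) at steps 0..n_steps inclusive.

        Step 0 is the un-actuated state; step j has total per-tip travel
        j * per_step_displacement.  Strictly decreasing by construction.
        """
        import numpy as np

        closure_per_step = self.per_step_displacement * (2 if self.symmetric else 1)
        j = np.arange(self.n_steps + 1, dtype=float)
        return initial_separation_um - closure_per_step * j


def build_actuation_profile(
    volts_per_step: float, max_volts: float, gain: float, symmetric: bool = True
) -> ActuationProfile:
    """Build the staircase profile: n_steps = floor(max_volts / volts_per_step)."""
    if volts_per_step <= 0 or max_volts <= 0 or gain <= 0:
        raise ValidationError("voltage inputs and gain must be positive")
    if max_volts < volts_per_step:
        raise ValidationError("max_volts must be >= volts_per_step")
    n_steps = math.floor(max_volts / volts_per_step)
    return ActuationProfile(volts_per_step, n_steps, gain, symmetric)


@dataclass(frozen=True)
class CantileverSpec:
    """Rectangular cantilever geometry and stiffness.

    If ``spring_constant`` (N/m) is given it wins; otherwise it is derived
    from geometry and ``material_modulus`` via the Euler-Bernoulli tip-load
    relation k = 3 E I / L^3 with I = w t^3 / 12.
    """

    length: float = 1.6e-3  # m
    width: float = 100e-6  # m
    thickness: float = 15e-6  # m
    material_modulus: float | None = None  # Pa
    spring_constant: float | None = None  # N/m

    def __post_init__(self) -> None:
        for name in ("length", "width", "thickness"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.material_modulus is not None and self.material_modulus <= 0:
            raise ValidationError("material_modulus must be positive")
        if self.spring_constant is not None and self.spring_constant <= 0:
            raise ValidationError("spring_constant must be positive")


@dataclass(frozen=True)
class SpheroidSpec:
    """Homogeneous elastic sphere standing in for a spheroid.

    ``youngs_modulus == 0`` means "no spheroid" (the reference run).
    """

    diameter_um: float
    youngs_modulus_pa: float
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValidationError("diameter must be positive")
        if self.youngs_modulus_pa < 0:
            raise ValidationError("modulus must be >= 0")
        if not 0.0 <= self.poisson_ratio <= 0.5 + 1e-12:
            raise ValidationError("poisson_ratio must be in [0, 0.5]")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0


@dataclass(frozen=True)
class TemRegionPreset:
    """Per-region morphology targets for the TEM tessellation generator.

    Areas in μm²; ``target_space_density`` is the uncovered (interstitial)
    area fraction in [0, 1); ``gap_style`` is "uniform" (constant rim gap)
    or "beaded" (sinusoidally modulated gap mimicking the bead-shaped
    interstitial spaces seen between adjacent cells).
    """

    region: str
    cell_area_mean: float
    cell_area_sd: float
    nucleus_area_mean: float
    nucleus_area_sd: float
    target_space_density: float
    gap_style: str = "beaded"

    def __post_init__(self) -> None:
        if self.region not in ("inner", "outer"):
            raise ValidationError("region must be 'inner' or 'outer'")
        for name in ("cell_area_mean", "cell_area_sd", "nucleus_area_mean", "nucleus_area_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.target_space_density < 1.0:
            raise ValidationError("target_space_density must be in [0, 1)")
        if self.nucleus_area_mean >= self.cell_area_mean:
            raise ValidationError("nucleus mean area must be below cell mean area")
        if self.gap_style not in ("uniform", "beaded"):
            raise ValidationError("gap_style must be 'uniform' or 'beaded'")


def cantilever_spring_constant(spec: CantileverSpec) -> float:
    """Spring constant (N/m): explicit value if set, else 3EI/L^3."""
    if spec.spring_constant is not None:
        return spec.spring_constant
    if spec.material_modulus is None:
        raise ValidationError(
            "need either spring_constant or material_modulus on the cantilever spec"
        )
    second_moment = spec.width * spec.thickness**3 / 12.0
    return 3.0 * spec.material_modulus * second_moment / spec.length**3
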