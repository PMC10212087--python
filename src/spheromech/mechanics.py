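"""Contact mechanics: deflection → force → Young's modulus.

Model
-----
A homogeneous elastic sphere (radius R, modulus E, Poisson ratio ν) is
compressed between two rigid plates (the cantilever tips).  Each plate
contact is a Hertz sphere-on-flat contact carrying half the total
compression δ, so the force transmitted through the sphere is

    F(δ) = (4/3) · E/(1-ν²) · √R · (δ/2)^{3/2}.

The cantilever is a linear spring: F = k·d with d the tip deflection.
Equating the two closes the measurement: track the tips, difference
against a no-spheroid reference run to get d, convert to force with k,
pair with the compression δ inferred from the tip separation, and regress
F on the geometry factor g(δ) = (4/3)(1-ν²)^{-1}√R(δ/2)^{3/2} to estimate
E.  Because F is linear in E the least-squares fit is closed-form.

All public functions take sample-scale lengths in μm and convert to SI
internally; forces are N and moduli Pa throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._errors import InsufficientDataError, NoContactError, ValidationError
from .specs import CantileverSpec, cantilever_spring_constant  # noqa: F401  (re-export)

log = logging.getLogger(__name__)

_UM = 1e-6


@dataclass(frozen=True)
class ForceDisplacementCurve:
    """Per-step spheroid compression (μm) and contact force (N)."""

    compression_um: np.ndarray
    force_n: np.ndarray
    contact_step: int
    radius_um: float
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if len(self.compression_um) != len(self.force_n):
            raise ValidationError("compression and force must have equal length")
        if np.any(np.asarray(self.compression_um) < 0):
            raise ValidationError("compression must be non-negative")

    def post_contact(self) -> tuple[np.ndarray, np.ndarray]:
        """(δ, F) restricted to steps with δ > 0."""
        delta = np.asarray(self.compression_um, dtype=float)
        force = np.asarray(self.force_n, dtype=float)
        mask = delta > 0
        return delta[mask], force[mask]


@dataclass(frozen=True)
class ModulusEstimate:
    youngs_modulus_pa: float
    residual_n: float  # RMS force residual
    n_points: int
    method: str  # "closed_form" | "grid_oracle"


def hertz_force(youngs_modulus_pa: float, poisson_ratio: float, radius_m: float,
                compression_m: float) -> float:
    """Two-plate Hertz force (N) at total compression δ (m)."""
    if compression_m < 0:
        raise ValidationError("compression must be >= 0")
    if radius_m <= 0:
        raise ValidationError("radius must be positive")
    if not 0.0 <= poisson_ratio <= 0.5 + 1e-12:
        raise ValidationError("poisson_ratio must be in [0, 0.5]")
    return youngs_modulus_pa * _geometry_factor(poisson_ratio, radius_m, compression_m)


def _geometry_factor(poisson_ratio: float, radius_m, compression_m):
    """g(δ) with F = E · g(δ); vectorized over δ."""
    delta = np.asarray(compression_m, dtype=float)
    return (4.0 / 3.0) / (1.0 - poisson_ratio**2) * np.sqrt(radius_m) * (delta / 2.0) ** 1.5


def force_from_deflection(deflections_um: np.ndarray, spring_constant: float) -> np.ndarray:
    """Per-step contact force (N) from per-tip deflections (μm, shape (n, 2)).

    Force is k times the mean of the two tips' absolute deflections
    (equilibrium requires equal and opposite contact forces; averaging the
    two optical readings halves the readout noise).  A tip apparently
    pulled *inward* (deflection of the wrong sign, i.e. toward the
    spheroid) is clipped to zero with a warning.
    """
    if spring_constant <= 0:
        raise ValidationError("spring_constant must be positive")
    d = np.asarray(deflections_um, dtype=float)
    if d.ndim != 2 or d.shape[1] != 2:
        raise ValidationError("deflections must have shape (n_steps, 2)")
    # Outward deflection: top tip pushed up (negative row), bottom pushed down.
    outward = np.column_stack([-d[:, 0], d[:, 1]])
    if np.any(outward < -1e-9):
        log.warning("negative (inward) deflections clipped to 0 at %d steps",
                    int(np.sum(np.any(outward < -1e-9, axis=1))))
    outward = np.clip(outward, 0.0, None)
    return spring_constant * outward.mean(axis=1) * _UM


def compression_series(separation_um: np.ndarray, diameter_um: float
                       ) -> tuple[np.ndarray, int]:
    """Per-step compression δ (μm) and the first-contact step index.

    δ(step) = max(0, diameter - separation(step)).
    """
    if diameter_um <= 0:
        raise ValidationError("diameter must be positive")
    sep = np.asarray(separation_um, dtype=float)
    delta = np.clip(diameter_um - sep, 0.0, None)
    in_contact = np.nonzero(delta > 0)[0]
    if in_contact.size == 0:
        raise NoContactError(
            f"tip separation never fell below the diameter ({diameter_um:g} μm)")
    return delta, int(in_contact[0])


def fit_modulus(curve: ForceDisplacementCurve) -> ModulusEstimate:
    """Closed-form zero-intercept least squares for E.

    With F = E·g(δ), the LSQ estimate is E = Σ(g·F) / Σ(g²) over the
    post-contact points.  Reported residual is the RMS force error (N).
    """
    delta_um, force = curve.post_contact()
    if len(delta_um) < 2:
        raise InsufficientDataError(
            f"need >= 2 post-contact points, got {len(delta_um)}")
    if np.all(force == 0):
        log.warning("all forces are zero; reporting modulus 0")
        return ModulusEstimate(0.0, 0.0, len(delta_um), "closed_form")
    g = _geometry_factor(curve.poisson_ratio, curve.radius_um * _UM, delta_um * _UM)
    modulus = float(np.sum(g * force) / np.sum(g * g))
    residual = float(np.sqrt(np.mean((force - modulus * g) ** 2)))
    return ModulusEstimate(modulus, residual, len(delta_um), "closed_form")


def modulus_oracle(curve: ForceDisplacementCurve, modulus_grid_pa: np.ndarray
                   ) -> ModulusEstimate:
    """Exhaustive grid scan minimizing the RMS force residual.

    Independent verification path for :func:`fit_modulus`; warns if the
    minimum lands on the grid edge (grid too small).
    """
    delta_um, force = curve.post_contact()
    if len(delta_um) < 2:
        raise InsufficientDataError(
            f"need >= 2 post-contact points, got {len(delta_um)}")
    grid = np.asarray(modulus_grid_pa, dtype=float)
    g = _geometry_factor(curve.poisson_ratio, curve.radius_um * _UM, delta_um * _UM)
    residuals = np.sqrt(np.mean((force[None, :] - grid[:, None] * g[None, :]) ** 2, axis=1))
    best = int(np.argmin(residuals))
    if best in (0, len(grid) - 1):
        log.warning("grid-scan minimum at grid edge (E=%g Pa); enlarge the grid",
                    grid[best])
    return ModulusEstimate(float(grid[best]), float(residuals[best]),
                           len(delta_um), "grid_oracle")


def force_ratio(modulus_a_pa: float, modulus_b_pa: float, poisson_ratio: float = 0.5,
                radius_m: float = 212.5e-6, compression_m: float = 40e-6) -> float:
    """F(E_a)/F(E_b) at equal geometry — equals E_a/E_b under this model."""
    if modulus_b_pa <= 0:
        raise ValidationError("modulus_b must be positive")
    if compression_m <= 0:
        raise ValidationError("compression must be positive")
    return (hertz_force(modulus_a_pa, poisson_ratio, radius_m, compression_m)
            / hertz_force(modulus_b_pa, poisson_ratio, radius_m, compression_m))
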