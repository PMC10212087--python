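"""Synthetic microtweezer compression experiments.

Emulates the optical side of the stiffness measurement: two cantilever
tips approach along the vertical image axis in equal commanded steps; in
the loaded run a spheroid between them resists, deflecting each tip
outward until the cantilever restoring force k·d balances the two-plate
Hertz contact force.  Frames are rendered by stamping a tip template at
the true (sub-pixel) tip positions with additive Gaussian pixel noise, and
the exact positions/forces/compressions are returned as ground truth.

The reference run is the same actuation with modulus 0 (no spheroid) —
the control against which loaded tip positions are differenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ValidationError
from .mechanics import hertz_force
from .specs import ActuationProfile, CantileverSpec, SpheroidSpec, cantilever_spring_constant

_UM = 1e-6


@dataclass(frozen=True)
class FrameSpec:
    """Camera geometry for rendered frames (intensities in [0, 1])."""

    height_px: int = 384
    width_px: int = 128
    pixel_pitch_um: float = 2.0  # μm per pixel
    background: float = 0.12

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0 or self.pixel_pitch_um <= 0:
            raise ValidationError("frame dimensions and pixel pitch must be positive")
        if not 0.0 <= self.background < 1.0:
            raise ValidationError("background must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Exact per-step state of a simulated compression experiment.

    Arrays are indexed by step 0..n_steps (n_steps+1 entries; step 0 is the
    un-actuated state).  Positions are (row, col) in px; the same positions
    in μm are positions_px * pixel_pitch.
    """

    reference_positions_px: np.ndarray  # (n+1, 2 tips, 2)
    loaded_positions_px: np.ndarray  # (n+1, 2 tips, 2)
    deflection_um: np.ndarray  # (n+1,) per-tip deflection d
    force_n: np.ndarray  # (n+1,)
    compression_um: np.ndarray  # (n+1,) total compression δ
    separation_um: np.ndarray  # (n+1,) actual loaded tip separation
    pixel_pitch_um: float
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def make_tip_template(size: int = 21, sigma: float = 3.0, amplitude: float = 0.75
                      ) -> np.ndarray:
    """Isotropic Gaussian tip pattern; anchor is the central pixel.

    A smooth, radially symmetric template keeps the correlation peak
    parabola-friendly for sub-pixel refinement and is the same for both
    tips, so tracked anchor separations equal physical tip separations.
    """
    if size < 5 or size % 2 == 0:
        raise ValidationError("template size must be odd and >= 5")
    half = size // 2
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    return amplitude * np.exp(-(x**2 + y**2) / (2.0 * sigma**2))


def solve_equilibrium_step(commanded_separation_um: float, cantilever: CantileverSpec,
                           spheroid: SpheroidSpec) -> tuple[float, float, float]:
    """Equilibrium (deflection d μm, force F N, compression δ μm) at one step.

    Solves k·d = F_hertz(δ) with δ = max(0, D - (s_cmd + 2d)): as the tips
    deflect outward by d each, the realized separation opens to s_cmd + 2d.
    The residual k·d - F is strictly increasing in d, so bisection on
    d ∈ [0, (D - s_cmd)/2] converges; iterate to |residual| < 1e-12 N.
    """
    spring_k = cantilever_spring_constant(cantilever)
    if spring_k <= 0:
        raise ValidationError("spring constant must be positive")
    diameter = spheroid.diameter_um
    if commanded_separation_um >= diameter:
        return 0.0, 0.0, 0.0
    if spheroid.youngs_modulus_pa == 0.0:
        return 0.0, 0.0, diameter - commanded_separation_um

    def residual(d_um: float) -> float:
        delta_um = max(0.0, diameter - (commanded_separation_um + 2.0 * d_um))
        force = hertz_force(spheroid.youngs_modulus_pa, spheroid.poisson_ratio,
                            spheroid.radius_um * _UM, delta_um * _UM)
        return spring_k * d_um * _UM - force

    lo, hi = 0.0, (diameter - commanded_separation_um) / 2.0
    # residual(lo) <= 0 (pure contact force), residual(hi) > 0 (no contact left)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r = residual(mid)
        if abs(r) < 1e-12:
            lo = hi = mid
            break
        if r < 0:
            lo = mid
        else:
            hi = mid
    d_um = 0.5 * (lo + hi)
    delta_um = max(0.0, diameter - (commanded_separation_um + 2.0 * d_um))
    return d_um, spring_k * d_um * _UM, delta_um


def render_tip_frame(tip_positions_px, template: np.ndarray, frame: FrameSpec,
                     noise_sd: float = 0.0, rng: np.random.Generator | None = None
                     ) -> np.ndarray:
    """Stamp the template at each (row, col) tip position onto one frame.

    Sub-pixel positions use bilinear placement: the template is split over
    the four integer-offset stamps with bilinear weights, which is exactly
    the adjoint of bilinear sampling.  Additive Gaussian noise (sd in
    intensity units, full range = 1) is clipped to [0, 1].
    """
    th, tw = template.shape
    if th >= frame.height_px or tw >= frame.width_px:
        raise ValidationError("template must be smaller than the frame")
    anchor = np.array([th // 2, tw // 2])
    img = np.full((frame.height_px, frame.width_px), frame.background, dtype=float)

    boxes = []
    for row, col in tip_positions_px:
        top = row - anchor[0]
        left = col - anchor[1]
        r0, c0 = int(np.floor(top)), int(np.floor(left))
        fr, fc = top - r0, left - c0
        if r0 < 0 or c0 < 0 or r0 + th + 1 > frame.height_px or c0 + tw + 1 > frame.width_px:
            raise ValidationError(
                f"tip at ({row:.1f}, {col:.1f}) px leaves the field of view")
        boxes.append((r0, c0, r0 + th + 1, c0 + tw + 1))
        for dr, wr in ((0, 1 - fr), (1, fr)):
            for dc, wc in ((0, 1 - fc), (1, fc)):
                if wr * wc == 0:
                    continue
                img[r0 + dr:r0 + dr + th, c0 + dc:c0 + dc + tw] += wr * wc * template
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            a, b = boxes[i], boxes[j]
            if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                raise ValidationError("tip stamps overlap; tips too close for rendering")
    if noise_sd > 0:
        if rng is None:
            raise ValidationError("noise_sd > 0 requires an rng")
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def simulate_compression_experiment(
    profile: ActuationProfile,
    cantilever: CantileverSpec,
    spheroid: SpheroidSpec,
    frame: FrameSpec | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    initial_separation_um: float = 500.0,
    template: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, SyntheticGroundTruth]:
    """Render a reference + loaded image sequence with exact ground truth.

    Returns ``(reference_frames, loaded_frames, truth)`` where the frame
    stacks have shape (n_steps+1, H, W).  The reference run uses modulus 0;
    the loaded run solves the per-step elastic equilibrium.  All randomness
    derives from ``seed`` (two independent child streams for the two runs),
    so identical seeds give identical pixel output.
    """
    frame = frame or FrameSpec()
    template = make_tip_template() if template is None else template
    pitch = frame.pixel_pitch_um
    sep_cmd = profile.commanded_separations(initial_separation_um)
    n = profile.n_steps

    mid_row = frame.height_px / 2.0
    col = frame.width_px / 2.0
    ref_pos = np.empty((n + 1, 2, 2))
    load_pos = np.empty((n + 1, 2, 2))
    deflection = np.zeros(n + 1)
    force = np.zeros(n + 1)
    compression = np.zeros(n + 1)
    separation = np.empty(n + 1)

    for j, s_cmd in enumerate(sep_cmd):
        half_cmd_px = (s_cmd / 2.0) / pitch
        d_um, f_n, delta_um = solve_equilibrium_step(s_cmd, cantilever, spheroid)
        deflection[j], force[j], compression[j] = d_um, f_n, delta_um
        separation[j] = s_cmd + 2.0 * d_um
        d_px = d_um / pitch
        ref_pos[j] = [[mid_row - half_cmd_px, col], [mid_row + half_cmd_px, col]]
        load_pos[j] = [[mid_row - half_cmd_px - d_px, col],
                       [mid_row + half_cmd_px + d_px, col]]

    ref_rng, load_rng = [np.random.default_rng(s)
                         for s in np.random.SeedSequence(seed).spawn(2)]
    ref_frames = np.empty((n + 1, frame.height_px, frame.width_px))
    load_frames = np.empty_like(ref_frames)
    for j in range(n + 1):
        try:
            ref_frames[j] = render_tip_frame(ref_pos[j], template, frame, noise_sd, ref_rng)
            load_frames[j] = render_tip_frame(load_pos[j], template, frame, noise_sd, load_rng)
        except ValidationError as err:
            raise ValidationError(f"step {j}: {err}") from err

    truth = SyntheticGroundTruth(
        reference_positions_px=ref_pos, loaded_positions_px=load_pos,
        deflection_um=deflection, force_n=force, compression_um=compression,
        separation_um=separation, pixel_pitch_um=pitch, seed=seed,
        extras={"commanded_separation_um": sep_cmd},
    )
    return ref_frames, load_frames, truth
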