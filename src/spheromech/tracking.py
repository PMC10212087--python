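"""Template-matching tip tracking.

Recovers per-step cantilever tip positions from image sequences.  The
match score is the zero-mean normalized cross-correlation (illumination
robust), the integer peak is refined to sub-pixel precision with a
separable 1-D parabola fit, and each step searches only a window around
the previous step's position — losing the pattern raises instead of
silently drifting.  Deflections come from differencing loaded against
reference trajectories at the same step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template as _ncc_surface

from ._errors import ConstantWindowError, TrackingLostError, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TipTemplate:
    """Tip pattern raster plus the anchor pixel reported as "the tip position"."""

    raster: np.ndarray
    anchor: tuple[int, int] | None = None  # (row, col); default = center

    def __post_init__(self) -> None:
        if self.raster.ndim != 2:
            raise ValidationError("template raster must be 2-D")
        if np.ptp(self.raster) == 0:
            raise ValidationError("template must be non-constant")
        a = self.anchor_point
        if not (0 <= a[0] < self.raster.shape[0] and 0 <= a[1] < self.raster.shape[1]):
            raise ValidationError("anchor must lie inside the template")

    @property
    def anchor_point(self) -> tuple[int, int]:
        if self.anchor is not None:
            return self.anchor
        return (self.raster.shape[0] // 2, self.raster.shape[1] // 2)


@dataclass(frozen=True)
class TipTrajectory:
    """Per-step sub-pixel positions of the two tips (top, bottom)."""

    run: str  # "reference" | "loaded"
    positions_px: np.ndarray  # (n_steps+1, 2 tips, 2) -> (row, col)
    scores: np.ndarray  # (n_steps+1, 2)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("match scores must be finite")

    @property
    def n_frames(self) -> int:
        return self.positions_px.shape[0]


@dataclass(frozen=True)
class DeflectionSeries:
    """Loaded-minus-reference tip displacement projected on the compression axis.

    ``deflections_um[:, 0]`` is the top tip (negative = pushed up/outward),
    ``[:, 1]`` the bottom tip (positive = pushed down/outward).
    ``separation_um`` is the loaded tip-to-tip separation per step.
    """

    deflections_um: np.ndarray  # (n_steps+1, 2)
    separation_um: np.ndarray  # (n_steps+1,)
    pixel_pitch_um: float


def match_template(frame: np.ndarray, template: TipTemplate,
                   search_window: tuple[int, int, int, int] | None = None
                   ) -> tuple[tuple[int, int], float, np.ndarray, tuple[int, int]]:
    """Best integer match of the template inside ``search_window``.

    Returns ``(position, score, surface, surface_origin)`` where position
    is the anchor location in frame coordinates, surface the ZNCC map over
    the window and surface_origin the frame coordinate of surface[0, 0]
    (as an anchor position).  Ties break to the smallest row, then column
    (row-major argmax).  A constant window has no defined correlation.
    """
    th, tw = template.raster.shape
    if search_window is None:
        search_window = (0, 0, frame.shape[0], frame.shape[1])
    r0, c0, r1, c1 = search_window
    r0, c0 = max(0, r0), max(0, c0)
    r1, c1 = min(frame.shape[0], r1), min(frame.shape[1], c1)
    window = frame[r0:r1, c0:c1]
    if window.shape[0] < th or window.shape[1] < tw:
        raise ValidationError("search window smaller than the template")
    if np.ptp(window) == 0 or np.ptp(template.raster) == 0:
        raise ConstantWindowError("zero-variance window: correlation undefined")
    surface = _ncc_surface(window, template.raster, pad_input=False)
    peak_flat = int(np.argmax(surface))  # row-major -> documented tie-break
    pr, pc = np.unravel_index(peak_flat, surface.shape)
    score = float(surface[pr, pc])
    ar, ac = template.anchor_point
    origin = (r0 + ar, c0 + ac)
    return (origin[0] + int(pr), origin[1] + int(pc)), score, surface, origin


def refine_subpixel(surface: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Sub-pixel offset of a correlation peak via separable parabola fits.

    Fits a 1-D parabola through the peak and its two axis neighbors per
    axis; the vertex offset is clamped to [-0.5, 0.5].  A peak on the
    surface border cannot be refined and returns offset (0, 0) with a
    warning.
    """
    pr, pc = peak
    if pr <= 0 or pc <= 0 or pr >= surface.shape[0] - 1 or pc >= surface.shape[1] - 1:
        log.warning("correlation peak on surface border at %s; skipping refinement", peak)
        return 0.0, 0.0

    def _axis_offset(m1: float, p0: float, p1: float) -> float:
        denom = m1 - 2.0 * p0 + p1
        if denom == 0:
            return 0.0
        return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))

    dr = _axis_offset(surface[pr - 1, pc], surface[pr, pc], surface[pr + 1, pc])
    dc = _axis_offset(surface[pr, pc - 1], surface[pr, pc], surface[pr, pc + 1])
    return dr, dc


def track_tips(frames: np.ndarray, template: TipTemplate | np.ndarray,
               initial_positions_px, search_radius: int = 10,
               score_floor: float = 0.5, run: str = "reference") -> TipTrajectory:
    """Track both tips through an image sequence.

    ``initial_positions_px`` seeds the first frame's search; every later
    frame searches a ±``search_radius`` window around the previous
    position.  A best score below ``score_floor`` raises
    :class:`TrackingLostError` naming the step (half-correlation on a
    structured template indicates occlusion or a lost pattern).
    """
    if isinstance(template, np.ndarray):
        template = TipTemplate(template)
    init = np.asarray(initial_positions_px, dtype=float)
    if init.shape != (2, 2):
        raise ValidationError("initial_positions_px must have shape (2, 2)")
    if search_radius < 1:
        raise ValidationError("search_radius must be >= 1")
    th, tw = template.raster.shape
    ar, ac = template.anchor_point

    n = frames.shape[0]
    positions = np.empty((n, 2, 2))
    scores = np.empty((n, 2))
    prev = init.copy()
    tip_names = ("top", "bottom")
    for j in range(n):
        for t in range(2):
            # window in frame coords, sized so an anchor within ±radius is reachable
            pr, pc = int(round(prev[t, 0])), int(round(prev[t, 1]))
            window = (pr - ar - search_radius, pc - ac - search_radius,
                      pr - ar + th + search_radius, pc - ac + tw + search_radius)
            (row, col), score, surface, origin = match_template(frames[j], template, window)
            if score < score_floor:
                raise TrackingLostError(j, tip_names[t], score, score_floor)
            dr, dc = refine_subpixel(surface, (row - origin[0], col - origin[1]))
            positions[j, t] = (row + dr, col + dc)
            scores[j, t] = score
        prev = positions[j]
    return TipTrajectory(run=run, positions_px=positions, scores=scores)


def compute_deflections(loaded: TipTrajectory, reference: TipTrajectory,
                        pixel_pitch_um: float, axis=(1.0, 0.0)) -> DeflectionSeries:
    """Per-tip deflection (μm) = (loaded - reference) · axis × pixel pitch.

    ``axis`` is the compression axis as a (row, col) unit vector; the
    default is vertical (tips approach along image rows).  Also emits the
    loaded tip separation per step for the compression computation.
    """
    if loaded.n_frames != reference.n_frames:
        raise ValidationError(
            f"step-count mismatch: loaded {loaded.n_frames} vs "
            f"reference {reference.n_frames}")
    if pixel_pitch_um <= 0:
        raise ValidationError("pixel_pitch must be positive")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    diff = loaded.positions_px - reference.positions_px  # (n, 2, 2)
    deflections = (diff @ ax) * pixel_pitch_um
    sep_vec = loaded.positions_px[:, 1, :] - loaded.positions_px[:, 0, :]
    separation = (sep_vec @ ax) * pixel_pitch_um
    return DeflectionSeries(deflections_um=deflections, separation_um=separation,
                            pixel_pitch_um=pixel_pitch_um)
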