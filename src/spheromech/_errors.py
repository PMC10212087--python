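"""Exception hierarchy.

Every failure mode the pipeline can hit on valid-looking input gets its own
class so callers (and the CLI) can distinguish "your data is wrong" from
"the algorithm lost its footing".
"""


class SpheromechError(Exception):
    """Base class for all package errors."""


class ValidationError(SpheromechError, ValueError):
    """Input violates a documented precondition."""


class ConstantWindowError(SpheromechError):
    """Normalized cross-correlation is undefined on a zero-variance window."""


class TrackingLostError(SpheromechError):
    """Best template-match score fell below the score floor."""

    def __init__(self, step: int, tip: str, score: float, floor: float):
        self.step, self.tip, self.score, self.floor = step, tip, score, floor
        super().__init__(
            f"tracking lost at step {step} (tip {tip!r}): "
            f"best score {score:.3f} < floor {floor:.3f}"
        )


class NoContactError(SpheromechError):
    """Tip separation never fell below the spheroid diameter."""


class InsufficientDataError(SpheromechError):
    """Too few post-contact points to fit a modulus."""


class PanelSelectionError(SpheromechError):
    """No edge-free panel available on one side of the center panel."""

    def __init__(self, side: str):
        self.side = side
        super().__init__(f"no edge-free outer panel on the {side} side")


class ConfigError(SpheromechError):
    """Pipeline configuration failed schema validation."""
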