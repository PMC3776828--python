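"""Exception hierarchy shared across the pipeline stages."""


class VoxmouseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VoxmouseError):
    """Inconsistent configuration: mismatched sizes, invalid thresholds, bad rigs."""


class CalibrationError(VoxmouseError):
    """Calibration file missing, malformed, or inconsistent with the trial layout."""


class ScriptError(VoxmouseError):
    """A trial script epoch is internally inconsistent (e.g. standing at 50 mm/s)."""


class RenderError(VoxmouseError):
    """The synthetic shape falls outside a camera frustum; names the camera."""


class TrialLayoutError(VoxmouseError):
    """On-disk trial directory does not match the expected layout."""
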