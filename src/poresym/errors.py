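"""Exception hierarchy shared across the package."""


class PoresymError(Exception):
    """Base class for all errors raised by this package."""


class TrajectoryError(PoresymError):
    """Malformed or inconsistent trajectory input."""


class RosterMismatchError(TrajectoryError):
    """Frames of a trajectory do not share the same atom roster."""


class SelectionError(PoresymError):
    """An atom/residue selection did not match the expected atoms."""


class DegenerateInputError(PoresymError):
    """Input is too degenerate for the requested operation."""


class CalibrationDomainError(PoresymError):
    """Fluorescence ratio outside the domain of the pH calibration."""
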