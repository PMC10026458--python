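"""Exception hierarchy."""


class T2PhantomError(Exception):
    """Base class for package errors."""


class DegenerateCalibrationError(T2PhantomError):
    """Calibration rows are collinear in concentration space."""


class UnphysicalPredictionError(T2PhantomError):
    """A predicted relaxation rate is non-positive."""


class NonInvertibleModelError(T2PhantomError):
    """The 2x2 relaxivity slope matrix is singular."""


class InfeasibleTargetError(T2PhantomError):
    """A designed concentration would be negative."""


class LayoutError(T2PhantomError):
    """Phantom geometry is invalid (overlapping tubes, tube outside body)."""


class TruthError(T2PhantomError):
    """Ground-truth maps contain unphysical relaxation times."""


class ProtocolError(T2PhantomError):
    """Acquisition protocol parameters are inconsistent."""


class FormatError(T2PhantomError):
    """On-disk artifact is missing metadata or internally inconsistent."""


class ConfigError(T2PhantomError):
    """Run configuration contains unknown or invalid keys."""
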