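"""Exception hierarchy shared by all simulator modules."""


class MyomechError(Exception):
    """Base class for all simulator errors."""


class ConfigError(MyomechError):
    """A configuration value violates its schema or physical constraint."""


class InvalidKinematicsError(MyomechError):
    """A deformation state is physically inadmissible (J <= 0, non-SPD C, ...)."""


class DegenerateElementError(MyomechError):
    """A finite element has zero or negative measure."""


class SolverDivergenceError(MyomechError):
    """An ODE integration produced NaN/Inf or failed to converge."""


class NonlinearDivergenceError(MyomechError):
    """The Newton iteration did not reach tolerance within max_iter."""


class CalibrationError(MyomechError):
    """Cell-model calibration failed or was not performed."""


class EmbeddingError(MyomechError):
    """A fiber node's local coordinates left its host element."""
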