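"""Exception hierarchy shared by all pipeline stages."""


class FundusIndexError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(FundusIndexError):
    """Invalid configuration value (bad ratio, non-positive SD, unknown key...)."""


class GeometryError(FundusIndexError):
    """Degenerate or out-of-bounds geometry (coincident points, circle outside image)."""


class DataError(FundusIndexError):
    """Invalid data passed to a statistical routine."""


class MissingLandmarkError(DataError):
    """A required landmark is absent; carries the landmark's name."""

    def __init__(self, landmark: str):
        self.landmark = landmark
        super().__init__(f"missing landmark: {landmark!r}")


class UndefinedValueError(DataError):
    """A quantity is undefined for the given input (e.g. TFI of an all-black sample)."""


class DegenerateLabelError(DataError):
    """Both classes are required but only one is present."""


class CollinearityError(DataError):
    """A regression predictor is constant or exactly collinear."""


class JoinError(DataError):
    """Subject ids of two tables do not match; carries the offending ids."""

    def __init__(self, ids):
        self.ids = sorted(ids)
        super().__init__(f"subject ids do not match between tables: {self.ids}")


class StageError(FundusIndexError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


class DegenerateFoldWarning(UserWarning):
    """A cross-validation fold contained a single class; the fit may be unstable."""
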