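"""Exception hierarchy shared across the package.

Every error carries a short machine-parsable ``tag`` used by the CLI to
emit one-line diagnostics and pick exit codes (2 for usage/input problems,
1 for data, model or fit failures).
"""


class BoxbindError(Exception):
    """Base class for all package errors."""

    tag = "E_ERROR"
    exit_code = 1

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message

    def oneline(self) -> str:
        return f"{self.tag}: {self.message}"


class MotifParseError(BoxbindError):
    tag = "E_MOTIF_PARSE"
    exit_code = 2


class DataError(BoxbindError):
    tag = "E_DATA"


class InputNotFoundError(BoxbindError):
    tag = "E_INPUT_NOT_FOUND"
    exit_code = 2


class UsageError(BoxbindError):
    tag = "E_USAGE"
    exit_code = 2


class NoTransitionError(BoxbindError):
    tag = "E_NO_TRANSITION"


class ModelError(BoxbindError):
    tag = "E_MODEL"


class FitError(BoxbindError):
    tag = "E_FIT"


class StatError(BoxbindError):
    tag = "E_STAT"


class GeometryError(BoxbindError):
    tag = "E_GEOMETRY"


class ConfigError(BoxbindError):
    tag = "E_CONFIG"
    exit_code = 2
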