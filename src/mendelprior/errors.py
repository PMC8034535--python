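"""Exception hierarchy with machine-readable codes and CLI exit codes."""

from __future__ import annotations


class MendelPriorError(Exception):
    """Base error. ``code`` is a stable machine-readable identifier."""

    exit_code = 4

    def __init__(self, message: str, code: str = "internal_error"):
        super().__init__(message)
        self.code = code


class ValidationError(MendelPriorError):
    """User input violates a documented limit or format rule."""

    exit_code = 2

    def __init__(self, message: str, code: str = "validation_error"):
        super().__init__(message, code)


class DataError(MendelPriorError):
    """Reference data is inconsistent or unresolvable."""

    exit_code = 3

    def __init__(self, message: str, code: str = "data_error"):
        super().__init__(message, code)
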