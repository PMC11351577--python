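"""Exception types shared across the pipeline."""


class QlungError(Exception):
    """Base class for all package errors."""


class ValidationError(QlungError, ValueError):
    """A contract violation in user-supplied data or configuration."""


class IOErrorWithPath(QlungError, IOError):
    """An I/O failure that names the offending path."""

    def __init__(self, path, message: str):
        self.path = str(path)
        super().__init__(f"{message}: {self.path}")
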