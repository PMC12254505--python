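"""Exception types shared across the package.

The CLI maps :class:`ValidationError` to exit code 2 and
:class:`ImageIOError` to exit code 3.
"""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class ImageIOError(OSError):
    """An image file could not be read or written."""
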