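"""Exception hierarchy shared across the package.

All data-level failures derive from :class:`PeakAnnotError` so the CLI can
map them to a clean exit status without swallowing programming errors.
"""

from __future__ import annotations


class PeakAnnotError(Exception):
    """Base class for all data and usage errors raised by peakannot."""


class ValidationError(PeakAnnotError, ValueError):
    """An in-memory object violates an invariant (bad coordinates,
    duplicate names, unstranded feature where a strand is required, ...)."""


class ParseError(PeakAnnotError, ValueError):
    """A file could not be parsed; carries the path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}:"
            if line is not None:
                prefix += f"{line}:"
            prefix += " "
        elif line is not None:
            prefix = f"line {line}: "
        super().__init__(prefix + message)
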