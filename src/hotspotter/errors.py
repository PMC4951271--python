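"""Exception hierarchy shared across the package.

Exit-code mapping in the CLI: usage errors -> 1, data/input errors -> 2.
"""


class HotspotterError(Exception):
    """Base class for all package-specific errors."""


class UsageError(HotspotterError):
    """The caller violated an API contract (bad argument, wrong shapes)."""


class InputError(HotspotterError):
    """An input file is missing, unreadable, or empty of usable records."""


class ParseError(InputError):
    """A record inside an input file is malformed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(HotspotterError):
    """A configuration table is incomplete (unknown element, missing reference entry)."""


class SchemaError(HotspotterError):
    """A feature table lacks columns required by a trained model."""


class DataError(HotspotterError):
    """The data are degenerate for the requested operation (one class, no exposed atoms)."""


class DegenerateStructureError(DataError):
    """A structure admits no solution (e.g. no solvent-exposed atom for depth indexing)."""
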