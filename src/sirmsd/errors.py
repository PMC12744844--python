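"""Exception hierarchy.

Every error raised by this package derives from :class:`SirmsdError`, so
callers (and the CLI) can distinguish domain failures from programming
errors.
"""


class SirmsdError(Exception):
    """Base class for all errors raised by this package."""


class PdbParseError(SirmsdError):
    """A fixed-column PDB record could not be parsed; names the line."""


class UnsupportedFeatureError(SirmsdError):
    """Input uses a feature this package deliberately rejects (e.g. insertion codes)."""


class AnnotationError(SirmsdError):
    """Annotated-XYZ input and its atom map disagree; names the row."""


class IncompleteResidueError(SirmsdError):
    """A residue is missing expected nucleobase atoms; lists the missing names."""


class PairingError(SirmsdError):
    """Atom pairing between two models failed; lists orphans on both sides."""


class UnknownElementError(SirmsdError):
    """An element symbol has no tabulated covalent radius."""


class TopologyError(SirmsdError):
    """Bond-graph traversal reached atoms it must never reach (e.g. the backbone)."""


class AssayError(SirmsdError):
    """Invalid reporter-assay input (non-positive luminescence, degenerate SOA)."""


class QcError(SirmsdError):
    """A required quality-control flag column is absent; names it."""


class ConfigError(SirmsdError):
    """Run configuration is invalid (unknown keys, missing inputs)."""
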