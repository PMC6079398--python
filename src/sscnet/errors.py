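"""Exception hierarchy shared by every stage of the pipeline.

Each class maps to a distinct process exit code so shell callers can
distinguish bad inputs from bad configuration from bugs.
"""


class SscnetError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class InputError(SscnetError):
    """The data handed to an operation violates its contract
    (malformed file, inconsistent margins, missing genes, ...)."""

    exit_code = 3


class ConfigurationError(SscnetError):
    """The run was set up wrongly (missing column, bad parameter,
    unreadable config) — the data itself may be fine."""

    exit_code = 2
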