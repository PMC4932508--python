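"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the command-line layer:
2 = configuration problem, 3 = malformed/inconsistent input,
4 = inference produced no candidates.
"""


class DrpError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(DrpError):
    """Invalid run configuration (bad parameter, missing file path)."""

    exit_code = 2


class InputError(DrpError):
    """Input data could not be used (parse failure, inconsistency)."""

    exit_code = 3


class FormatError(InputError):
    """A file violated its expected on-disk format."""


class TopologyError(InputError):
    """Disulphide/PTM annotation inconsistent with the sequence."""


class StateError(InputError):
    """A digestion state referenced a cleavage position that is not permitted."""


class NoCandidatesError(DrpError):
    """No digestion state explained any experimental mass."""

    exit_code = 4
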