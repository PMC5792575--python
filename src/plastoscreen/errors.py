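"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: bad configuration -> 2, input parse
failure -> 3, stage failure -> 4.
"""


class PlastoscreenError(Exception):
    """Base class for package errors."""


class ConfigError(PlastoscreenError):
    """Invalid run configuration (bad flag combination, impossible plan)."""


class InputParseError(PlastoscreenError):
    """An input file could not be read or violates its format contract."""


class StageError(PlastoscreenError):
    """An analysis stage failed on otherwise well-formed inputs."""
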