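"""Exception hierarchy shared across the package."""


class MitorecombError(Exception):
    """Base class for all package-specific errors."""


class InputError(MitorecombError, ValueError):
    """Invalid user-supplied value (bad alphabet, missing chromosome, ...)."""


class ParameterError(MitorecombError, ValueError):
    """A parameter outside its documented domain."""


class CoordinateError(MitorecombError, ValueError):
    """A coordinate outside the sequence, or an overrun on a linear molecule."""


class ParseError(MitorecombError, ValueError):
    """Malformed FASTA/FASTQ/TSV input; message names the offending record."""


class DegenerateInputError(MitorecombError, ValueError):
    """Input on which the requested statistic is undefined (e.g. all-N GC)."""


class NoSupportError(MitorecombError, ValueError):
    """Frequency requested for a repeat pair with zero classified reads."""


class TopologyError(MitorecombError, ValueError):
    """Operation requires a circular molecule but got a linear one."""


class ConfigError(MitorecombError, ValueError):
    """Inconsistent simulation or pipeline configuration."""
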