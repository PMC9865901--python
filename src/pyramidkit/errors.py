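"""Exception hierarchy shared across the pipeline stages."""


class PyramidkitError(Exception):
    """Base class for all pyramidkit errors."""


class ConfigError(PyramidkitError):
    """Invalid simulation or run configuration."""


class FormatError(PyramidkitError):
    """Malformed input file (bad code, bad coordinate, unknown vocabulary)."""


class LocusError(PyramidkitError):
    """A gene locus cannot be resolved against the genotype data."""


class DegenerateClassError(PyramidkitError):
    """A genotype class required for a contrast or mean is empty."""


class DegenerateContrastError(PyramidkitError):
    """Fewer than two usable classes for a statistical contrast."""


class LabelError(PyramidkitError):
    """Unknown haplotype or group label."""


class ParseError(PyramidkitError):
    """Unparseable protein-change notation."""
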