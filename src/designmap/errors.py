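"""Exception hierarchy; exit codes map validation vs numerical failures."""


class DesignMapError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(DesignMapError):
    """Input or configuration violates a documented contract."""

    exit_code = 2


class NumericalError(DesignMapError):
    """A computation failed (rank deficiency, undefined harmonization...)."""

    exit_code = 3
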