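"""Exception hierarchy for binderep."""


class BinderepError(Exception):
    """Base class for all binderep errors."""


class InputError(BinderepError):
    """Invalid or missing user input (files, values out of range)."""


class FormatError(BinderepError):
    """A file was readable but violated the expected dialect."""


class ConfigError(BinderepError):
    """Inconsistent configuration (e.g. mismatched sketch parameters)."""


class EmptySketchError(BinderepError):
    """A bin yielded no k-mers (all contigs shorter than k)."""


class ReassemblyError(BinderepError):
    """External assembler or quality tool failed; caller should fall back."""
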