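"""Exception hierarchy shared by all stages of the screen."""


class AAAScreenError(Exception):
    """Base class for all errors raised by this package."""


class InputError(AAAScreenError):
    """Unreadable or structurally invalid input (file, record, config)."""


class ScaffoldError(AAAScreenError):
    """Scaffold derivation or validation failure."""


class TaxonomyError(AAAScreenError):
    """Inconsistent taxonomy table (dangling or cyclic synonym chains)."""


class RelationalError(AAAScreenError):
    """Occurrence records inconsistent with the screened compound set."""
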