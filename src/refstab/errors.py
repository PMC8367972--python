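"""Exception hierarchy shared across the package."""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class ParseError(RefstabError, ValueError):
    """A delimited input file could not be parsed (names the offending cell)."""


class ConfigError(RefstabError, ValueError):
    """Inconsistent or incomplete configuration / annotation."""


class DomainError(RefstabError, ValueError):
    """An operation was called outside its mathematical domain."""
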