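"""Exception hierarchy for phedas."""


class PhedasError(Exception):
    """Base class for all phedas errors."""


class VocabFormatError(PhedasError):
    """A mapping file is missing required columns or is otherwise unreadable."""


class VocabIntegrityError(PhedasError):
    """A mapping file violates an integrity constraint (e.g. one ICD-9 code
    mapped to two different phecodes)."""


class ConfigError(PhedasError):
    """A run configuration is invalid; the message enumerates every problem."""


class DegenerateIntervalError(PhedasError):
    """An interval estimate or null interval has zero width."""
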