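"""Exception hierarchy for rearingnet."""


class RearingError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RearingError):
    """An input table is missing a required column."""


class ParseError(RearingError):
    """A cell of an input table holds an unparseable or disallowed value."""


class FixtureIntegrityError(RearingError):
    """The packaged study tables fail their row-count / column-sum checks."""


class ConfigError(RearingError):
    """A simulation configuration violates its parameter constraints."""
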