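"""Exception hierarchy for vortexhab."""


class VortexHabError(Exception):
    """Base class for all vortexhab errors."""


class EmptyWettedAreaError(VortexHabError):
    """The water surface lies at or below the channel invert: no wet cells."""


class EmptyFieldError(VortexHabError):
    """A vorticity computation was requested on a grid with no wet cells."""


class UndefinedMeanError(VortexHabError):
    """An area-weighted mean was requested over an empty cell selection."""


class ContractError(VortexHabError):
    """An operation was called outside its stated preconditions."""


class DegenerateTestError(VortexHabError):
    """Rank-sum variance is zero (all pooled values identical)."""


class CalibrationError(VortexHabError):
    """Circulation calibration could not bracket the requested mean vorticity."""


class UndefinedRateError(VortexHabError):
    """A relative change was requested against a zero baseline similarity."""


class SchemaError(VortexHabError):
    """A velocity-slice file does not conform to the grid CSV schema."""
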