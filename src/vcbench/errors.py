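"""Exception hierarchy for vcbench."""


class VcbenchError(Exception):
    """Base class for all vcbench errors."""


class VcfParseError(VcbenchError):
    """A VCF file could not be parsed (malformed header, record, or sample)."""


class BedParseError(VcbenchError):
    """A BED file could not be parsed; the message names the offending line."""


class UndefinedMetricError(VcbenchError):
    """A ratio metric was requested with a zero denominator.

    Undefined metrics are signalled, never silently reported as 0 or 1;
    report writers render them as ``NA``.
    """


class UnsatisfiableFixtureError(VcbenchError):
    """A fixture spec requests a category that the region geometry cannot host."""
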