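"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes): problems
with what the user handed us (:class:`InputError`) and problems with what the
data turned out to contain (:class:`DataError`).
"""


class GtDiscordError(Exception):
    """Base class for all package errors."""


class InputError(GtDiscordError):
    """Malformed or inconsistent user input (files, flags, specs)."""


class ManifestError(InputError):
    """Sample manifest is malformed or references unknown samples/files."""


class BedFormatError(InputError):
    """Malformed BED interval (carries the offending line number)."""


class CohortSpecError(InputError):
    """Invalid synthetic-cohort specification."""


class DataError(GtDiscordError):
    """Input parsed fine but its content cannot support the computation."""


class MalformedRecordError(DataError):
    """A VCF record is internally inconsistent (e.g. GT index out of range)."""


class EmptyPanelError(DataError):
    """Zero-length genotype panel."""


class TooFewSamplesError(DataError):
    """All-vs-all comparison needs at least two samples."""


class EmptyReportError(DataError):
    """No defined discordance rates to report on."""


class UnknownSampleError(DataError):
    """A requested sample name is absent from the data."""


class InvariantError(GtDiscordError):
    """Internal count algebra violated; indicates a bug, not bad input."""
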