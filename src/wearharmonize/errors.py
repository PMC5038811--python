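"""Exception hierarchy for the harmonization pipeline.

All pipeline errors derive from :class:`WearHarmonizeError` so callers can
catch one base class; the subclasses distinguish the failure families the
parsers and the homogenizer report.
"""


class WearHarmonizeError(Exception):
    """Base class for all package errors."""


class DocumentParseError(WearHarmonizeError):
    """Malformed JSON, unparseable timestamp, or otherwise unreadable input."""


class VocabularyError(WearHarmonizeError):
    """A state label or code outside the vendor's declared vocabulary."""


class ConsistencyError(WearHarmonizeError):
    """Internally inconsistent data: negative spans, overlaps, bad ordering,
    mismatched series lengths, negative counter totals."""


class IdentityError(WearHarmonizeError):
    """Missing or empty identity fields (device, date, student)."""


class ContractError(WearHarmonizeError):
    """An API contract violation, e.g. predicting with the wrong feature set."""


class ParameterError(WearHarmonizeError):
    """An invalid generator or model parameter (non-positive mean, bad rate)."""
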