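"""Exception hierarchy for parse failures.

Every parser failure derives from :class:`ParseError` and carries the
1-based line number (where known) and the identity of the offending
source, so batch drivers can report failures per input without losing
the locus of the defect.
"""

from __future__ import annotations


class ParseError(Exception):
    """A source file could not be turned into a document."""

    def __init__(self, message: str, line_no: int | None = None,
                 source: str | None = None):
        self.reason = message
        self.line_no = line_no
        self.source = source
        parts = []
        if source:
            parts.append(f"{source}: ")
        parts.append(message)
        if line_no is not None:
            parts.append(f" (line {line_no})")
        super().__init__("".join(parts))


class MissingTabError(ParseError):
    """An item line has a section-code prefix but no tab separator."""


class OrphanLineError(ParseError):
    """A prefix-less, uncapitalized line outside any table.

    Typically produced by a value containing an embedded carriage
    return, which pushes the remainder of the value onto its own line.
    """


class SSFFactorError(ParseError):
    """A SUBJECT_SAMPLE_FACTORS factors fragment cannot be split into
    exactly one key and one value (extra or missing ':')."""


class SSFAdditionalDataError(ParseError):
    """An additional-data fragment is ambiguous: a missing ';' between
    pairs or an extra '=' makes key/value assignment undecidable."""


class MultipleDataEndError(ParseError):
    """A table's ``*_DATA_END`` fence appears more than once."""


class JSONParseError(ParseError):
    """The JSON source is not well-formed JSON."""


class NonRecordRowError(JSONParseError):
    """A table row list contains a non-object value (e.g. ``false``)."""


class TopLevelDuplicateKeyError(JSONParseError):
    """The top level of the JSON object repeats a key; this is not
    supported (duplicate keys are handled only below the top level)."""
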