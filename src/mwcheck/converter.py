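"""Format conversion and round-trip verification.

A conversion is correct exactly when the parsed output carries the same
content as the parsed input; :func:`roundtrip_check` verifies this along
arbitrary chains of formats using the consistency comparator, so
"lossless" has a single definition everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParseError
from .fileio import (
    detect_format,
    read_document,
    read_json,
    read_mwtab,
    write_json,
    write_mwtab,
)
from .model import ConsistencyDifference, MWTabDocument

__all__ = ["convert", "convert_text", "roundtrip_check", "RoundTripReport"]

_EXTENSIONS = {"mwtab": ".txt", "json": ".json"}


@dataclass
class RoundTripReport:
    """Outcome of serializing/parsing a document along a format chain."""

    path: str
    lossless: bool
    differences: list[ConsistencyDifference] = field(default_factory=list)
    error: str | None = None


def convert_text(text: str, target_format: str, force: bool = False) -> str:
    """Convert in-memory file text to the target format's text.

    Converting to the source's own format is allowed and acts as a
    normalization pass (canonical section order, harmonized rows).
    """
    if target_format not in ("mwtab", "json"):
        raise ValueError(f"unknown target format {target_format!r}")
    doc = read_document(text, force=force)
    writer = write_mwtab if target_format == "mwtab" else write_json
    return writer(doc)


def convert(input_path, target_format: str, force: bool = False,
            output_dir=None, output_path=None) -> Path:
    """Convert one file on disk; returns the output path.

    Missing output directories are created.  Parse failures propagate.
    """
    input_path = Path(input_path)
    text = input_path.read_text(encoding="utf-8")
    out_text = convert_text(text, target_format, force=force)
    if output_path is None:
        base = input_path.stem + _EXTENSIONS[target_format]
        directory = Path(output_dir) if output_dir else input_path.parent
        output_path = directory / base
    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    output_path.write_text(out_text, encoding="utf-8", newline="\n")
    return output_path


def roundtrip_check(doc: MWTabDocument, chain: list[str]) -> RoundTripReport:
    """Serialize/parse *doc* along *chain* and report losslessness.

    Every step writes the current document in the chain's format and
    reads it back; the final document is compared against the starting
    model.  Any intermediate parse failure yields ``lossless=False``
    with the error recorded.
    """
    from .consistency import compare_documents

    if not chain:
        raise ValueError("chain must contain at least one format")
    current = doc
    label = "->".join(chain)
    for fmt in chain:
        if fmt not in ("mwtab", "json"):
            raise ValueError(f"unknown format {fmt!r} in chain")
        writer = write_mwtab if fmt == "mwtab" else write_json
        reader = read_mwtab if fmt == "mwtab" else read_json
        try:
            current = reader(writer(current))
        except ParseError as exc:
            return RoundTripReport(label, lossless=False, error=str(exc))
    differences = compare_documents(doc, current)
    strict_equal = doc == current
    return RoundTripReport(label,
                           lossless=strict_equal and not differences,
                           differences=differences)
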