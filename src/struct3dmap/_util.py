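"""Small shared helpers."""

from __future__ import annotations

import re

_UNSAFE = re.compile(r"[|/\\\s]+")


def sanitize_id(identifier: str) -> str:
    """Make a protein/structure ID safe for use as a filename.

    Pipe characters (UniProt-style ``sp|P12345|NAME`` IDs), path separators
    and whitespace are replaced with underscores. The original ID is always
    preserved inside output records; only filenames are sanitized.
    """
    return _UNSAFE.sub("_", identifier)
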