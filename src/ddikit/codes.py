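"""ICD-10 code normalization.

Hospital discharge abstracts carry ICD-10-GM codes in heterogeneous
spellings ("J84.1", "j841 ", "E84.0*"). All pipeline stages operate on a
canonical form: uppercase, no dot after the three-character stem, no
trailing cross-reference markers. The canonical pattern is one letter,
two digits, then up to four alphanumerics.
"""

from __future__ import annotations

import re

from .errors import MalformedCodeError

_CANONICAL = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]{0,4}$")

# dagger/asterisk cross-reference markers and open-ended range dashes
_TRAILING_MARKERS = "-*†"


def normalize_icd_code(raw: str) -> str:
    """Return the canonical form of an ICD-10 code string.

    Uppercases, strips surrounding whitespace, removes the single dot
    after the 3-character stem and trailing ``-``/``*``/``†`` markers.

    Raises
    ------
    MalformedCodeError
        If the input is empty after stripping or the result does not
        match the canonical pattern.
    """
    if raw is None:
        raise MalformedCodeError(str(raw), "empty input")
    code = str(raw).strip().upper()
    if not code:
        raise MalformedCodeError(raw, "empty input")
    code = code.rstrip(_TRAILING_MARKERS)
    if len(code) > 3 and code[3] == ".":
        code = code[:3] + code[4:]
    if not _CANONICAL.match(code):
        raise MalformedCodeError(raw, f"normalized form {code!r} not canonical")
    return code


def is_canonical(code: str) -> bool:
    """True if ``code`` is already in canonical form."""
    return bool(_CANONICAL.match(code))
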