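"""Second-level ATC codes: validation and truncation.

The WHO Anatomical Therapeutic Chemical system classifies drugs at five
levels.  A second-level code is one anatomical main-group letter (14 letters
are in use: A, B, C, D, G, H, J, L, M, N, P, R, S, V) followed by two digits,
e.g. ``C09`` for agents acting on the renin-angiotensin system.  A full
fifth-level code is seven characters, e.g. ``C09BA03``.

Validation here is purely syntactic: no WHO index is bundled (it is licensed
and versioned), but :func:`load_allow_list` lets a user tighten validation to
an explicit set of codes.

Note the asymmetry, deliberate: :data:`FULL_ATC_PATTERN` — the pattern used to
harvest codes from search-result text — accepts any capital letter in the
first position, while :func:`parse_level2` enforces the 14 main-group letters.
Extraction favours fidelity; validation favours strictness.
"""

from __future__ import annotations

import re
from pathlib import Path

from .errors import InvalidCodeError

#: The 14 anatomical main-group letters of the ATC system.
MAIN_GROUP_LETTERS = "ABCDGHJLMNPRSV"

LEVEL2_PATTERN = re.compile(rf"^[{MAIN_GROUP_LETTERS}][0-9]{{2}}$")

#: Pattern for a full (fifth-level) ATC code as harvested from free text.
FULL_ATC_PATTERN = re.compile(r"[A-Z]\d{2}[A-Z]{2}\d{2}")


def parse_level2(text: str, allow_list: frozenset[str] | None = None) -> str:
    """Validate ``text`` as a second-level ATC code.

    Input is stripped and upper-cased before matching, so ``"b01"`` parses to
    ``"B01"``.  When ``allow_list`` is given, the code must additionally be a
    member.

    Raises
    ------
    InvalidCodeError
        If the text does not match the second-level syntax (or allow-list).
    """
    if not isinstance(text, str):
        raise InvalidCodeError(repr(text))
    candidate = text.strip().upper()
    if not LEVEL2_PATTERN.match(candidate):
        raise InvalidCodeError(text)
    if allow_list is not None and candidate not in allow_list:
        raise InvalidCodeError(text)
    return candidate


def is_level2(text: str) -> bool:
    """True iff ``text`` parses as a second-level ATC code."""
    try:
        parse_level2(text)
    except InvalidCodeError:
        return False
    return True


def truncate_to_level2(full_code: str) -> str:
    """Truncate a full seven-character ATC code to its second level.

    ``"C09BA03"`` → ``"C09"``.  The input must match
    :data:`FULL_ATC_PATTERN` in its entirety.
    """
    candidate = full_code.strip().upper()
    if not FULL_ATC_PATTERN.fullmatch(candidate):
        raise InvalidCodeError(full_code)
    return candidate[:3]


def load_allow_list(path: str | Path) -> frozenset[str]:
    """Read an optional user-supplied allow-list: one level-2 code per line.

    Blank lines and ``#`` comments are ignored; each entry must itself be a
    syntactically valid second-level code.
    """
    codes = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        entry = line.strip()
        if not entry or entry.startswith("#"):
            continue
        codes.append(parse_level2(entry))
    return frozenset(codes)
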