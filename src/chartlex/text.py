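"""Low-level text primitives: tokenization, sentence segmentation,
normalization for de-duplication.

Tokenization is lowercase, splits on non-alphanumeric characters, and keeps
hyphenated clinical compounds (``non-compliant``, ``34-week``) as single
tokens — the same unit root-prefix matching operates on.
"""
from __future__ import annotations

import re
from typing import List

from .errors import InputError

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")

#: Abbreviations (dot-stripped, lowercase) that must not end a sentence.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st",
    "pt", "pts", "dx", "hx", "fx", "appt",
    "vs", "eg", "ie", "etc", "approx", "resp",
    "wk", "wks", "yo", "mo", "hr", "min", "sec",
    "g", "kg", "mg", "cm", "mm", "lb", "oz", "no",
}

_TERMINAL_RE = re.compile(r"[.!?]+(?=\s|$)")


def tokenize(text: str) -> List[str]:
    """Lowercase word tokens; hyphenated compounds stay intact."""
    return _TOKEN_RE.findall(text.lower())


def _is_abbreviation_boundary(text: str, punct_start: int) -> bool:
    """True when the punctuation at ``punct_start`` terminates an abbreviation
    or an initial rather than a sentence."""
    if text[punct_start] != ".":
        return False
    prefix = text[:punct_start]
    m = re.search(r"([A-Za-z][A-Za-z.]*)$", prefix)
    if not m:
        return False
    token = m.group(1).replace(".", "").lower()
    if token in _ABBREVIATIONS:
        return True
    if len(token) == 1 and m.group(1)[0].isupper():  # middle initial "J."
        return True
    return False


def segment(text: str) -> List[str]:
    """Split note text into ordered sentences.

    Rule-based and deterministic: sentence boundaries are terminal
    punctuation runs followed by whitespace or end-of-text, except after a
    known abbreviation or a single-letter initial; decimals never split
    because the dot is not followed by whitespace.  Text with no terminal
    punctuation is one sentence.
    """
    if not text:
        raise InputError("cannot segment empty text")
    sentences = []
    start = 0
    for m in _TERMINAL_RE.finditer(text):
        if _is_abbreviation_boundary(text, m.start()):
            continue
        chunk = text[start:m.end()].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences if sentences else [text.strip()]


def normalize_for_dedup(text: str) -> str:
    """Casefold, strip digits, collapse whitespace — so templated sentences
    differing only in ages/dates collapse to one key."""
    lowered = re.sub(r"\d+", "", text.casefold())
    return re.sub(r"\s+", " ", lowered).strip()
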