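"""Cytogenetic-label grammar.

Fixture tokens follow the shorthand used in comparative painting tables:

* ``<chrom>[<arm>[<qual>]]`` — e.g. ``13`` (whole chromosome), ``3q``
  (whole arm), ``8qt`` (terminal q), ``1qi`` (interstitial q);
* qualifier letters: ``p`` proximal, ``i`` interstitial, ``d`` distal,
  ``t`` terminal;
* ``/`` joins a centromere-spanning composite (``12p/qp``);
* ``+`` separates two physically separate blocks (``1qp + 6pt``);
* ``or`` separates alternative assignments of one signal (``5q or 2qd``);
* the suffix words ``Inv`` and ``bi-armed`` are morphology flags, not
  positions;
* internal whitespace is arbitrary (``8 qt`` == ``8qt``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import QUALIFIERS, RegionLabel

_SIMPLE_RE = re.compile(
    r"^(?P<chrom>\d+|[XY])(?P<body>(?:[pq][pidt]?)(?:/[pq][pidt]?)*)?$"
)

#: flag words accepted after a label, mapped to canonical flag names
_FLAG_WORDS = {"inv": "inverted", "inverted": "inverted", "bi-armed": "bi-armed"}


class LabelParseError(ValueError):
    """A fixture token does not conform to the label grammar."""


@dataclass(frozen=True)
class ParsedBlock:
    """One block parsed from a fixture token: a primary label, any ``or``
    alternatives, and morphology flags."""

    label: RegionLabel
    alternatives: tuple[RegionLabel, ...] = ()
    flags: frozenset[str] = frozenset()


def parse_simple_label(token: str) -> RegionLabel:
    """Parse a single (non-composite-entry) label token such as ``8qt``,
    ``12p/qp`` or ``X``.  Whitespace inside the token is ignored."""
    cleaned = re.sub(r"\s+", "", token)
    if not cleaned:
        raise LabelParseError("empty label token")
    m = _SIMPLE_RE.match(cleaned)
    if not m:
        raise LabelParseError(f"malformed label token {token!r}")
    chrom = m.group("chrom")
    body = m.group("body")
    if not body:
        return RegionLabel(chrom)
    parts: list[tuple[str, str | None]] = []
    for piece in body.split("/"):
        arm = piece[0]
        qual = QUALIFIERS[piece[1]] if len(piece) == 2 else None
        parts.append((arm, qual))
    if len(parts) > 2:
        raise LabelParseError(
            f"malformed composite {token!r}: more than two arm segments"
        )
    if len(parts) == 2 and not (parts[0][0] == "p" and parts[1][0] == "q"):
        raise LabelParseError(
            f"malformed composite {token!r}: must span the centromere p->q"
        )
    return RegionLabel(chrom, tuple(parts))


def parse_region_label(text: str) -> list[ParsedBlock]:
    """Parse a full fixture entry into an ordered list of blocks.

    ``+``-separated parts become separate blocks; ``or`` alternatives are
    returned in the alternatives channel of each block; ``Inv``/``bi-armed``
    suffixes become flags.
    """
    if text is None or not text.strip():
        raise LabelParseError("empty token")
    blocks: list[ParsedBlock] = []
    for block_text in text.split("+"):
        if not block_text.strip():
            raise LabelParseError(f"malformed composite entry {text!r}")
        blocks.append(_parse_block(block_text))
    return blocks


def _parse_block(block_text: str) -> ParsedBlock:
    words = block_text.split()
    flags: set[str] = set()
    fragments: list[str] = []  # label fragments between separators
    labels: list[str] = []

    def flush() -> None:
        if fragments:
            labels.append("".join(fragments))
            fragments.clear()

    for word in words:
        lw = word.lower()
        if lw == "or":
            if not fragments:
                raise LabelParseError(
                    f"malformed 'or' alternative in {block_text!r}"
                )
            flush()
        elif lw in _FLAG_WORDS:
            flags.add(_FLAG_WORDS[lw])
        else:
            fragments.append(word)
    flush()
    if not labels:
        raise LabelParseError(f"no label found in {block_text!r}")
    parsed = [parse_simple_label(tok) for tok in labels]
    return ParsedBlock(
        label=parsed[0],
        alternatives=tuple(parsed[1:]),
        flags=frozenset(flags),
    )
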