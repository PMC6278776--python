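"""Parsing of DMPK repeat-interruption pattern strings.

Expanded DMPK alleles are written in the field as a block structure such as
``(CTG)n CTC (CTG)26``: a leading pure CTG tract of unknown length followed
by an ordered series of interruption and CTG blocks at the 3' end.  Units are
trinucleotides (CTG, CCG, CTC, GGC, CAG) or the CCGCTG hexamer, each with a
repeat count that is either a positive integer or ``n`` (unknown).

The parsed structure yields the *interrupted block length*: the number of
trinucleotide repeats from the first non-CTG block to the 3' end.  That count
is the constant subtracted from every sized allele to obtain the pure 5'-end
view of an interrupted expansion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "UNKNOWN",
    "PatternError",
    "InterruptionPattern",
    "parse_interruption_pattern",
    "interrupted_block_length",
]

#: Sentinel for an unspecified repeat count (the ``n`` in ``(CTG)n``).
UNKNOWN = "n"

#: Recognised repeat units.  CCGCTG is a first-class hexamer unit and
#: contributes two trinucleotides per repeat.
UNITS = ("CCGCTG", "CTG", "CCG", "CTC", "GGC", "CAG")

_HEXAMERS = {"CCGCTG"}


class PatternError(ValueError):
    """Raised for malformed pattern text or invalid block arithmetic."""


@dataclass(frozen=True)
class InterruptionPattern:
    """Parsed block structure of a repeat-interruption pattern string.

    Attributes
    ----------
    blocks : tuple of (unit, count)
        Ordered 5'→3' blocks.  ``count`` is a positive int or :data:`UNKNOWN`.
    source_text : str
        The text the pattern was parsed from ("" if built directly).
    """

    blocks: tuple[tuple[str, int | str], ...]
    source_text: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise PatternError("a pattern must contain at least one block")
        for unit, count in self.blocks:
            if unit not in UNITS:
                raise PatternError(f"unknown repeat unit {unit!r}")
            if count != UNKNOWN and (not isinstance(count, int) or count < 1):
                raise PatternError(
                    f"block ({unit}, {count!r}): count must be a positive "
                    f"integer or {UNKNOWN!r}"
                )

    @property
    def is_pure(self) -> bool:
        """True for an uninterrupted expansion: a single CTG block."""
        return len(self.blocks) == 1 and self.blocks[0][0] == "CTG"

    def format(self) -> str:
        """Canonical text form, e.g. ``(CTG)n CTC (CTG)26``."""
        parts = []
        for unit, count in self.blocks:
            if count == UNKNOWN:
                parts.append(f"({unit})n")
            elif count == 1 and unit not in _HEXAMERS:
                parts.append(unit)
            else:
                parts.append(f"({unit}){count}")
        return " ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


# One block: "(UNIT)count", "(UNIT)n", "(UNIT)_count_" or a bare unit
# (count 1).  Bold/emphasis markup (* and _) from table exports is stripped
# before tokenisation.
_BLOCK_RE = re.compile(
    r"\(\s*(?P<punit>[ACGT]+)\s*\)\s*(?:(?P<count>\d+)|(?P<n>n))"
    r"|(?P<bare>[ACGT]+)",
    re.IGNORECASE,
)


def parse_interruption_pattern(text: str) -> InterruptionPattern:
    """Parse a pattern string into an :class:`InterruptionPattern`.

    Accepts the notational variants found in published tables:
    ``(CCGCTG)_3_`` ≡ ``(CCGCTG)3``, bold markup, bare single units
    (a lone ``CCG`` is a block of count 1), and the shorthand
    ``pure CTG expansion`` for ``(CTG)n``.

    Raises
    ------
    PatternError
        If the text is empty or contains an unparseable token.
    """
    if text is None or not text.strip():
        raise PatternError("empty pattern text")
    raw = text.strip()
    if raw.lower() in {"pure", "pure ctg expansion", "(ctg)n"}:
        return InterruptionPattern((("CTG", UNKNOWN),), source_text=raw)

    cleaned = raw.replace("*", "").replace("_", "")
    blocks: list[tuple[str, int | str]] = []
    pos = 0
    while pos < len(cleaned):
        if cleaned[pos].isspace():
            pos += 1
            continue
        m = _BLOCK_RE.match(cleaned, pos)
        if m is None:
            raise PatternError(
                f"cannot parse pattern at {cleaned[pos:pos + 12]!r} "
                f"(offset {pos} of {raw!r})"
            )
        if m.group("bare"):
            # markup stripping can fuse adjacent single units ("CTG**CCG**"
            # -> "CTGCCG"); bare runs are read as consecutive trinucleotides
            run = m.group("bare").upper()
            if len(run) % 3 != 0:
                raise PatternError(
                    f"bare unit run {run!r} in {raw!r} is not a whole "
                    "number of trinucleotides"
                )
            for i in range(0, len(run), 3):
                tri = run[i:i + 3]
                if tri not in UNITS:
                    raise PatternError(
                        f"unknown repeat unit {tri!r} in {raw!r}"
                    )
                blocks.append((tri, 1))
        else:
            unit = m.group("punit").upper()
            if unit not in UNITS:
                raise PatternError(f"unknown repeat unit {unit!r} in {raw!r}")
            if m.group("n"):
                count: int | str = UNKNOWN
            else:
                count = int(m.group("count"))
                if count < 1:
                    raise PatternError(f"non-positive count in {raw!r}")
            blocks.append((unit, count))
        pos = m.end()
    return InterruptionPattern(tuple(blocks), source_text=raw)


def _tri_per_repeat(unit: str) -> int:
    return 2 if unit in _HEXAMERS else 1


def interrupted_block_length(
    pattern: InterruptionPattern, override: int | None = None
) -> int:
    """Trinucleotide length of the interrupted 3' part of an expansion.

    The interrupted part runs from the first non-CTG block to the 3' end,
    so pure CTG runs lying *between* interruptions count toward it.  A pure
    expansion has an interrupted part of 0.  When ``override`` is given it
    is returned as-is: a per-patient override is the authoritative
    subtraction constant and pattern arithmetic is only the fallback.

    Raises
    ------
    PatternError
        If an interior block has unknown count and no override is supplied.
    """
    if override is not None:
        if override < 0:
            raise PatternError("override must be non-negative")
        return int(override)
    if pattern.is_pure:
        return 0
    # locate first non-CTG block
    start = next(
        (i for i, (unit, _) in enumerate(pattern.blocks) if unit != "CTG"),
        None,
    )
    if start is None:
        return 0
    total = 0
    for unit, count in pattern.blocks[start:]:
        if count == UNKNOWN:
            raise PatternError(
                "pattern has an interior block of unknown count; supply a "
                "per-patient interrupted_block_override"
            )
        total += count * _tri_per_repeat(unit)
    return total
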