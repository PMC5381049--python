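"""Parsing and matching of PROSITE-flavoured NLS/NES motif notation.

The notation used throughout the package (and by the curated motif lists it
ships) is a small dialect of the PROSITE pattern language written inline with
amino-acid one-letter codes:

* a bare letter is a literal residue (``P`` matches proline);
* ``.`` is a wildcard matching any one of the 20 standard residues;
* ``[KR]`` is a residue class matching any listed residue;
* any of the above may carry a repeat count ``{m}`` or range ``{m,n}``,
  e.g. ``.{20,24}`` or ``K{1,4}``;
* the typographic ellipsis ``…`` is normalised to three wildcards (``...``).

Patterns are parsed into an explicit element list so that length statistics,
complexity scoring and matching all share one structural representation.
Matching is deliberately *not* delegated to a general regex engine: the
dialect needs "shortest expansion per start offset" semantics and a wildcard
that excludes ambiguity codes (``X``, ``B``, ``Z``, ``U``) and stop marks,
which a translated ``re`` pattern would not give directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "STANDARD_RESIDUES",
    "MotifElement",
    "MotifPattern",
    "MatchSpan",
    "MotifParseError",
    "parse_motif",
    "render_motif",
    "length_bounds",
    "nominal_length",
    "scan_sequence",
    "nes_consensus",
    "read_motif_file",
    "fixture_motifs",
]

#: The 20 standard amino-acid one-letter codes. Wildcards match exactly these;
#: ambiguity codes (X, B, Z, J), selenocysteine/pyrrolysine (U, O) and '*'
#: match nothing.
STANDARD_RESIDUES: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

_ELLIPSIS = "…"  # '…'


class MotifParseError(ValueError):
    """Raised for malformed motif text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class MotifElement:
    """One unit of a motif: a literal, wildcard or residue class with repeats.

    ``residues`` is empty for wildcards, a singleton for literals and holds
    two or more letters for a class.  ``residue_order`` preserves the order
    the letters were written in so rendering round-trips the source text.
    """

    kind: str  # "literal" | "wildcard" | "residue_class"
    residues: frozenset[str]
    repeat_min: int = 1
    repeat_max: int = 1
    residue_order: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("literal", "wildcard", "residue_class"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.repeat_min < 1 or self.repeat_max < self.repeat_min:
            raise ValueError(
                f"invalid repeat range {{{self.repeat_min},{self.repeat_max}}}"
            )
        if not self.residues <= STANDARD_RESIDUES:
            bad = "".join(sorted(self.residues - STANDARD_RESIDUES))
            raise ValueError(f"non-standard residue letters {bad!r}")
        if self.kind == "wildcard" and self.residues:
            raise ValueError("wildcard elements carry no residues")
        if self.kind == "literal" and len(self.residues) != 1:
            raise ValueError("literal elements carry exactly one residue")
        if self.kind == "residue_class" and len(self.residues) < 2:
            raise ValueError("residue classes need at least two residues")
        if not self.residue_order:
            object.__setattr__(self, "residue_order", tuple(sorted(self.residues)))

    @property
    def match_set(self) -> frozenset[str]:
        """Letters this element accepts at each repeated position."""
        return STANDARD_RESIDUES if self.kind == "wildcard" else self.residues


@dataclass(frozen=True)
class MotifPattern:
    """A parsed motif: the (ellipsis-normalised) source text and its elements."""

    source_text: str
    elements: tuple[MotifElement, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern has no elements")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.source_text


@dataclass(frozen=True)
class MatchSpan:
    """Half-open [start, end) coordinates of one motif occurrence."""

    start: int
    end: int
    matched_text: str


def _parse_repeat(text: str, pos: int) -> tuple[int, int, int]:
    """Parse a '{m}' or '{m,n}' suffix starting at ``pos`` (the '{')."""
    close = text.find("}", pos)
    if close < 0:
        raise MotifParseError("unclosed '{'", pos)
    body = text[pos + 1 : close]
    parts = body.split(",")
    if not body or len(parts) > 2 or not all(p.isdigit() for p in parts):
        raise MotifParseError(f"malformed repeat {{{body}}}", pos)
    lo = int(parts[0])
    hi = int(parts[-1])
    if lo < 1:
        raise MotifParseError("repeat minimum must be >= 1", pos)
    if hi < lo:
        raise MotifParseError(f"repeat minimum {lo} exceeds maximum {hi}", pos)
    return lo, hi, close + 1


def parse_motif(text: str) -> MotifPattern:
    """Parse motif notation into a :class:`MotifPattern`.

    Raises :class:`MotifParseError` (with the offending position) on empty
    input, non-standard residue letters, malformed brackets or braces, empty
    classes and inverted repeat ranges.
    """
    if not text:
        raise MotifParseError("empty motif", 0)
    norm = text.replace(_ELLIPSIS, "...")
    elements: list[MotifElement] = []
    i = 0
    n = len(norm)
    while i < n:
        ch = norm[i]
        if ch == ".":
            kind, residues, order = "wildcard", frozenset(), ()
            i += 1
        elif ch == "[":
            close = norm.find("]", i)
            if close < 0:
                raise MotifParseError("unclosed '['", i)
            letters = norm[i + 1 : close]
            if not letters:
                raise MotifParseError("empty residue class", i)
            bad = [c for c in letters if c not in STANDARD_RESIDUES]
            if bad:
                raise MotifParseError(
                    f"invalid residue {bad[0]!r} in class", i + letters.index(bad[0]) + 1
                )
            order = tuple(dict.fromkeys(letters))
            if len(order) < 2:
                raise MotifParseError("residue class needs >= 2 distinct residues", i)
            kind, residues = "residue_class", frozenset(order)
            i = close + 1
        elif ch.isalpha() and ch.isupper():
            if ch not in STANDARD_RESIDUES:
                raise MotifParseError(f"non-standard residue letter {ch!r}", i)
            kind, residues, order = "literal", frozenset(ch), (ch,)
            i += 1
        else:
            raise MotifParseError(f"unexpected character {ch!r}", i)
        lo, hi = 1, 1
        if i < n and norm[i] == "{":
            lo, hi, i = _parse_repeat(norm, i)
        elements.append(
            MotifElement(kind=kind, residues=residues, repeat_min=lo,
                         repeat_max=hi, residue_order=order)
        )
    return MotifPattern(source_text=norm, elements=tuple(elements))


def render_motif(p: MotifPattern) -> str:
    """Render a pattern back to dialect text (inverse of :func:`parse_motif`)."""
    parts: list[str] = []
    for e in p.elements:
        if e.kind == "wildcard":
            base = "."
        elif e.kind == "literal":
            base = next(iter(e.residues))
        else:
            base = "[" + "".join(e.residue_order) + "]"
        if e.repeat_min == e.repeat_max == 1:
            suffix = ""
        elif e.repeat_min == e.repeat_max:
            suffix = f"{{{e.repeat_min}}}"
        else:
            suffix = f"{{{e.repeat_min},{e.repeat_max}}}"
        parts.append(base + suffix)
    return "".join(parts)


def length_bounds(p: MotifPattern) -> tuple[int, int]:
    """Minimum and maximum number of residues a match can span."""
    return (
        sum(e.repeat_min for e in p.elements),
        sum(e.repeat_max for e in p.elements),
    )


def nominal_length(p: MotifPattern) -> int:
    """Nominal residue length of a motif.

    For fixed-length motifs this is just the length; for variable-length
    motifs it is the midpoint of the (min, max) span, rounded half-up, the
    convention under which the bipartite patterns ``K[RK]{3,5}.{11,18}[RK]K
    .{2,3}K`` and ``[KR]{4}.{20,24}K{1,4}.K`` measure 25 and 31 residues.
    """
    lo, hi = length_bounds(p)
    return (lo + hi + 1) // 2


def _match_end(elements: tuple[MotifElement, ...], seq: str, start: int) -> int | None:
    """Smallest end offset of a match anchored at ``start``, or None.

    Dynamic programme over elements: the set of offsets reachable after
    consuming each element.  Equivalent to enumerating every concrete
    expansion and taking the shortest one that matches.
    """
    n = len(seq)
    offsets: Iterable[int] = (start,)
    for e in elements:
        allowed = e.match_set
        lo, hi = e.repeat_min, e.repeat_max
        nxt: set[int] = set()
        for o in offsets:
            run = 0
            cap = min(hi, n - o)
            while run < cap and seq[o + run] in allowed:
                run += 1
            if run >= lo:
                nxt.update(range(o + lo, o + run + 1))
        if not nxt:
            return None
        offsets = nxt
    return min(offsets)


def scan_sequence(p: MotifPattern, seq: str) -> list[MatchSpan]:
    """All matches of ``p`` in ``seq``, one span per matching start offset.

    At each start offset the shortest matching expansion is reported, so
    spans may overlap across offsets but never share a start.  ``seq`` is
    expected uppercase; letters outside the 20 standard residues never
    match any element.
    """
    min_len, _ = length_bounds(p)
    n = len(seq)
    if n < min_len:
        return []
    first = p.elements[0].match_set
    spans: list[MatchSpan] = []
    last_start = n - min_len
    for start in range(last_start + 1):
        if seq[start] not in first:
            continue
        end = _match_end(p.elements, seq, start)
        if end is not None:
            spans.append(MatchSpan(start=start, end=end, matched_text=seq[start:end]))
    return spans


def nes_consensus() -> MotifPattern:
    """The classical leucine-rich nuclear export signal consensus.

    L-x(2,3)-[LIVFM]-x(2,3)-L-x-[LI]: hydrophobic anchor residues at regular
    spacing, the signature recognised by the exportin CRM1.
    """
    return parse_motif("L.{2,3}[LIVFM].{2,3}L.[LI]")


def read_motif_file(path: str | Path) -> list[MotifPattern]:
    """Read a motif list: one motif per line, '#' starts a comment, blanks skipped."""
    patterns: list[MotifPattern] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            patterns.append(parse_motif(line))
    return patterns


def fixture_motifs() -> list[MotifPattern]:
    """The 16 curated NLS-like motifs shipped with the package."""
    from importlib.resources import files

    text = files("nlscan.data").joinpath("nls_motifs.txt").read_text()
    patterns = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            patterns.append(parse_motif(line))
    return patterns


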