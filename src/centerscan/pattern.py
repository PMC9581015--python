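"""PROSITE-dialect motif patterns: parsing, rendering, relaxation and matching.

A search motif for a protein functional center is an ordered list of
elements, each of which is one of

* a **fixed** residue, e.g. ``H`` (optionally repeated, ``A(3)``);
* a residue **class** in square brackets, e.g. ``[KR]`` — any listed
  residue matches;
* an **excluded class** in curly braces, e.g. ``{P}`` — any standard
  residue *not* listed matches (standard PROSITE semantics);
* a ranged **wildcard**, ``x``, ``x(N)`` or ``x(N,M)`` — between N and M
  arbitrary residues.

Two surface dialects are accepted: the compact form used throughout this
package (``[KS]x[CGS]x(10)[KR]``) and hyphen-separated PROSITE
(``H-x(12)-P``).  ``<`` and ``>`` anchor a pattern to the N-/C-terminus.
Coordinates in all match output are 1-based with inclusive ends, the
ScanProsite convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "STANDARD_AA",
    "AMBIGUOUS_AA",
    "PatternElement",
    "MotifPattern",
    "MatchSpan",
    "PatternParseError",
    "parse_pattern",
    "render_pattern",
    "length_range",
    "find_matches",
    "brute_force_matches",
    "expand_class",
    "widen_gap",
    "sanitize_sequence",
]

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes tolerated in sequences.  They match only
#: wildcard elements, never fixed residues or classes — the conservative
#: choice that minimises false-positive hits.
AMBIGUOUS_AA = frozenset("XBZJUO")


class PatternParseError(ValueError):
    """Raised for malformed pattern text; carries the offending offset."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class PatternElement:
    """One unit of a motif pattern.

    ``kind`` is ``fixed``, ``class``, ``excluded_class`` or ``wildcard``.
    ``residues`` is empty for wildcards.  ``repeat_min``/``repeat_max``
    give the (inclusive) number of sequence positions the element spans.
    """

    kind: str
    residues: frozenset[str]
    repeat_min: int
    repeat_max: int

    def __post_init__(self) -> None:
        if self.kind not in {"fixed", "class", "excluded_class", "wildcard"}:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.repeat_min < 0 or self.repeat_max < self.repeat_min:
            raise ValueError(
                f"invalid repeat range ({self.repeat_min},{self.repeat_max})"
            )
        if self.kind == "wildcard":
            if self.residues:
                raise ValueError("wildcard elements carry no residues")
        else:
            if not self.residues:
                raise ValueError(f"{self.kind} element needs at least one residue")
            bad = set(self.residues) - STANDARD_AA
            if bad:
                raise ValueError(f"non-standard residues {sorted(bad)} in element")
            if self.kind == "fixed" and len(self.residues) != 1:
                raise ValueError("fixed element must hold exactly one residue")
            if self.kind == "fixed" and self.repeat_min != self.repeat_max:
                raise ValueError("fixed element repeat must be exact")
            if self.repeat_min < 1:
                raise ValueError("non-wildcard elements repeat at least once")

    def matches_residue(self, ch: str) -> bool:
        """Whether a single sequence character satisfies this element."""
        if self.kind == "wildcard":
            return True
        if ch not in STANDARD_AA:  # ambiguity codes never satisfy specific elements
            return False
        if self.kind == "excluded_class":
            return ch not in self.residues
        return ch in self.residues


@dataclass(frozen=True)
class MotifPattern:
    """A parsed search motif: ordered elements plus provenance text."""

    motif_id: str
    elements: tuple[PatternElement, ...]
    source_text: str = ""
    n_anchor: bool = False
    c_anchor: bool = False

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern must contain at least one element")

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True, order=True)
class MatchSpan:
    """One occurrence of a motif in a sequence (1-based, inclusive end)."""

    seq_id: str
    start: int
    end: int
    matched_text: str = field(compare=False)
    motif_id: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched_text):
            raise ValueError("span length disagrees with matched text")


# ---------------------------------------------------------------------------
# parsing / rendering


def _parse_repeat(text: str, i: int) -> tuple[int, int, int]:
    """Parse ``(N)`` or ``(N,M)`` starting at text[i] == '('."""
    j = text.find(")", i)
    if j < 0:
        raise PatternParseError(f"unterminated repeat {text[i:]!r}", i)
    body = text[i + 1 : j]
    parts = body.split(",")
    if len(parts) not in (1, 2) or not all(p.strip().isdigit() for p in parts):
        raise PatternParseError(f"malformed repeat ({body})", i)
    lo = int(parts[0])
    hi = int(parts[-1])
    if hi < lo:
        raise PatternParseError(f"repeat minimum {lo} exceeds maximum {hi}", i)
    return lo, hi, j + 1


def parse_pattern(text: str, motif_id: str = "custom") -> MotifPattern:
    """Parse a pattern string into a :class:`MotifPattern`.

    Whitespace and hyphen separators are ignored; letters are upper-cased;
    a trailing PROSITE period is tolerated.  Raises
    :class:`PatternParseError` for unbalanced brackets, empty classes,
    inverted repeat ranges or non-amino-acid letters, naming the offending
    token and its offset in the cleaned string.
    """
    if not text or not text.strip():
        raise PatternParseError("empty pattern", 0)
    clean = "".join(text.split()).upper().replace("-", "")
    if clean.endswith("."):
        clean = clean[:-1]
    n_anchor = clean.startswith("<")
    if n_anchor:
        clean = clean[1:]
    c_anchor = clean.endswith(">")
    if c_anchor:
        clean = clean[:-1]

    elements: list[PatternElement] = []
    i = 0
    while i < len(clean):
        ch = clean[i]
        if ch in "[{":
            closer = "]" if ch == "[" else "}"
            j = clean.find(closer, i)
            if j < 0:
                raise PatternParseError(f"unbalanced {ch!r}", i)
            body = clean[i + 1 : j]
            if not body:
                raise PatternParseError("empty residue class", i)
            bad = set(body) - STANDARD_AA
            if bad:
                raise PatternParseError(
                    f"non-amino-acid letters {sorted(bad)} in class {body!r}", i
                )
            lo, hi = 1, 1
            i = j + 1
            if i < len(clean) and clean[i] == "(":
                lo, hi, i = _parse_repeat(clean, i)
            kind = "class" if ch == "[" else "excluded_class"
            elements.append(PatternElement(kind, frozenset(body), lo, hi))
        elif ch == "X":
            lo, hi = 1, 1
            i += 1
            if i < len(clean) and clean[i] == "(":
                lo, hi, i = _parse_repeat(clean, i)
            elements.append(PatternElement("wildcard", frozenset(), lo, hi))
        elif ch in STANDARD_AA:
            lo, hi = 1, 1
            i += 1
            if i < len(clean) and clean[i] == "(":
                lo, hi, i = _parse_repeat(clean, i)
                if lo != hi:
                    raise PatternParseError(
                        f"fixed residue {ch!r} cannot take a ranged repeat", i
                    )
            elements.append(PatternElement("fixed", frozenset(ch), lo, hi))
        else:
            raise PatternParseError(f"unexpected character {ch!r}", i)
    if not elements:
        raise PatternParseError("pattern contains no elements", 0)
    return MotifPattern(
        motif_id=motif_id,
        elements=tuple(elements),
        source_text=text.strip(),
        n_anchor=n_anchor,
        c_anchor=c_anchor,
    )


def render_pattern(p: MotifPattern) -> str:
    """Render a pattern in the canonical compact dialect.

    Class residues are emitted alphabetically and degenerate ranges
    collapse (``x(3,3)`` → ``x(3)``), so rendering canonicalises;
    ``parse_pattern(render_pattern(p))`` reproduces ``p`` element-wise.
    """
    parts: list[str] = []
    if p.n_anchor:
        parts.append("<")
    for el in p.elements:
        if el.kind == "wildcard":
            core = "x"
        elif el.kind == "fixed":
            core = next(iter(el.residues))
        else:
            lo_b, hi_b = ("[", "]") if el.kind == "class" else ("{", "}")
            core = lo_b + "".join(sorted(el.residues)) + hi_b
        if (el.repeat_min, el.repeat_max) == (1, 1):
            parts.append(core)
        elif el.repeat_min == el.repeat_max:
            parts.append(f"{core}({el.repeat_min})")
        else:
            parts.append(f"{core}({el.repeat_min},{el.repeat_max})")
    if p.c_anchor:
        parts.append(">")
    return "".join(parts)


def length_range(p: MotifPattern) -> tuple[int, int]:
    """Minimum and maximum sequence length a pattern can span."""
    return (
        sum(el.repeat_min for el in p.elements),
        sum(el.repeat_max for el in p.elements),
    )


# ---------------------------------------------------------------------------
# sequence hygiene


def sanitize_sequence(seq: str, seq_id: str = "?") -> str:
    """Upper-case a sequence, truncate at ``*`` and drop ``-`` characters.

    A stop character terminates the usable sequence; alignment gaps are
    skipped.  Both events are logged as warnings, never errors.
    """
    s = seq.upper()
    if "*" in s:
        cut = s.index("*")
        logger.warning("sequence %s: '*' at position %d; truncating", seq_id, cut + 1)
        s = s[:cut]
    if "-" in s:
        logger.warning("sequence %s: gap characters '-' removed", seq_id)
        s = s.replace("-", "")
    bad = set(s) - STANDARD_AA - AMBIGUOUS_AA
    if bad:
        raise ValueError(f"sequence {seq_id}: invalid characters {sorted(bad)}")
    return s


# ---------------------------------------------------------------------------
# matching


def _element_run_ok(el: PatternElement, seq: str, pos: int, count: int) -> bool:
    return all(el.matches_residue(seq[pos + k]) for k in range(count))


def _end_sets(p: MotifPattern, seq: str) -> list[list[frozenset[int]]]:
    """Dynamic-programming table of reachable end offsets.

    ``table[ei][pos]`` is the set of 0-based offsets immediately *after*
    the last consumed residue when elements ``ei:`` are matched starting
    at ``pos``.  Shared across all start positions, which keeps matching
    polynomial for ranged wildcards.
    """
    n = len(seq)
    n_el = len(p.elements)
    table: list[list[frozenset[int]]] = [
        [frozenset()] * (n + 1) for _ in range(n_el + 1)
    ]
    table[n_el] = [frozenset({pos}) for pos in range(n + 1)]
    for ei in range(n_el - 1, -1, -1):
        el = p.elements[ei]
        for pos in range(n, -1, -1):
            ends: set[int] = set()
            hi = min(el.repeat_max, n - pos)
            if el.kind == "wildcard":
                for k in range(el.repeat_min, hi + 1):
                    ends |= table[ei + 1][pos + k]
            else:
                # per-residue predicate; a failure truncates longer runs
                ok = 0
                while ok < hi and el.matches_residue(seq[pos + ok]):
                    ok += 1
                for k in range(el.repeat_min, ok + 1):
                    ends |= table[ei + 1][pos + k]
            table[ei][pos] = frozenset(ends)
    return table


def find_matches(
    p: MotifPattern,
    seq: str,
    seq_id: str = "seq",
    mode: str = "all_spans",
) -> list[MatchSpan]:
    """All occurrences of a motif in a sequence.

    Returns every distinct ``(start, end)`` span in ascending order;
    overlapping matches, including several end positions per start caused
    by ranged wildcards, are all reported.  ``mode="shortest_per_start"``
    keeps only the shortest span at each start for compact reports.
    Output coordinates are 1-based, ends inclusive.
    """
    if mode not in {"all_spans", "shortest_per_start"}:
        raise ValueError(f"unknown mode {mode!r}")
    seq = seq.upper()
    if not seq:
        return []
    table = _end_sets(p, seq)
    spans: list[tuple[int, int]] = []
    starts = [0] if p.n_anchor else range(len(seq) + 1)
    for start in starts:
        ends = table[0][start]
        if p.c_anchor:
            ends = ends & {len(seq)}
        valid = sorted(e for e in ends if e > start)
        if not valid:
            continue
        if mode == "shortest_per_start":
            valid = valid[:1]
        spans.extend((start, e) for e in valid)
    spans.sort()
    return [
        MatchSpan(seq_id, s + 1, e, seq[s:e], p.motif_id) for s, e in spans
    ]


def brute_force_matches(
    p: MotifPattern, seq: str, seq_id: str = "seq"
) -> list[MatchSpan]:
    """Exhaustive reference matcher for short sequences.

    Recursively enumerates every assignment of elements to residue runs
    with no memoization or pruning beyond bounds; serves as the
    independent oracle that defines the matching contract.  Intended for
    sequences of at most a few dozen residues.
    """
    seq = seq.upper()
    n = len(seq)
    found: set[tuple[int, int]] = set()

    def walk(ei: int, pos: int, start: int) -> None:
        if ei == len(p.elements):
            if pos > start and not (p.c_anchor and pos != n):
                found.add((start, pos))
            return
        el = p.elements[ei]
        for count in range(el.repeat_min, el.repeat_max + 1):
            if pos + count > n:
                break
            if el.kind == "wildcard" or _element_run_ok(el, seq, pos, count):
                walk(ei + 1, pos + count, start)

    starts = [0] if p.n_anchor else range(n + 1)
    for start in starts:
        walk(0, start, start)
    return [
        MatchSpan(seq_id, s + 1, e, seq[s:e], p.motif_id)
        for s, e in sorted(found)
    ]


# ---------------------------------------------------------------------------
# relaxation


def expand_class(
    p: MotifPattern, element_index: int, extra_residues: Iterable[str]
) -> MotifPattern:
    """Enlarge one class (or promote a fixed residue to a class).

    Motif relaxation by adding residues of similar physicochemical
    character to a conserved position — e.g. ``[IL]`` widened to
    ``[VIL]``.  Returns a new pattern; the original is unchanged.  The
    match set of the result is a superset of the original's.
    """
    if not 0 <= element_index < len(p.elements):
        raise IndexError(f"element index {element_index} out of range")
    el = p.elements[element_index]
    if el.kind not in {"fixed", "class"}:
        raise ValueError(f"cannot expand a {el.kind} element")
    extra = frozenset(r.upper() for r in extra_residues)
    bad = extra - STANDARD_AA
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)}")
    merged = el.residues | extra
    if merged == el.residues:
        return p
    kind = "fixed" if len(merged) == 1 else "class"
    new_el = PatternElement(kind, merged, el.repeat_min, el.repeat_max)
    elements = p.elements[:element_index] + (new_el,) + p.elements[element_index + 1 :]
    return replace(p, elements=elements)


def widen_gap(
    p: MotifPattern, element_index: int, new_min: int, new_max: int
) -> MotifPattern:
    """Relax a wildcard's gap range.

    Only widening is permitted (``new_min <= old min``,
    ``new_max >= old max``); tightening must go through re-parsing so the
    superset-of-matches guarantee holds by construction.
    """
    if not 0 <= element_index < len(p.elements):
        raise IndexError(f"element index {element_index} out of range")
    el = p.elements[element_index]
    if el.kind != "wildcard":
        raise ValueError(f"element {element_index} is {el.kind}, not a wildcard")
    if new_min > el.repeat_min or new_max < el.repeat_max:
        raise ValueError(
            f"widen_gap cannot narrow ({el.repeat_min},{el.repeat_max}) "
            f"to ({new_min},{new_max})"
        )
    if new_min < 0:
        raise ValueError("gap minimum must be non-negative")
    new_el = PatternElement("wildcard", frozenset(), new_min, new_max)
    elements = p.elements[:element_index] + (new_el,) + p.elements[element_index + 1 :]
    return replace(p, elements=elements)
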