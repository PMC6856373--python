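"""Prosite-syntax pattern parsing and protein sequence scanning.

The Prosite pattern grammar supported here covers the elements used by the
NADH-diphosphatase detection pattern and by ScanProsite-style motifs in
general:

* fixed residues (``M``),
* residue classes (``[ILV]``),
* negated classes (``{P}``),
* the wildcard ``x``,
* repeat counts ``(n)`` and ranges ``(n,m)`` attached to any of the above,
* N/C-terminal anchors ``<`` and ``>``.

Two spellings are accepted and are fully equivalent: the canonical Prosite
dialect with ``-`` separators and an optional trailing period
(``G-x(5)-E.``) and the compact dialect with no separators (``Gx(5)E``).

Coordinates are 1-based inclusive throughout (Prosite/UniProt convention).

Ambiguity handling is deliberately conservative so that motif hits are never
asserted on uncertain residues: ``X`` satisfies only the wildcard element,
while ``B``/``Z``/``U``/``O`` satisfy only the wildcard — never a class,
a negated class or a fixed residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_AA = "XBZUO"
ALPHABET = frozenset(STANDARD_AA + AMBIGUITY_AA)

_STANDARD_SET = frozenset(STANDARD_AA)

ScanMode = Literal["greedy", "lazy", "all"]


class PatternSyntaxError(ValueError):
    """Raised when a pattern string cannot be parsed."""


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside the accepted alphabet."""


@dataclass(frozen=True)
class PatternElement:
    """One element of a Prosite pattern.

    kind is one of ``exact``, ``class``, ``negated``, ``wildcard``;
    ``residues`` is empty only for wildcards; repeats are inclusive bounds
    with ``1 <= min_repeat <= max_repeat``.
    """

    kind: str
    residues: frozenset
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self):
        if self.kind not in ("exact", "class", "negated", "wildcard"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "wildcard":
            if self.residues:
                raise ValueError("wildcard element must have an empty residue set")
        elif not self.residues:
            raise ValueError(f"{self.kind} element requires a non-empty residue set")
        if not self.residues <= _STANDARD_SET:
            bad = "".join(sorted(self.residues - _STANDARD_SET))
            raise ValueError(f"non-standard residues in element: {bad}")
        if not (1 <= self.min_repeat <= self.max_repeat):
            raise ValueError(
                f"invalid repeat range ({self.min_repeat},{self.max_repeat})"
            )

    def matches(self, ch: str) -> bool:
        if self.kind == "wildcard":
            return ch in ALPHABET
        if ch not in _STANDARD_SET:
            return False  # ambiguity codes never satisfy classes or fixed residues
        if self.kind == "negated":
            return ch not in self.residues
        return ch in self.residues


@dataclass(frozen=True)
class PrositePattern:
    """A parsed Prosite pattern: an ordered element list plus anchors."""

    elements: tuple
    source_text: str
    anchored_n: bool = False
    anchored_c: bool = False

    def __post_init__(self):
        if not self.elements:
            raise ValueError("pattern must contain at least one element")

    @property
    def min_span(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_repeat for e in self.elements)

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class MatchSpan:
    """A located motif occurrence (1-based inclusive coordinates)."""

    sequence_id: str
    start: int
    end: int
    matched_text: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError("require 1 <= start <= end")
        if len(self.matched_text) != self.end - self.start + 1:
            raise ValueError("matched_text length inconsistent with span")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with identifier and optional description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        validate_sequence(self.residues)


def validate_sequence(residues: str) -> None:
    if not residues:
        raise SequenceAlphabetError("empty sequence")
    bad = set(residues) - ALPHABET
    if bad:
        raise SequenceAlphabetError(
            "sequence contains characters outside the accepted alphabet: "
            + "".join(sorted(bad))
        )


# ---------------------------------------------------------------------------
# parsing

_TOKEN_RE = re.compile(
    r"""
    (?P<class>\[(?P<class_body>[A-Za-z]*)\])
  | (?P<negated>\{(?P<neg_body>[A-Za-z]*)\})
  | (?P<wild>[xX])
  | (?P<exact>[A-Wa-wYyZz])       # single residue letter (x handled above)
  | (?P<repeat>\((?P<rep_body>[^)]*)\))
  | (?P<sep>-)
  | (?P<anchor_n><)
  | (?P<anchor_c>>)
  | (?P<period>\.)
  | (?P<bad>.)
    """,
    re.VERBOSE,
)


def parse_pattern(text: str) -> PrositePattern:
    """Parse a Prosite pattern in either the dash-separated or compact dialect.

    Raises :class:`PatternSyntaxError` on unbalanced brackets, empty classes,
    inverted repeat ranges, repeats applied to anchors, or unknown characters.
    """
    if not text or not text.strip():
        raise PatternSyntaxError("empty pattern text")
    s = text.strip()
    if s.count("[") != s.count("]") or s.count("{") != s.count("}"):
        raise PatternSyntaxError(f"unbalanced brackets in {text!r}")
    if s.count("(") != s.count(")"):
        raise PatternSyntaxError(f"unbalanced parentheses in {text!r}")

    elements: list[PatternElement] = []
    anchored_n = anchored_c = False
    seen_period = False
    last_was_element = False  # a repeat may only follow an element

    for m in _TOKEN_RE.finditer(s):
        kind = m.lastgroup
        if seen_period and kind is not None:
            raise PatternSyntaxError("characters after terminating period")
        if kind == "sep":
            last_was_element = False
            continue
        if kind == "period":
            seen_period = True
            continue
        if kind == "anchor_n":
            if elements or anchored_n:
                raise PatternSyntaxError("'<' anchor must come first")
            anchored_n = True
            last_was_element = False
            continue
        if kind == "anchor_c":
            if anchored_c:
                raise PatternSyntaxError("duplicate '>' anchor")
            anchored_c = True
            last_was_element = False
            continue
        if kind == "repeat":
            if anchored_c or not last_was_element or not elements:
                raise PatternSyntaxError("repeat count must follow a pattern element")
            lo, hi = _parse_repeat(m.group("rep_body"))
            prev = elements[-1]
            if prev.min_repeat != 1 or prev.max_repeat != 1:
                raise PatternSyntaxError("element already carries a repeat count")
            elements[-1] = PatternElement(prev.kind, prev.residues, lo, hi)
            last_was_element = False
            continue
        if anchored_c:
            raise PatternSyntaxError("'>' anchor must come last")
        if kind == "class":
            body = m.group("class_body").upper()
            if not body:
                raise PatternSyntaxError("empty residue class []")
            elements.append(_make_class("class", body))
        elif kind == "negated":
            body = m.group("neg_body").upper()
            if not body:
                raise PatternSyntaxError("empty negated class {}")
            elements.append(_make_class("negated", body))
        elif kind == "wild":
            elements.append(PatternElement("wildcard", frozenset()))
        elif kind == "exact":
            ch = m.group("exact").upper()
            if ch not in _STANDARD_SET:
                raise PatternSyntaxError(f"unknown residue letter {ch!r}")
            elements.append(PatternElement("exact", frozenset(ch)))
        else:
            raise PatternSyntaxError(
                f"unknown character {m.group('bad')!r} in pattern {text!r}"
            )
        last_was_element = True

    if not elements:
        raise PatternSyntaxError(f"pattern {text!r} contains no elements")
    return PrositePattern(tuple(elements), text, anchored_n, anchored_c)


def _make_class(kind: str, body: str) -> PatternElement:
    residues = frozenset(body)
    if not residues <= _STANDARD_SET:
        bad = "".join(sorted(residues - _STANDARD_SET))
        raise PatternSyntaxError(f"unknown residue letter(s) {bad!r} in class")
    return PatternElement(kind, residues)


def _parse_repeat(body: str) -> tuple:
    parts = [p.strip() for p in body.split(",")]
    if not all(p.isdigit() for p in parts) or len(parts) not in (1, 2):
        raise PatternSyntaxError(f"malformed repeat count ({body})")
    lo = int(parts[0])
    hi = int(parts[-1])
    if lo < 1:
        raise PatternSyntaxError("repeat counts must be >= 1")
    if lo > hi:
        raise PatternSyntaxError(f"inverted repeat range ({body})")
    return lo, hi


def min_span(pattern: PrositePattern) -> int:
    """Shortest sequence length the pattern can match."""
    return pattern.min_span


def max_span(pattern: PrositePattern) -> int:
    """Longest sequence length the pattern can match."""
    return pattern.max_span


# ---------------------------------------------------------------------------
# scanning

def _reachable_ends(seq: str, elements, start: int) -> set:
    """All exclusive end offsets of matches of `elements` beginning at `start`.

    Forward dynamic program over the element list; each element extends every
    reachable position by any admissible repeat count over a contiguous run of
    matching residues.
    """
    positions = {start}
    n = len(seq)
    for el in elements:
        nxt: set = set()
        for p in positions:
            limit = min(el.max_repeat, n - p)
            run = 0
            while run < limit and el.matches(seq[p + run]):
                run += 1
            if run >= el.min_repeat:
                nxt.update(range(p + el.min_repeat, p + run + 1))
        if not nxt:
            return set()
        positions = nxt
    return positions


def scan(
    pattern: PrositePattern,
    sequence,
    mode: ScanMode = "greedy",
    sequence_id: str | None = None,
) -> list:
    """Find all occurrences of `pattern` in a protein sequence.

    mode:
        * ``greedy`` — per matching start position, the longest valid end
          (ScanProsite-style default);
        * ``lazy`` — the shortest valid end per start;
        * ``all`` — every distinct (start, end) pair.

    Returns :class:`MatchSpan` objects sorted by (start, end).
    """
    if mode not in ("greedy", "lazy", "all"):
        raise ValueError(f"unknown scan mode {mode!r}")
    if isinstance(sequence, SequenceRecord):
        seq = sequence.residues
        seq_id = sequence_id if sequence_id is not None else sequence.id
    else:
        seq = str(sequence).upper()
        validate_sequence(seq)
        seq_id = sequence_id if sequence_id is not None else ""

    n = len(seq)
    lo = pattern.min_span
    starts: Iterable[int]
    if pattern.anchored_n:
        starts = (0,)
    else:
        starts = range(0, max(n - lo + 1, 0))

    spans: list[MatchSpan] = []
    for s0 in starts:
        ends = _reachable_ends(seq, pattern.elements, s0)
        if pattern.anchored_c:
            ends = {e for e in ends if e == n}
        if not ends:
            continue
        if mode == "greedy":
            chosen = (max(ends),)
        elif mode == "lazy":
            chosen = (min(ends),)
        else:
            chosen = tuple(sorted(ends))
        for e in chosen:
            spans.append(MatchSpan(seq_id, s0 + 1, e, seq[s0:e]))
    spans.sort(key=lambda sp: (sp.start, sp.end))
    return spans


def match_trace(pattern: PrositePattern, sequence, start: int, end: int) -> list:
    """1-based start position of each pattern element within a known match.

    The assignment is made greedily from the left (each element takes the
    largest repeat count that still allows the remaining elements to reach
    `end`), which makes the trace deterministic.

    `start`/`end` are 1-based inclusive coordinates of an existing match, as
    returned by :func:`scan`; raises ValueError if no assignment reaches `end`.
    """
    seq = sequence.residues if isinstance(sequence, SequenceRecord) else str(sequence).upper()
    elements = pattern.elements
    target = end  # exclusive offset == inclusive 1-based end
    k = len(elements)

    # reachable[i] = set of offsets from which elements[i:] can reach target
    reachable: list[set] = [set() for _ in range(k + 1)]
    reachable[k] = {target}
    for i in range(k - 1, -1, -1):
        el = elements[i]
        # forward from every candidate offset; candidates bounded by span sums
        lo_rest = sum(e.min_repeat for e in elements[i:])
        hi_rest = sum(e.max_repeat for e in elements[i:])
        for p in range(max(start - 1, target - hi_rest), target - lo_rest + 1):
            limit = min(el.max_repeat, target - p)
            run = 0
            while run < limit and el.matches(seq[p + run]):
                run += 1
            if any(p + r in reachable[i + 1] for r in range(el.min_repeat, run + 1)):
                reachable[i].add(p)
    if (start - 1) not in reachable[0]:
        raise ValueError(f"no match of pattern at span ({start}, {end})")

    trace = []
    p = start - 1
    for i, el in enumerate(elements):
        trace.append(p + 1)
        limit = min(el.max_repeat, target - p)
        run = 0
        while run < limit and el.matches(seq[p + run]):
            run += 1
        for r in range(run, el.min_repeat - 1, -1):  # greedy from the left
            if p + r in reachable[i + 1]:
                p = p + r
                break
        else:  # pragma: no cover - guarded by reachability above
            raise ValueError("trace construction failed")
    return trace


# ---------------------------------------------------------------------------
# regex translation

def to_regex_text(pattern: PrositePattern, lazy: bool = False) -> str:
    """Translate a pattern to Python regex source.

    Wildcards become the explicit accepted-alphabet class (so that the regex
    reproduces the scanner's conservative ambiguity policy); negated classes
    become the explicit complement within the 20 standard residues; repeats
    become bounded quantifiers (greedy by default, lazy with ``lazy=True``).
    """
    parts = []
    if pattern.anchored_n:
        parts.append("^")
    for el in pattern.elements:
        if el.kind == "wildcard":
            atom = "[" + STANDARD_AA + AMBIGUITY_AA + "]"
        elif el.kind == "exact":
            atom = next(iter(el.residues))
        elif el.kind == "class":
            atom = "[" + "".join(sorted(el.residues)) + "]"
        else:  # negated: explicit complement, standard residues only
            atom = "[" + "".join(sorted(_STANDARD_SET - el.residues)) + "]"
        if (el.min_repeat, el.max_repeat) == (1, 1):
            quant = ""
        elif el.min_repeat == el.max_repeat:
            quant = "{%d}" % el.min_repeat
        else:
            quant = "{%d,%d}" % (el.min_repeat, el.max_repeat)
            if lazy:
                quant += "?"
        parts.append(atom + quant)
    if pattern.anchored_c:
        parts.append("$")
    return "".join(parts)


# ---------------------------------------------------------------------------
# FASTA and TSV plumbing

def read_fasta(path) -> list:
    """Read a FASTA file into SequenceRecords (wrapped or unwrapped lines)."""
    records = [
        SequenceRecord(rec.id, str(rec.seq), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def matches_to_rows(spans: Iterable[MatchSpan], pattern_id: str) -> Iterator[dict]:
    for sp in spans:
        yield {
            "sequence_id": sp.sequence_id,
            "pattern_id": pattern_id,
            "start": sp.start,
            "end": sp.end,
            "matched_seq": sp.matched_text,
        }
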