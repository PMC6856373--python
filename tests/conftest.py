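"""Shared fixtures and the independent regex-translation scan oracle.

The oracle deliberately re-tokenizes pattern text itself (it never calls the
package's parser) and enumerates every (start, end) span by brute force,
testing each candidate substring with ``re.fullmatch``.  It is the ground
truth the native scanner is compared against.
"""

from __future__ import annotations

import re

import numpy as np
import pytest

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUITY_AA = "XBZUO"

_TOKEN = re.compile(r"\[([A-Z]+)\]|\{([A-Z]+)\}|([A-Z])|\((\d+)(?:,(\d+))?\)|-|\.")


def oracle_tokens(pattern_text: str):
    """(atom-regex, lo, hi) triples tokenized independently of the package."""
    out = []
    pos = 0
    text = pattern_text.strip()
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise ValueError(f"oracle cannot tokenize at {text[pos:]!r}")
        pos = m.end()
        cls, neg, letter, lo, hi = m.groups()
        if cls is not None:
            atom = "[" + cls + "]"
        elif neg is not None:
            atom = "[" + "".join(sorted(set(STANDARD_AA) - set(neg))) + "]"
        elif letter is not None:
            if letter == "X":
                atom = "[" + STANDARD_AA + AMBIGUITY_AA + "]"
            else:
                atom = letter
        elif lo is not None:
            a, l, h = out.pop()
            out.append((a, int(lo), int(hi) if hi else int(lo)))
            continue
        else:
            continue  # separator / period
        out.append((atom, 1, 1))
    return out


def oracle_spans(pattern_text: str, sequence: str):
    """Every (start, end) span (1-based inclusive) matched by the pattern."""
    toks = oracle_tokens(pattern_text.replace("x", "X"))
    lo = sum(t[1] for t in toks)
    hi = sum(t[2] for t in toks)
    rx = re.compile(
        "".join(
            a + ("" if (l, h) == (1, 1) else "{%d,%d}" % (l, h)) for a, l, h in toks
        )
    )
    n = len(sequence)
    spans = []
    for s in range(n):
        for e in range(s + lo, min(s + hi, n) + 1):
            if rx.fullmatch(sequence, s, e):
                spans.append((s + 1, e))
    return spans


def random_small_pattern(rng: np.random.Generator) -> str:
    """A random, valid small pattern in the compact dialect."""
    n_elems = int(rng.integers(2, 6))
    parts = []
    for _ in range(n_elems):
        kind = rng.choice(["exact", "class", "negated", "wild"], p=[0.35, 0.25, 0.1, 0.3])
        if kind == "exact":
            parts.append(str(rng.choice(list(STANDARD_AA))))
        elif kind == "class":
            k = int(rng.integers(2, 5))
            parts.append("[" + "".join(rng.choice(list(STANDARD_AA), k, replace=False)) + "]")
        elif kind == "negated":
            k = int(rng.integers(1, 4))
            parts.append("{" + "".join(rng.choice(list(STANDARD_AA), k, replace=False)) + "}")
        else:
            parts.append("x")
        if rng.random() < 0.45:
            a = int(rng.integers(1, 4))
            b = a + int(rng.integers(0, 4))
            parts.append(f"({a},{b})" if b > a else f"({a})")
    return "".join(parts)


@pytest.fixture(scope="session")
def minimal_nadd_instance() -> str:
    """The shortest all-Ala-filled realization of the NADD pattern (99 aa)."""
    return (
        "C" + "AA" + "C" + "A" * 12 + "C" + "A" * 5 + "Y" + "P" + "AAA" + "P"
        + "AA" + "I" + "A" * 25 + "G" + "F" + "A" * 4 + "E" + "A" * 7 + "R"
        + "E" + "AA" + "E" + "E" + "A" * 13 + "Q" + "P" + "W" + "P" + "A"
        + "P" + "AA" + "Q" + "M"
    )


@pytest.fixture(scope="session")
def nudix_box_23mer() -> str:
    """A 23-mer satisfying the Nudix-box motif, Ala fillers."""
    return "G" + "A" * 5 + "E" + "A" * 7 + "RE" + "I" + "A" + "EE" + "A" + "G" + "V"
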