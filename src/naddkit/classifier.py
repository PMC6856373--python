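"""NADH-diphosphatase (NADD) motif catalog and sequence classification.

NADDs are the Nudix-hydrolase subfamily hydrolysing NAD(H) into NMN(H) and
AMP.  Detection rests on a single Prosite-compatible pattern spanning the
zinc-binding domain (three of the four Zn-coordinating Cys positions), the
Nudix box and the core of the NADD signature.  A sequence is called NADD iff
the pattern matches at least once; feature sub-spans (zinc positions, Nudix
box, signature core) are annotated for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import pandas as pd

from . import motif
from ._util import round_half_away
from .motif import MatchSpan, PrositePattern, SequenceRecord

# The NADD detection pattern: zinc domain ([CS]x(2)[CD]x(12,15)[CN]...),
# Nudix box (GFx(4)Ex(7)REx(2)EE) and signature core (Q[PQ]W[PA]xP).
NADD_PATTERN_TEXT = (
    "[CS]x(2)[CD]x(12,15)[CN]x(5,35)[YF]Px(3)Px(2)Ix(25,32)"
    "GFx(4)Ex(7)REx(2)EEx(13,14)Q[PQ]W[PA]xPx(2,9)[QLIMA]M"
)

# Generic Nudix-box motif GX5EX7REUXEEXGU with U = bulky hydrophobe (I/L/V).
NUDIX_BOX_TEXT = "G-x(5)-E-x(7)-R-E-[ILV]-x-E-E-x-G-[ILV]"

# Classical eight-residue NADD signature and the core form used in the
# detection pattern.
NADD_SIGNATURE_FULL_TEXT = "S-Q-P-W-P-F-P-x-S"
NADD_SIGNATURE_CORE_TEXT = "Q-[PQ]-W-[PA]-x-P"

# Element indices (0-based) of the three zinc-coordinating positions in the
# NADD pattern: [CS], [CD] and [CN].  The fourth Zn-coordinating cysteine is
# not a pattern element and is deliberately not reported.
ZINC_ELEMENT_INDICES = (0, 2, 4)


@dataclass(frozen=True)
class MotifCatalog:
    nadd_pattern: PrositePattern
    nudix_box: PrositePattern
    nadd_signature_full: PrositePattern
    nadd_signature_core: PrositePattern


@lru_cache(maxsize=1)
def motif_catalog() -> MotifCatalog:
    """The parsed motif constants (parsed once, cached)."""
    return MotifCatalog(
        nadd_pattern=motif.parse_pattern(NADD_PATTERN_TEXT),
        nudix_box=motif.parse_pattern(NUDIX_BOX_TEXT),
        nadd_signature_full=motif.parse_pattern(NADD_SIGNATURE_FULL_TEXT),
        nadd_signature_core=motif.parse_pattern(NADD_SIGNATURE_CORE_TEXT),
    )


NAMED_PATTERNS = {
    "nadd": NADD_PATTERN_TEXT,
    "nudix_box": NUDIX_BOX_TEXT,
    "nadd_signature_full": NADD_SIGNATURE_FULL_TEXT,
    "nadd_signature_core": NADD_SIGNATURE_CORE_TEXT,
}


@dataclass(frozen=True)
class NaddAnnotation:
    """Classification verdict and feature sub-spans for one sequence."""

    sequence_id: str
    is_nadd: bool
    nadd_span: Optional[MatchSpan]
    zinc_positions: Optional[tuple]
    nudix_box_span: Optional[MatchSpan]
    signature_core_span: Optional[MatchSpan]


def classify(sequence: SequenceRecord) -> NaddAnnotation:
    """Classify one sequence; NADD iff the detection pattern matches.

    When positive, ``nadd_span`` is the first greedy match and
    ``zinc_positions`` are the 1-based positions matched by the [CS], [CD]
    and [CN] elements of that match.  The Nudix box and signature core are
    located independently anywhere in the sequence.
    """
    cat = motif_catalog()
    nadd_hits = motif.scan(cat.nadd_pattern, sequence, mode="greedy")
    if nadd_hits:
        span = nadd_hits[0]
        trace = motif.match_trace(cat.nadd_pattern, sequence, span.start, span.end)
        zinc = tuple(trace[i] for i in ZINC_ELEMENT_INDICES)
    else:
        span = None
        zinc = None
    box_hits = motif.scan(cat.nudix_box, sequence, mode="greedy")
    core_hits = motif.scan(cat.nadd_signature_core, sequence, mode="greedy")
    return NaddAnnotation(
        sequence_id=sequence.id,
        is_nadd=span is not None,
        nadd_span=span,
        zinc_positions=zinc,
        nudix_box_span=box_hits[0] if box_hits else None,
        signature_core_span=core_hits[0] if core_hits else None,
    )


def annotation_row(ann: NaddAnnotation) -> dict:
    return {
        "sequence_id": ann.sequence_id,
        "is_nadd": ann.is_nadd,
        "nadd_start": ann.nadd_span.start if ann.nadd_span else pd.NA,
        "nadd_end": ann.nadd_span.end if ann.nadd_span else pd.NA,
        "zinc_pos1": ann.zinc_positions[0] if ann.zinc_positions else pd.NA,
        "zinc_pos2": ann.zinc_positions[1] if ann.zinc_positions else pd.NA,
        "zinc_pos3": ann.zinc_positions[2] if ann.zinc_positions else pd.NA,
        "nudix_box_start": ann.nudix_box_span.start if ann.nudix_box_span else pd.NA,
        "signature_start": (
            ann.signature_core_span.start if ann.signature_core_span else pd.NA
        ),
    }


def batch_classify(fasta_path) -> tuple:
    """Classify every record of a FASTA file.

    Returns ``(table, summary)`` where `table` is a DataFrame with one row
    per sequence and `summary` has keys ``n_total``, ``n_matched`` and
    ``percent`` (the matched rate, one decimal).
    """
    records = motif.read_fasta(fasta_path)
    rows = [annotation_row(classify(rec)) for rec in records]
    table = pd.DataFrame(rows)
    n_total = len(table)
    n_matched = int(table["is_nadd"].sum())
    summary = {
        "n_total": n_total,
        "n_matched": n_matched,
        "percent": summarize_rate(n_matched, n_total),
    }
    return table, summary


def summarize_rate(n_matched: int, n_total: int) -> float:
    """Matched percentage, one decimal, half away from zero."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_matched <= n_total:
        raise ValueError("require 0 <= n_matched <= n_total")
    return round_half_away(100.0 * n_matched / n_total, 1)
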