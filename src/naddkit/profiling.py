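"""Distribution summaries: taxonomy rollups and domain-architecture tables.

Two reporting surfaces common in protein-family surveys:

* **domain architectures** — a protein's ordered Pfam-style domain names
  joined with ``_`` (e.g. ``NUDIX-like_zf-NADH-PPase_NUDIX``, the canonical
  NADD architecture), tabulated as counts and percentages;
* **taxonomy rollups** — counts of classified-positive sequences per
  taxonomic rank, with percentages of both the parent level and the total.

Percentages are rounded half away from zero, one decimal, except that values
below 0.1% in magnitude keep two decimals (so tiny shares such as 0.07%
survive rounding).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import round_half_away

UNASSIGNED = "unassigned"

# Overlap resolution for domain hits (the field's usual greedy scheme):
# overlapping means shared length > this fraction of the shorter hit.
OVERLAP_FRACTION = 0.30


@dataclass(frozen=True)
class DomainHit:
    """One Pfam-style domain hit on a protein (1-based inclusive)."""

    sequence_id: str
    domain_name: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("domain hit requires start <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def round_percent(x: float) -> float:
    """One decimal, except two decimals below 0.1% (keeps e.g. 0.07 printable)."""
    return round_half_away(x, 2 if abs(x) < 0.1 else 1)


# ---------------------------------------------------------------------------
# domain architectures

def _overlap(a: DomainHit, b: DomainHit) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


def resolve_overlaps(hits: Sequence[DomainHit]) -> list:
    """Greedy overlap resolution.

    Priority: higher score first; ties broken by longer hit, then smaller
    start.  A candidate is dropped when it overlaps an already-kept hit by
    more than ``OVERLAP_FRACTION`` of the shorter hit's length.
    """
    ranked = sorted(
        hits,
        key=lambda h: (-(h.score if h.score is not None else 0.0), -h.length, h.start),
    )
    kept: list = []
    for cand in ranked:
        clash = False
        for k in kept:
            ov = _overlap(cand, k)
            if ov > 0 and ov > OVERLAP_FRACTION * min(cand.length, k.length):
                clash = True
                break
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


def architecture_of(hits: Sequence[DomainHit]) -> str:
    """Architecture string of one sequence: retained hits by ascending start."""
    if not hits:
        raise ValueError("cannot derive an architecture from zero domain hits")
    return "_".join(h.domain_name for h in resolve_overlaps(hits))


def architectures_from_hits(hits_table: pd.DataFrame) -> pd.Series:
    """Per-sequence architecture strings from a tidy domain-hit table."""
    required = {"sequence_id", "domain_name", "start", "end"}
    missing = required - set(hits_table.columns)
    if missing:
        raise ValueError(f"domain-hit table missing columns: {sorted(missing)}")
    out = {}
    for seq_id, grp in hits_table.groupby("sequence_id", sort=True):
        hits = [
            DomainHit(
                str(r.sequence_id),
                str(r.domain_name),
                int(r.start),
                int(r.end),
                float(r.score) if "score" in grp.columns and pd.notna(r.score) else None,
            )
            for r in grp.itertuples()
        ]
        out[seq_id] = architecture_of(hits)
    return pd.Series(out, name="architecture")


def tabulate_architectures(architectures: Iterable[str]) -> pd.DataFrame:
    """Counts and percentages per architecture, descending by count.

    Ties in count are ordered by name so the table is deterministic.
    """
    archs = list(architectures)
    if not archs:
        raise ValueError("empty architecture list")
    counts = pd.Series(archs).value_counts()
    df = counts.rename_axis("architecture").reset_index(name="count")
    df = df.sort_values(["count", "architecture"], ascending=[False, True])
    total = df["count"].sum()
    df["percent"] = [round_percent(100.0 * c / total) for c in df["count"]]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# taxonomy rollups

def read_lineages(path, ranks: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a lineage TSV in either dialect.

    Dialect A: ``sequence_id`` plus one column per rank.
    Dialect B: ``sequence_id`` plus a single ``lineage`` column of
    semicolon-delimited names, interpreted against `ranks` (required then).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "sequence_id" not in df.columns:
        raise ValueError("lineage table requires a 'sequence_id' column")
    if "lineage" in df.columns and len(df.columns) == 2:
        if not ranks:
            raise ValueError("semicolon-dialect lineage table requires explicit ranks")
        parts = df["lineage"].str.split(";", expand=True)
        parts.columns = list(ranks)[: parts.shape[1]]
        parts = parts.apply(lambda c: c.str.strip())
        df = pd.concat([df[["sequence_id"]], parts], axis=1)
    return df


def taxonomy_rollup(
    classification: pd.DataFrame,
    lineages: pd.DataFrame,
    ranks: Sequence[str],
) -> pd.DataFrame:
    """Roll classified-positive sequences up a rank hierarchy.

    `classification` needs columns ``sequence_id`` and ``is_nadd``;
    `lineages` needs ``sequence_id`` plus the requested rank columns.
    Sequences without a lineage (or with an empty name at some rank) are
    counted under ``unassigned``.

    Returns a tidy frame with one row per (rank, taxon): columns ``rank``,
    ``taxon``, ``parent``, ``count``, ``percent_of_parent`` and
    ``percent_of_total``; within a rank, rows are ordered by descending
    count then name.
    """
    if classification.empty:
        raise ValueError("empty classification table")
    for col in ("sequence_id", "is_nadd"):
        if col not in classification.columns:
            raise ValueError(f"classification table missing column {col!r}")
    positives = classification.loc[classification["is_nadd"].astype(bool), ["sequence_id"]]
    merged = positives.merge(lineages, on="sequence_id", how="left")
    total = len(merged)
    if total == 0:
        raise ValueError("no classified-positive sequences to roll up")

    for rank in ranks:
        if rank not in merged.columns:
            merged[rank] = pd.NA
    named = merged[list(ranks)].fillna(UNASSIGNED).replace("", UNASSIGNED)

    rows = []
    for depth, rank in enumerate(ranks):
        if depth == 0:
            groups = named.groupby(rank).size()
            parent_sizes = {None: total}
            parents = {taxon: None for taxon in groups.index}
        else:
            parent_rank = ranks[depth - 1]
            groups = named.groupby([parent_rank, rank]).size()
            parent_sizes = named.groupby(parent_rank).size().to_dict()
            parents = {}
        if depth == 0:
            items = [((None, taxon), n) for taxon, n in groups.items()]
        else:
            items = list(groups.items())
        for (parent, taxon), n in items:
            parent_n = parent_sizes[parent]
            rows.append(
                {
                    "rank": rank,
                    "taxon": taxon,
                    "parent": parent if parent is not None else "",
                    "count": int(n),
                    "percent_of_parent": round_percent(100.0 * n / parent_n),
                    "percent_of_total": round_percent(100.0 * n / total),
                }
            )
    df = pd.DataFrame(rows)
    rank_order = {r: i for i, r in enumerate(ranks)}
    df = df.sort_values(
        by=["rank", "count", "taxon"],
        ascending=[True, False, True],
        key=lambda col: col.map(rank_order) if col.name == "rank" else col,
    )
    return df.reset_index(drop=True)


def read_domain_hits(path) -> pd.DataFrame:
    """Read a domain-hit TSV (header required)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sequence_id", "domain_name", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain-hit table missing columns: {sorted(missing)}")
    return df
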