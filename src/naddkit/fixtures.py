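"""Seeded synthetic-data generators.

Every generator is deterministic under a fixed seed and self-checking where
a guarantee is claimed (pattern positives are re-scanned before being
returned, negatives are verified not to match).  The generators emulate the
statistical structure each analysis needs — motif instances in random
flanks, covarying column pairs, clade-structured alignments, noisy
saturation kinetics — not realistic protein evolution (no indels, no rate
heterogeneity, no phylogenetic correlation beyond the two-clade split).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import motif
from .coevolution import Alignment, BLOSUM62_BACKGROUND
from .kinetics import KineticDataset
from .motif import PrositePattern, SequenceRecord, STANDARD_AA

_AA = np.array(list(STANDARD_AA))


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_residues(rng, n: int, background: Optional[np.ndarray] = None) -> str:
    p = background if background is not None else None
    return "".join(rng.choice(_AA, size=n, p=p))


def realize_pattern(
    pattern: PrositePattern,
    rng: np.random.Generator,
    minimal: bool = False,
) -> str:
    """One conforming instance: uniform choices within classes and repeats."""
    out = []
    std = set(STANDARD_AA)
    for el in pattern.elements:
        reps = el.min_repeat if minimal else int(
            rng.integers(el.min_repeat, el.max_repeat + 1)
        )
        if el.kind == "exact":
            pool = sorted(el.residues)
        elif el.kind == "class":
            pool = sorted(el.residues)
        elif el.kind == "negated":
            pool = sorted(std - el.residues)
        else:
            pool = sorted(std)
        out.append("".join(rng.choice(pool) for _ in range(reps)))
    return "".join(out)


def make_pattern_positive(
    pattern: PrositePattern,
    flank_length: int = 30,
    seed: int = 0,
    minimal: bool = False,
    seq_id: str = "positive",
    background: Optional[np.ndarray] = None,
) -> SequenceRecord:
    """A guaranteed pattern match embedded in random flanks (self-checked)."""
    rng = _rng(seed)
    core = realize_pattern(pattern, rng, minimal=minimal)
    left = _random_residues(rng, flank_length, background)
    right = _random_residues(rng, flank_length, background)
    rec = SequenceRecord(seq_id, left + core + right)
    assert motif.scan(pattern, rec), "generator self-check failed: no match"
    return rec


def make_pattern_negative(
    pattern: PrositePattern,
    seed: int = 0,
    seq_id: str = "negative",
    max_tries: int = 100,
) -> SequenceRecord:
    """A near-miss: one fixed element of a positive mutated out of its class.

    Candidate elements are those with repeat (1,1) and kind exact/class.
    The mutation is verified internally to destroy every match; rare cases
    where an alternative match survives are retried with a fresh draw.
    """
    std = set(STANDARD_AA)
    fixed_idx = [
        i
        for i, el in enumerate(pattern.elements)
        if el.kind in ("exact", "class") and (el.min_repeat, el.max_repeat) == (1, 1)
    ]
    if not fixed_idx:
        raise ValueError("pattern has no fixed (1,1) class/exact element to mutate")
    rng = _rng(seed)
    for _ in range(max_tries):
        core = realize_pattern(pattern, rng, minimal=True)
        trace = motif.match_trace(pattern, core, 1, len(core))
        i = int(rng.choice(fixed_idx))
        el = pattern.elements[i]
        pos = trace[i] - 1
        outside = sorted(std - el.residues)
        mutated = core[:pos] + str(rng.choice(outside)) + core[pos + 1 :]
        if not motif.scan(pattern, mutated, sequence_id=seq_id):
            return SequenceRecord(seq_id, mutated)
    raise RuntimeError("could not construct a verified negative")


def make_classification_set(
    pattern: PrositePattern,
    n_positive: int,
    n_negative: int,
    seed: int = 0,
    flank_length: int = 20,
) -> list:
    """A labelled FASTA-ready set: `pos<i>` records match, `neg<i>` do not."""
    rng = _rng(seed)
    records = []
    for i in range(n_positive):
        records.append(
            make_pattern_positive(
                pattern, flank_length, seed=int(rng.integers(2**31)),
                seq_id=f"pos{i + 1}",
            )
        )
    for i in range(n_negative):
        records.append(
            make_pattern_negative(
                pattern, seed=int(rng.integers(2**31)), seq_id=f"neg{i + 1}"
            )
        )
    return records


def make_covarying_msa(
    n_seqs: int = 64,
    n_cols: int = 30,
    planted_pairs: Sequence[tuple] = ((0, 1),),
    seed: int = 0,
    n_invariant: int = 0,
) -> Alignment:
    """An MSA with planted covarying column pairs in i.i.d. noise.

    Each planted pair follows a two-state paired alphabet: every sequence
    draws one of two states, state 0 writing e.g. (A, V) into the pair and
    state 1 e.g. (S, T), so the columns are perfectly correlated while each
    marginal is two-valued.  Remaining columns are i.i.d. uniform over the
    20 residues; optionally the first `n_invariant` free columns are made
    invariant.
    """
    rng = _rng(seed)
    planted_cols = {c for pair in planted_pairs for c in pair}
    if len(planted_cols) != 2 * len(planted_pairs):
        raise ValueError("planted pairs must not share columns")
    if any(c >= n_cols for c in planted_cols):
        raise ValueError("planted column outside the alignment")
    cols = np.empty((n_seqs, n_cols), dtype="<U1")
    free = [c for c in range(n_cols) if c not in planted_cols]
    for k, c in enumerate(free):
        if k < n_invariant:
            cols[:, c] = rng.choice(_AA)
        else:
            cols[:, c] = rng.choice(_AA, size=n_seqs)
    for (ci, cj) in planted_pairs:
        a1, b1, a2, b2 = rng.choice(_AA, size=4, replace=False)
        states = rng.integers(0, 2, size=n_seqs)
        cols[:, ci] = np.where(states == 0, a1, a2)
        cols[:, cj] = np.where(states == 0, b1, b2)
    rows = ["".join(cols[i]) for i in range(n_seqs)]
    return Alignment([f"seq{i + 1}" for i in range(n_seqs)], rows)


def make_clade_msa(
    n_per_clade: int = 5,
    n_cols: int = 200,
    within_id: float = 0.95,
    between_id: float = 0.60,
    seed: int = 0,
) -> Alignment:
    """A two-clade alignment for tree-building tests.

    Two clade ancestors differ at a fraction (1 - between_id) of columns;
    each taxon then mutates away from its ancestor at rate
    (1 - within_id)/2, targeting pairwise within-clade identity around
    `within_id` and between-clade identity at or below `between_id`.
    Taxa are named A1..An and B1..Bn.
    """
    rng = _rng(seed)
    anc_a = rng.choice(_AA, size=n_cols)
    anc_b = anc_a.copy()
    diff = rng.random(n_cols) < (1.0 - between_id)
    for c in np.nonzero(diff)[0]:
        choices = [a for a in _AA if a != anc_a[c]]
        anc_b[c] = rng.choice(choices)

    mut_rate = (1.0 - within_id) / 2.0
    ids, rows = [], []
    for clade, anc in (("A", anc_a), ("B", anc_b)):
        for i in range(n_per_clade):
            seq = anc.copy()
            hits = np.nonzero(rng.random(n_cols) < mut_rate)[0]
            for c in hits:
                choices = [a for a in _AA if a != anc[c]]
                seq[c] = rng.choice(choices)
            ids.append(f"{clade}{i + 1}")
            rows.append("".join(seq))
    return Alignment(ids, rows)


def mm_design_grid(km_mM: float) -> list:
    """A 7-level substrate grid designed for precise KM estimation.

    Optimal-design theory for saturation kinetics with relative error puts
    the information about KM in points well below KM and the information
    about Vmax at saturation, so the grid concentrates four levels at
    0.1-0.5 x KM and three at 5-25 x KM.
    """
    return [round(f * km_mM, 6) for f in (0.1, 0.2, 0.3, 0.5, 5.0, 12.5, 25.0)]


def make_mm_data(
    km_mM: float,
    kcat: float,
    enzyme_uM: float,
    s_grid_mM: Sequence[float],
    cv: float = 0.05,
    n_rep: int = 3,
    seed: int = 0,
    substrate: str = "substrate",
) -> KineticDataset:
    """Noisy Michaelis–Menten initial rates on a substrate grid.

    Rates carry multiplicative Gaussian noise of coefficient of variation
    `cv` (clipped at zero); `cv=0` reproduces the curve exactly.
    """
    rng = _rng(seed)
    s = np.repeat(np.asarray(s_grid_mM, float), n_rep)
    vmax = kcat * enzyme_uM
    v_true = vmax * s / (km_mM + s)
    noise = rng.normal(1.0, cv, size=len(s)) if cv > 0 else np.ones(len(s))
    v = np.clip(v_true * noise, 0.0, None)
    reps = np.tile(np.arange(1, n_rep + 1), len(s_grid_mM))
    return KineticDataset(substrate, s, v, enzyme_uM, replicates=reps)


def make_profiling_tables(
    architecture_spec: dict,
    lineage_spec: Optional[dict] = None,
    seed: int = 0,
    domain_length: int = 80,
    gap: int = 10,
):
    """Domain-hit and lineage tables realising given distributions.

    `architecture_spec` maps architecture strings (domains joined by ``_``)
    to sequence counts; each sequence gets consecutive non-overlapping hits
    realising its architecture.  `lineage_spec` maps rank-name tuples to
    counts and is assigned to sequences in order (cycled if short).
    Returns ``(hits_table, lineage_table)`` DataFrames.
    """
    rng = _rng(seed)
    hit_rows = []
    lineage_assignments = []
    if lineage_spec:
        for names, count in lineage_spec.items():
            lineage_assignments.extend([names] * count)
    seq_no = 0
    lin_rows = []
    for arch, count in architecture_spec.items():
        domains = arch.split("_")
        for _ in range(count):
            seq_no += 1
            seq_id = f"seq{seq_no}"
            pos = 1
            for dom in domains:
                length = domain_length + int(rng.integers(0, 10))
                hit_rows.append(
                    {
                        "sequence_id": seq_id,
                        "domain_name": dom,
                        "start": pos,
                        "end": pos + length - 1,
                        "score": float(np.round(rng.uniform(20, 100), 1)),
                    }
                )
                pos += length + gap
            if lineage_assignments:
                names = lineage_assignments[(seq_no - 1) % len(lineage_assignments)]
                row = {"sequence_id": seq_id}
                for k, name in enumerate(names):
                    row[f"rank{k + 1}"] = name
                lin_rows.append(row)
    hits = pd.DataFrame(hit_rows)
    lineages = pd.DataFrame(lin_rows) if lin_rows else pd.DataFrame()
    return hits, lineages
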