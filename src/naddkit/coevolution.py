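"""MISTIC-style coevolution analysis of protein multiple sequence alignments.

Given an MSA, the analysis computes per-column conservation and a mutual
information (MI) network between columns:

* sequences are clustered at an identity threshold and weighted 1/cluster
  size, so redundant sequences do not dominate the statistics;
* per-column Kullback–Leibler (KL) conservation against a background
  amino-acid distribution (BLOSUM62 marginals by default);
* pairwise MI between columns, z-scored against a null built by
  independently permuting each column's residues;
* cumulative MI (cMI) per column: the sum of its above-threshold MI z-scores;
* proximity MI (pMI) per residue: the mean cMI of its spatial neighbours,
  when a contact/distance table is available;
* a tiered edge list (top 5% / 70–95% / last 70% of above-threshold edges),
  exportable for circos-style drawing.

All information quantities are in natural-log units (nats).  Gaps are never
counted as residues: a column's frequency vector is over the 20 standard
amino acids, and for pair statistics only sequences ungapped in both columns
contribute.  Ambiguity codes are treated as gaps for these statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .motif import STANDARD_AA, read_fasta

GAP = "-"
N_AA = 20
_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

# Defaults following the published MISTIC protocol; all configurable.
DEFAULT_CLUSTERING_IDENTITY = 0.62
DEFAULT_PSEUDOCOUNT = 0.05
DEFAULT_GAP_CUTOFF = 0.5
DEFAULT_N_SHUFFLES = 100
DEFAULT_MI_THRESHOLD = 6.5

# BLOSUM62 background (marginal) amino-acid frequencies, ACDE... order.
BLOSUM62_BACKGROUND = np.array(
    [
        0.074,  # A
        0.025,  # C
        0.054,  # D
        0.054,  # E
        0.047,  # F
        0.074,  # G
        0.026,  # H
        0.068,  # I
        0.058,  # K
        0.099,  # L
        0.025,  # M
        0.045,  # N
        0.039,  # P
        0.034,  # Q
        0.052,  # R
        0.057,  # S
        0.051,  # T
        0.073,  # V
        0.013,  # W
        0.032,  # Y
    ]
)
BLOSUM62_BACKGROUND = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()


@dataclass
class Alignment:
    """An MSA with optional reference sequence for residue numbering."""

    ids: list
    rows: list
    reference_id: Optional[str] = None

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: rows of unequal length")
        self.rows = [r.upper() for r in self.rows]
        if self.reference_id is not None and self.reference_id not in self.ids:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path, reference_id: Optional[str] = None) -> "Alignment":
        records = read_fasta(path)
        return cls([r.id for r in records], [r.residues for r in records], reference_id)

    def column_to_ref(self) -> np.ndarray:
        """Map alignment column (0-based) -> ungapped 1-based reference
        residue number, 0 where the reference is gapped.  Columns are
        numbered 1..n_cols when no reference is set."""
        if self.reference_id is None:
            return np.arange(1, self.n_cols + 1)
        row = self.rows[self.ids.index(self.reference_id)]
        out = np.zeros(self.n_cols, dtype=int)
        k = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                k += 1
                out[c] = k
        return out


def encode(alignment: Alignment) -> np.ndarray:
    """Integer-encode the MSA: 0..19 for standard residues, -1 for gaps
    and ambiguity codes."""
    arr = np.full((alignment.n_seqs, alignment.n_cols), -1, dtype=np.int8)
    for i, row in enumerate(alignment.rows):
        for j, ch in enumerate(row):
            arr[i, j] = _AA_INDEX.get(ch, -1)
    return arr


def _one_hot(enc: np.ndarray) -> np.ndarray:
    """(n_seqs, n_cols, 20) one-hot; gap rows are all-zero."""
    n, L = enc.shape
    oh = np.zeros((n, L, N_AA))
    valid = enc >= 0
    ii, jj = np.nonzero(valid)
    oh[ii, jj, enc[ii, jj]] = 1.0
    return oh


def sequence_weights(
    alignment: Alignment, clustering_identity: float = DEFAULT_CLUSTERING_IDENTITY
) -> np.ndarray:
    """1/cluster-size weights from single-linkage identity clustering.

    Identity between two rows = matches / columns where both are ungapped;
    rows with no comparable columns count as 0 identity.  Clusters are the
    connected components of the >=threshold graph.
    """
    enc = encode(alignment)
    n = alignment.n_seqs
    valid = enc >= 0
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        eq = (enc[i] == enc[i + 1 :]) & both
        denom = both.sum(axis=1)
        ident = np.divide(
            eq.sum(axis=1), denom, out=np.zeros(len(denom)), where=denom > 0
        )
        adj[i, i + 1 :] = ident >= clustering_identity
    adj |= adj.T
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return 1.0 / sizes[labels]


def weighted_frequencies(
    alignment: Alignment,
    clustering_identity: float = DEFAULT_CLUSTERING_IDENTITY,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gap_cutoff: float = DEFAULT_GAP_CUTOFF,
    weights: Optional[np.ndarray] = None,
):
    """Per-column weighted residue frequencies with a pseudocount.

    Each column's frequency vector gets ``pseudocount`` added per residue
    cell before normalisation (pair tables in :func:`mi_zscores` use
    ``pseudocount / 20`` per joint cell, which keeps the joint's marginals
    consistent with the single-column frequencies).

    Returns ``(freqs, flagged, weights)``: an (n_cols, 20) array, a boolean
    mask of columns whose weighted gap fraction exceeds `gap_cutoff`, and
    the sequence weights used.
    """
    if alignment.n_seqs < 2:
        raise ValueError("need at least two sequences")
    if weights is None:
        weights = sequence_weights(alignment, clustering_identity)
    enc = encode(alignment)
    oh = _one_hot(enc)
    counts = np.einsum("s,sca->ca", weights, oh)
    totals = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount) / (totals + N_AA * pseudocount)
    wsum = weights.sum()
    gap_fraction = 1.0 - totals[:, 0] / wsum
    flagged = gap_fraction > gap_cutoff
    return freqs, flagged, weights


def kl_conservation(
    freqs: np.ndarray,
    background: Optional[np.ndarray] = None,
    flagged: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-column KL divergence sum_a p_a ln(p_a / q_a) in nats.

    `freqs` rows are already gap-excluded and normalised over the 20
    residues.  Flagged (gappy) columns get NaN.
    """
    q = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)
    if q.shape != (N_AA,) or np.any(q <= 0):
        raise ValueError("background must be a strictly positive 20-vector")
    q = q / q.sum()
    p = np.asarray(freqs, float)
    if np.any(p.sum(axis=1) <= 0):
        raise ValueError("column with zero residue mass")
    p = p / p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / q), 0.0)
    kl = terms.sum(axis=1)
    if flagged is not None:
        kl = np.where(flagged, np.nan, kl)
    return kl


def _joint_counts(oh: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted joint residue counts for every column pair.

    Returns (L, L, 20, 20); only sequences ungapped in both columns
    contribute (gap one-hot rows are all-zero)."""
    n, L, _ = oh.shape
    flat = oh.reshape(n, L * N_AA)
    joint = (weights[:, None] * flat).T @ flat
    return joint.reshape(L, N_AA, L, N_AA).transpose(0, 2, 1, 3)


def _mi_from_joint(joint: np.ndarray, pseudocount: float) -> np.ndarray:
    """MI matrix (L, L) from joint counts; NaN where a pair has no mass."""
    j = joint + pseudocount / N_AA
    tot = j.sum(axis=(2, 3))
    ok = tot > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = j / tot[:, :, None, None]
        pa = p.sum(axis=3)
        pb = p.sum(axis=2)
        outer = pa[:, :, :, None] * pb[:, :, None, :]
        terms = np.where(p > 0, p * np.log(p / outer), 0.0)
    mi = terms.sum(axis=(2, 3))
    mi[~ok] = np.nan
    return mi


def mutual_information(
    alignment: Alignment,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    weights: Optional[np.ndarray] = None,
    clustering_identity: float = DEFAULT_CLUSTERING_IDENTITY,
) -> np.ndarray:
    """Raw weighted MI matrix between all column pairs, in nats.

    The diagonal is the MI of a column with itself; with ``pseudocount=0``
    this equals the column's Shannon entropy exactly (MI(X,X) = H(X)).
    """
    if weights is None:
        weights = sequence_weights(alignment, clustering_identity)
    oh = _one_hot(encode(alignment))
    return _mi_from_joint(_joint_counts(oh, weights), pseudocount)


def column_entropy(
    alignment: Alignment,
    weights: Optional[np.ndarray] = None,
    clustering_identity: float = DEFAULT_CLUSTERING_IDENTITY,
) -> np.ndarray:
    """Weighted Shannon entropy of each column (nats, gaps excluded)."""
    if weights is None:
        weights = sequence_weights(alignment, clustering_identity)
    oh = _one_hot(encode(alignment))
    counts = np.einsum("s,sca->ca", weights, oh)
    tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / tot
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return terms.sum(axis=1)


def mi_zscores(
    alignment: Alignment,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    clustering_identity: float = DEFAULT_CLUSTERING_IDENTITY,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gap_cutoff: float = DEFAULT_GAP_CUTOFF,
) -> np.ndarray:
    """Pairwise MI z-scores against a column-shuffle null.

    The null independently permutes each column's residues across sequences
    (`n_shuffles` times, seeded); z_ij = (MI_ij - null mean) / null sd.
    Columns flagged as too gappy, and the diagonal, are NaN.
    """
    if n_shuffles < 20:
        raise ValueError("n_shuffles must be >= 20")
    weights = sequence_weights(alignment, clustering_identity)
    _, flagged, _ = weighted_frequencies(
        alignment, clustering_identity, pseudocount, gap_cutoff, weights=weights
    )
    if (~flagged).sum() < 2:
        raise ValueError("fewer than two usable (non-gappy) columns")
    enc = encode(alignment)
    oh = _one_hot(enc)
    n, L, _ = oh.shape
    mi = _mi_from_joint(_joint_counts(oh, weights), pseudocount)

    rng = np.random.default_rng(seed)
    null_sum = np.zeros((L, L))
    null_sumsq = np.zeros((L, L))
    shuffled = np.empty_like(oh)
    for _ in range(n_shuffles):
        for c in range(L):
            shuffled[:, c, :] = oh[rng.permutation(n), c, :]
        m = _mi_from_joint(_joint_counts(shuffled, weights), pseudocount)
        null_sum += m
        null_sumsq += m * m
    mean = null_sum / n_shuffles
    var = null_sumsq / n_shuffles - mean * mean
    sd = np.sqrt(np.maximum(var, 0.0) * n_shuffles / max(n_shuffles - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 1e-12, (mi - mean) / sd, 0.0)
    z[np.eye(L, dtype=bool)] = np.nan
    z[flagged, :] = np.nan
    z[:, flagged] = np.nan
    return z


def cumulative_mi(
    z_matrix: np.ndarray, threshold: float = DEFAULT_MI_THRESHOLD
) -> np.ndarray:
    """cMI_i = sum over j of z_ij restricted to z_ij > threshold."""
    z = np.asarray(z_matrix, float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("z-matrix must be square")
    passing = np.where(np.nan_to_num(z, nan=-np.inf) > threshold, z, 0.0)
    np.fill_diagonal(passing, 0.0)
    return passing.sum(axis=1)


def proximity_mi(
    cmi: np.ndarray,
    contacts: pd.DataFrame,
    radius: Optional[float] = None,
    positions: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """pMI_i = mean cMI over residues in contact with i (excluding i).

    `contacts` needs columns ``res_i``/``res_j`` (1-based positions in the
    numbering of `positions`, default 1..len(cmi)) and optionally
    ``distance``; with `radius` set, only pairs with distance <= radius
    count as contacts.  Positions with no contacts get NaN.
    """
    cmi = np.asarray(cmi, float)
    pos = list(positions) if positions is not None else list(range(1, len(cmi) + 1))
    index = {p: k for k, p in enumerate(pos)}
    if not {"res_i", "res_j"} <= set(contacts.columns):
        raise ValueError("contact table requires res_i and res_j columns")
    df = contacts
    if radius is not None:
        if "distance" not in df.columns:
            raise ValueError("radius filtering requires a distance column")
        df = df[df["distance"] <= radius]
    neighbours: dict = {k: [] for k in range(len(cmi))}
    for r in df.itertuples():
        a, b = int(r.res_i), int(r.res_j)
        if a not in index or b not in index:
            raise ValueError(f"contact ({a},{b}) outside the reference numbering")
        if a == b:
            continue
        neighbours[index[a]].append(index[b])
        neighbours[index[b]].append(index[a])
    out = np.full(len(cmi), np.nan)
    for k, nbrs in neighbours.items():
        if nbrs:
            out[k] = float(np.mean(cmi[sorted(set(nbrs))]))
    return out


def tier_edges(
    z_matrix: np.ndarray, threshold: float = DEFAULT_MI_THRESHOLD
) -> pd.DataFrame:
    """Above-threshold edges ranked and tiered.

    Of the edges with z > threshold, the strongest 5% (by count,
    ceil(0.05 n)) are tier ``top5``, the next block up to the strongest 30%
    is ``mid`` (the 70th–95th percentile band) and the remaining 70% are
    ``low``.  Columns: col_i, col_j (0-based, i < j), z, tier.
    """
    z = np.asarray(z_matrix, float)
    iu, ju = np.triu_indices(z.shape[0], k=1)
    vals = z[iu, ju]
    keep = np.nan_to_num(vals, nan=-np.inf) > threshold
    edges = pd.DataFrame({"col_i": iu[keep], "col_j": ju[keep], "z": vals[keep]})
    if edges.empty:
        edges["tier"] = pd.Series(dtype=str)
        return edges
    edges = edges.sort_values(
        ["z", "col_i", "col_j"], ascending=[False, True, True]
    ).reset_index(drop=True)
    n = len(edges)
    n_top = int(np.ceil(0.05 * n))
    n_mid = max(int(np.ceil(0.30 * n)) - n_top, 0)
    tiers = ["top5"] * n_top + ["mid"] * n_mid + ["low"] * (n - n_top - n_mid)
    edges["tier"] = tiers[:n]
    return edges


@dataclass
class MINetwork:
    """Full coevolution analysis result for one alignment."""

    columns: np.ndarray  # reference residue numbers per alignment column
    kl: np.ndarray
    z: np.ndarray
    cmi: np.ndarray
    pmi: Optional[np.ndarray]
    edges: pd.DataFrame
    flagged: np.ndarray
    weights: np.ndarray


def analyze(
    alignment: Alignment,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    threshold: float = DEFAULT_MI_THRESHOLD,
    clustering_identity: float = DEFAULT_CLUSTERING_IDENTITY,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gap_cutoff: float = DEFAULT_GAP_CUTOFF,
    background: Optional[np.ndarray] = None,
    contacts: Optional[pd.DataFrame] = None,
    radius: Optional[float] = None,
) -> MINetwork:
    """Run the full pipeline: weights, KL, MI z-scores, cMI, pMI, edge tiers."""
    weights = sequence_weights(alignment, clustering_identity)
    freqs, flagged, _ = weighted_frequencies(
        alignment, clustering_identity, pseudocount, gap_cutoff, weights=weights
    )
    kl = kl_conservation(freqs, background, flagged)
    z = mi_zscores(
        alignment, n_shuffles, seed, clustering_identity, pseudocount, gap_cutoff
    )
    cmi = cumulative_mi(z, threshold)
    refnum = alignment.column_to_ref()
    pmi = None
    if contacts is not None:
        pmi = proximity_mi(cmi, contacts, radius, positions=refnum)
    edges = tier_edges(z, threshold)
    return MINetwork(refnum, kl, z, cmi, pmi, edges, flagged, weights)


def per_column_table(net: MINetwork) -> pd.DataFrame:
    """Tidy per-column TSV content: column, ref_residue, KL, cMI, pMI."""
    df = pd.DataFrame(
        {
            "column": np.arange(1, len(net.kl) + 1),
            "ref_residue": net.columns,
            "kl": net.kl,
            "cmi": net.cmi,
            "pmi": net.pmi if net.pmi is not None else np.nan,
        }
    )
    return df
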