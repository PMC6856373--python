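# Methods

This note records the models and procedures naddkit implements, the
parameters that matter, the numerical conventions, and what the synthetic
generators do and do not emulate.

## Pattern engine

A Prosite pattern is an ordered list of elements — fixed residue, residue
class `[..]`, negated class `{..}`, wildcard `x` — each with an inclusive
repeat range (n, m), n ≥ 1. Both the compact spelling (`Gx(5)E`) and the
canonical dash-separated spelling (`G-x(5)-E.`) parse to the same element
list; `<` and `>` anchors are supported by the grammar though the NADD
motifs do not use them.

Scanning uses a forward dynamic program: from each candidate start the set
of reachable offsets is propagated element by element, each element
extending every reachable position by any admissible repeat count over a
contiguous run of matching residues. This enumerates every valid (start,
end) pair without the exponential blow-up of naive backtracking; cost is
O(starts × elements × max-repeat). Greedy mode keeps the longest end per
start (ScanProsite-like), lazy the shortest, all every distinct end.
Greedy is the default; classification uses match existence only, so the
mode cannot change a verdict.

Ambiguity policy (conservative by design, to avoid asserting motif hits on
uncertain residues): `X` satisfies only the wildcard; `B`, `Z`, `U`, `O`
satisfy only the wildcard — never a class, negated class or fixed residue.
The regex translation (`to_regex_text`) encodes the same policy with
explicit character sets, which is what makes it usable as an independent
cross-check: a brute-force oracle enumerating all substrings against the
translated regex must agree with the native scanner span for span.

Match traces (the per-element start positions within a known match) are
reconstructed by a backward-reachability pass followed by a left-greedy
walk, making the trace deterministic when several repeat assignments reach
the same end. The NADD classifier reads the three zinc-coordinating
positions (the `[CS]`, `[CD]`, `[CN]` elements) off this trace. The fourth
zinc-coordinating cysteine of the subfamily is not a pattern element and
is deliberately not reported.

## Classification and reporting

A sequence is NADD iff the detection pattern matches at least once
("any match" semantics); the first greedy span is reported. The Nudix box
and the signature core are located independently for annotation only.
Matched rates are percentages rounded half away from zero to one decimal
(Python's built-in banker's rounding would turn 3.195% into 3.2% only by
accident of binary representation; the Decimal-based rule is exact).

Taxonomy rollups count classified positives per rank with percentages of
both the parent level and the total, sequences without lineage grouped
under `unassigned`; child counts at any rank sum to the parent count.
Percentages use the half-away-from-zero rule at one decimal, switching to
two decimals below 0.1% so tiny shares survive printing. Domain
architectures order retained hits by start coordinate and join names with
`_`; overlaps are resolved greedily — higher score first, ties to the
longer hit, then the smaller start — dropping a candidate only when it
overlaps a kept hit by more than 30% of the shorter hit's length.
Adjacent identical domain names are not collapsed (Ank_2 / Ank_5 and the
like are family names, not repeat counts).

## Coevolution analysis

Sequences are clustered at 62% identity (single linkage over pairwise
identity computed on mutually ungapped columns) and weighted 1 / cluster
size, the standard defence against redundant sampling. Frequencies carry
a pseudocount λ = 0.05 per residue cell; pair tables use λ/20 per joint
cell so the joint's marginals remain consistent with the single-column
frequencies. Columns whose weighted gap fraction exceeds 0.5 are flagged
and excluded. All parameters are configurable; these defaults follow the
published MISTIC protocol.

Per-column conservation is the Kullback–Leibler divergence
Σ_a p_a ln(p_a/q_a) in nats against the BLOSUM62 marginal background
(configurable). Pairwise mutual information
MI_ij = Σ_ab p_ab ln(p_ab/(p_a p_b)) is computed from weighted,
pseudocounted joints over sequences ungapped in both columns; with the
pseudocount disabled the identities MI_ij = MI_ji and MI_ii = H_i hold to
machine precision, which the tests assert at 1e-9. Significance comes from
a null of 100 independent per-column permutations of the residues across
sequences: z_ij = (MI_ij − null mean)/(null sd). The 6.5 threshold is
applied to these z-scores (the original figure does not say whether its
threshold was raw or z-scored; z-scored is assumed and documented here).
cMI_i sums the above-threshold z-scores of column i; pMI_i averages the
cMI of residues in spatial contact with i when a contact/distance table is
supplied, and is absent otherwise.

Edge tiers over the above-threshold edges: the strongest ceil(0.05 n)
edges are `top5`, the next block up to the strongest 30% is `mid` (the
70th–95th percentile band), the remaining 70% `low`. Count-based cutoffs
make the single-edge case well-defined (it is `top5`).

## Phylogeny

Distances: p-distance (mismatches over pairwise-comparable sites, gaps
and ambiguity codes deleted pairwise) and Poisson correction
d = −ln(1 − p). Maximum-likelihood substitution-matrix distances (e.g.
JTT) are intentionally out of scope: they add a rate-matrix machinery
orthogonal to this toolkit's purpose, and at the divergence levels the
bundled generators produce, NJ topology is robust to the distance choice.

Neighbor joining follows Saitou–Nei with the standard Q-criterion
Q_ij = (m−2)d_ij − r_i − r_j. Ties in Q are broken by the
lexicographically smallest index pair over the current node ordering
(original taxa first, agglomerated nodes in creation order), making the
algorithm deterministic; under exact distance ties a taxon permutation
can therefore legitimately alter weakly supported splits, while strong
splits are unaffected. Negative branch lengths are clamped to zero with
the deficit transferred to the sibling branch (Kuhner–Felsenstein). On
additive matrices NJ recovers topology and branch lengths exactly; the
tests verify this with a four-point oracle on random additive quartets,
and cross-check topologies against an independent NJ implementation.

Bootstrap support is the Felsenstein column bootstrap: columns resampled
with replacement, one tree per replicate, support = percentage of
successful replicates containing each internal bipartition of the
full-data tree. Replicates where some pair loses all comparable sites
(or saturates the Poisson transform) are skipped and counted. Trees are
dendropy objects; Newick output carries branch lengths and support as
internal node labels.

## Kinetics

The model is plain Michaelis–Menten, v = Vmax·S/(KM + S) — no substrate
inhibition or Hill variants. Unit contract: S and KM in mM, rates in
µM/s, E0 in µM, so kcat = Vmax/E0 is in 1/s and kcat/KM in 1/(mM·s).
Initial values come from a Hanes–Woolf linearisation (S/v on S); the fit
is scipy nonlinear least squares with non-negativity bounds. Residuals
carry relative (1/v) weights by default: chromatographic peak areas have
a roughly constant coefficient of variation, for which relative weighting
is the efficient estimator; unweighted fitting is available. Standard
errors come from the fit covariance; the efficiency SE uses first-order
propagation with KM and kcat treated as independent.

Report rounding: KM, kcat and efficiencies to three significant figures,
substrate-preference ratios to two decimals, all half away from zero.

The initial-rate helper is an ordinary least-squares slope over a stated
linear window (at least three points) — peak integration itself is out of
scope.

## Synthetic generators and what passing tests mean

All generators are deterministic under a fixed seed, and self-checking
where they promise a property: pattern positives are re-scanned before
being returned, negatives (a fixed element of a minimal positive mutated
out of its class) are verified not to match and re-drawn in the rare case
an alternative match survives.

* Covarying MSAs plant perfectly correlated two-state column pairs in
  i.i.d. uniform noise — a best-case coevolution signal. Recovery there
  shows the MI machinery is correct, not that real, phylogenetically
  confounded alignments would behave as cleanly.
* Clade MSAs mutate two ancestor sequences (differing at a fraction
  1 − between_id of sites) independently per taxon at rate
  (1 − within_id)/2. There are no indels, no rate heterogeneity and no
  within-clade structure, so bootstrap values near 100% are expected by
  construction.
* Kinetic datasets apply multiplicative Gaussian noise of coefficient of
  variation `cv` to exact Michaelis–Menten rates, clipped at zero. The
  default 7-level design (`mm_design_grid`) concentrates four levels at
  0.1–0.5×KM and three at 5–25×KM, following optimal-design reasoning:
  with relative error, KM information lives below KM and Vmax information
  at saturation. Even at this design the asymptotic KM relative SE at 5%
  CV with triplicates is ≈ 2–3%, so over 200 independent experiments the
  worst single run is an extreme-order statistic around 3σ and can
  occasionally exceed 10% relative error; the median sits comfortably
  under 5%.

## Problem sizes

The bundled checks run at desk scale, chosen to exercise every code path
while completing in minutes: scanner-oracle comparison over ~1,100 random
sequences (≤ 60 aa) and 52 patterns; 200 simulated kinetic experiments
(21 points each); 100 random additive quartets; a 10-taxon two-clade
bootstrap at 100 replicates; 100 coevolution alignments of 64 × 30 with a
100-permutation null. Database-scale figures (thousands of sequences
against UniProtKB releases) are inherently release-dependent and are
covered as arithmetic on their published counts, not recomputed.

## Known limitations

* Approximate (mismatch-tolerant) pattern matching and Prosite profiles
  are not implemented; patterns are exact.
* The coevolution null permutes columns independently, which destroys
  phylogenetic correlation; on real alignments MI z-scores are known to be
  inflated by shared ancestry.
* NJ tie-breaking is input-order dependent under exact ties (documented
  above); JTT/ML distances are not offered.
* The kinetics module fits initial rates only; it does not model substrate
  inhibition, cooperativity, or progress curves.
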