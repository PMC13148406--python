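# Methods

This note records the models, numerical choices, and deliberate
simplifications behind markerphylo, in the order the pipeline runs.

## Profile HMM architecture and scoring

Each marker profile is a Plan-7-style model with match states M_1..M_M,
insert states I_1..I_{M-1}, delete states D_1..D_M, and begin/end states.
Alignment is **glocal**: every path runs B → {M_1 | D_1} ... {M_M | D_M} →
E, so the model is always traversed in full, while any number of flanking
sequence residues are absorbed before B and after E by free loop states
that emit at the null frequencies — their emission log-odds is zero and
the loop transitions carry no penalty. This is the natural contract for
single-domain, BUSCO-style markers; multihit local alignment, E-value
calibration, and bias filters are deliberately out of scope (thresholds
operate on bit scores; `STATS` lines in HMMER3 inputs are parsed and
ignored). There is no I_0 state; files whose begin node carries insert
mass (hmmbuild output) have that mass folded proportionally into B→M_1 and
B→D_1 on read.

Scores are log-odds against the null in bits. `forward_bits` sums over all
paths; `viterbi` maximises and returns the state path used for alignment.
Both DPs run in natural-log space with per-row vectorisation over model
positions; the same-row delete recursion D_k = op(in_k, D_{k-1} + t_DD) is
solved with a cumulative-sum offset so `logaddexp.accumulate` /
`maximum.accumulate` apply. Probability zero is floored at −10⁶ nats
instead of −inf so those scans stay NaN-free; any score reachable only
through a floored step is far below −5·10⁵ nats and is reported as −inf.
Both DPs match brute-force path enumeration to 10⁻⁹ bits on small models
(see the test suite).

**Search acceleration.** Scoring every sequence against every profile with
the full DP is quadratic and dominated by hopeless pairs. `search_sample`
therefore screens each pair with the best full-length ungapped diagonal
score (computable with one vectorised gather) and skips the DP when even
that bound plus a 30-bit safety margin cannot reach the reporting cutoff —
the same engineering idea as HMMER's acceleration filters. The screen is a
heuristic: an alignment with indels can in principle beat the best single
diagonal by more than the margin, so `prefilter=False` gives the exact
contract. On realistic inputs true hits sit hundreds of bits above the
cutoff and decoys hundreds below, and the planted-hit tests run both modes.

**Thresholds.** The reporting threshold is the profile's gathering cutoff
(GA line) when present, else a flat floor, default 10 bits — low enough to
keep genuinely homologous but diverged copies, high enough that random
sequences (expected negative log-odds per residue) never reach it.

**Worker plan.** Below eight CPUs one search instance uses all cores; at
eight or more the pool becomes `floor(n/4)` instances of four cores
(single large instances scale poorly). The current executor runs instances
sequentially; the plan is computed, logged, and contract-tested so a
process-pool executor can be dropped in without semantic change.

## Orthology and checkpointing

Strict single-copy enforcement removes an entire (marker, sample) cell
whenever it holds ≥ 2 passing hits; one duplicated marker never costs a
sample its other markers. A sequence may serve several markers — markers
are treated as independent. Markers kept for tree building must be present
in ≥ `min_taxa` samples (default 4, the run-level minimum; the run itself
also requires ≥ 4 samples).

Checkpoints are JSON-lines files: a header with a format version and a
fingerprint (digest of marker-set digest, threshold, and sequence type),
then one record per sample keyed by the SHA-256 of the file's raw bytes.
Compressed inputs are hashed as-is, without decompression, so shared
checkpoints are reproducible byte-for-byte. Renaming a file changes
nothing; editing it forces a re-search of that sample only. Entries whose
files are absent from a run are dropped from that run's hit table but kept
in the checkpoint, so removed samples can return for free. A fingerprint
mismatch is refused unless forced (then everything is re-searched).
Checkpointing covers only the search step; downstream artifacts are cheap
and always rebuilt.

## Alignment and trimming

Surviving sequences are threaded through their Viterbi paths: column k
holds the residue emitted at M_k, `-` where the path used D_k; insert and
flank residues are discarded, so every marker alignment has width M.
Trimming keeps parsimony-informative columns only — ≥ 2 distinct states,
each in ≥ 2 rows, with gaps and ambiguity codes (X/B/Z/J/U/O/\* for
peptides, anything outside ACGT for nucleotides) counting as missing; this
is the strictest reading of "informative" and is idempotent by
construction. Internal indices are 0-based; reports and partition files
are 1-based inclusive.

CDS mode searches and aligns on the translation (standard genetic code),
then threads the codons that sit behind each aligned residue back under
the trimmed columns (peptide gap → `---`). Because insert/flank residues
are dropped by profile alignment, the pipeline slices codons by the
recorded residue indices rather than assuming the CDS matches the aligned
row end-to-end.

## Informativeness scoring

Gene trees for scoring are neighbor joining on pairwise distances computed
over columns where both rows are present. NJ is implemented directly
(deterministic Q-criterion tie-break toward the first pair, negative
branch estimates clamped to zero, exact 3-cluster termination) and
recovers additive matrices exactly — topology and branch lengths — which
the suite verifies against random tree-derived matrices and dendropy's
independent implementation.

Treeness is Σ internal / Σ all branch lengths on the unrooted shape (a
bifurcating root's two child edges count as one edge); zero-length trees
score 0 with a warning. RCV is Σ_j Σ_i |c_ij − c̄_j| / (n·t) with gaps and
ambiguity excluded from the counts. The ranking statistic is
treeness / max(RCV, ε) with ε = 10⁻⁹: perfectly homogeneous composition is
maximally desirable and must rank above any positive RCV, not divide by
zero. Ties break lexicographically by marker id. Filtering is opt-in
(default keeps all markers): small "best-n" subsets can reduce accuracy,
and an aggressively filtered, informative-sites-only matrix under-represents
invariant sites.

**Distance model choice.** `pairwise_distance` offers raw mismatch
fraction (p), Poisson correction −ln(1−p), and JC69 for nucleotides, with
saturated pairs capped at distance 10 with a warning. The *pipeline*
builds all trees from p-distances: trimmed alignments contain only
parsimony-informative sites, and log-corrections assume sites are an
unbiased sample of the sequence — on ascertainment-filtered columns they
over-correct, distort additivity, and demonstrably cost NJ short internal
branches. Raw p is monotone in evolutionary distance at the divergences
the pipeline targets and is robust to the filtering.

## Species-tree inference

**Consensus (quartet) mode.** For tips T and gene trees G, the objective
is Σ_{g∈G} |{quartets q ⊆ tips(g): g and S induce the same topology on
q}|, the ASTRAL-style maximum-quartet-support criterion. Induced quartet
topologies come from the four-point condition on unit-branch-length
(topological) distances; ties mean the quartet is unresolved (polytomies
are accepted and simply contribute nothing). Up to 8 taxa the search is
exhaustive: all (2n−5)!! topologies are enumerated once per tip count,
their per-quartet codes cached, and each candidate scored from a
quartet × topology count table in one vectorised pass. Beyond 8 taxa a
greedy start (NJ on the mean topological distance across gene trees) is
refined by NNI hill-climbing to a local optimum — an honest desk-scale
stand-in for dedicated quartet solvers, and exact on the scales the
package targets by construction for n ≤ 8. Ties between optimal
topologies resolve to the first enumerated.

**Concatenation mode.** Markers are concatenated in sorted-id order; taxa
missing from a marker get gap runs over exactly that partition; partitions
tile [1, width] with 1-based inclusive bounds and round-trip through a
RAxML-style partition file (`PROT, mk0001 = 1-200`). The internal tree is
NJ on supermatrix p-distances; the supermatrix and partition file are also
written for external partitioned-ML tools, which is deliberately where
model selection and ML search live.

**Branch support.** Nonparametric bootstrap (default B = 100): columns are
resampled with replacement, the tree rebuilt, and each internal branch of
the point tree labelled with the percentage of replicates containing its
split. (The contract — % of replicates containing a split — matches
approximate methods like UFBoot while staying exact and dependency-free.)
Site concordance factors follow the quartet-sampling definition: for each
internal branch, q = 100 quartets with one tip drawn from each of the four
surrounding subtrees; a site is decisive for a quartet when all four
residues are present and form two states of two rows each, and concordant
when its pairing matches the branch; the branch sCF is the mean supporting
percentage over quartets with decisive sites, or missing if there are
none. All sampling derives from the run seed; identical seeds give
identical annotations.

**Benchmark statistics.** Plain Robinson–Foulds distance is the symmetric
difference of non-trivial split sets, normalised by 2(n−3); a group is
monophyletic iff its tips form one side of some bipartition of the
unrooted tree (singletons by convention). Both are cross-checked against
independent implementations in the suite.

## Synthetic data generator

The simulator emulates the pipeline's inputs end to end with a known
truth. The species tree is a Yule tree: a uniformly chosen extant lineage
splits until n tips exist; every branch length is 0.01 + Exp(mean 0.04)
substitutions/site — the floor keeps internal branches away from the
degenerate zero-length regime no real species tree occupies, and the
resulting root-to-tip depth at the default 8 taxa stays below ~0.3
substitutions/site, the "low divergence" regime the defaults target.

Marker families evolve site-independently under an equal-rate 20-state
model (the protein analogue of Jukes–Cantor): along a branch of length b
each site changes to a uniformly chosen different residue with probability
p(b) = (19/20)(1 − e^{−20rb/19}). The closed form makes the generator
checkable by Monte Carlo and the expected pairwise distances analytic.
Proteomes contain each taxon's marker genes under opaque shuffled ids plus
n_decoys random sequences drawn from the same background frequencies as
the markers — so search specificity is genuinely exercised — and,
optionally, near-identical paralogs (1% point mutations) injected for
chosen (sample, marker) pairs. CDS fixtures back-translate each protein
with uniformly random synonymous codons. Marker profiles are built from
the *true* alignments with Laplace pseudocounts
((count + α)/(n_obs + 20α), α = 1), match columns at gap fraction ≤ 0.5,
and fixed documented transitions (M→M 0.9, M→I 0.05, M→D 0.05; I→M 0.8,
I→I 0.2; D→M 0.8, D→D 0.2; begin 0.95/0.05).

Everything is a pure function of the `SimulationSpec`; the seed fixes all
draws, and the peptide and CDS renderings of one spec contain the same
proteins (content and codon choice use separate streams).

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: no indels (real alignments need insert states
to do real work; here Viterbi paths are almost pure match), no
across-site rate variation or empirical exchangeabilities, no
compositional bias, no incomplete lineage sorting or horizontal transfer
(gene trees disagree with the species tree only through substitution
noise), and decoys are i.i.d. background rather than real non-orthologous
gene families. Results on fixtures bound correctness of the machinery, not
accuracy on empirical proteomes.

## Default study conditions and problem sizes

The defaults — 8 taxa, 50 markers × 200 residues, rate 1.0,
5 decoys/sample — are the conditions under which the package's acceptance
quantities are computed: 20 replicate seeds, both inference modes, with
topology recovery (RF = 0 against the generating tree) expected in ≥ 90%
of replicates. Unit and property tests use smaller systems (4–8 taxa,
markers of 25–150 residues) chosen to exercise each contract quickly.

## Known limitations

* Glocal-only search mis-scores multi-domain or fragmented proteins;
  truncated genes surface as low-scoring hits or dropped rows.
* The diagonal prefilter can, in adversarial cases, skip a pair whose
  gapped alignment clears the cutoff while every diagonal is > 30 bits
  short; exact mode exists but is slower.
* NJ-based internal trees carry no substitution-model sophistication; the
  supermatrix + partition export is the intended path to ML inference.
* The NNI consensus search (> 8 taxa) finds a local optimum only.
* sCF is undefined (and reported missing) on branches adjacent to
  polytomies and on alignments without decisive sites.
* Checkpoint files are version-locked: a format bump invalidates old
  checkpoints rather than migrating them.
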