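"""Per-ortholog informativeness: gene trees, treeness, RCV, ranking.

Orthologs differ widely in how much clean, tree-like signal they carry.
Following the treeness/RCV idea, each marker alignment gets a quick
distance-based gene tree; *treeness* (internal branch length over total
tree length) rewards markers whose divergence lives on internal branches,
while *RCV* (relative composition variability) penalises compositional
heterogeneity across taxa, a classic source of systematic error.  Markers
are ranked by treeness / RCV, and the user may keep only the top n —
though filtering is opt-in, since aggressive subsetting can hurt accuracy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .alignment import MarkerAlignment, residue_codes
from .errors import InputError
from .profile_hmm import AMINO20, DNA4

#: rcv floor used in the treeness/RCV ratio: a perfectly homogeneous
#: composition should rank (very) high, not divide by zero
RCV_EPSILON = 1e-9

#: distance assigned to saturated pairs (log-correction undefined)
SATURATION_CAP = 10.0

DISTANCE_MODELS = ("p", "poisson", "jc69")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise InputError(f"distance matrix shape {self.d.shape} does not match {n} taxa")

    def validate(self) -> None:
        if not np.all(np.isfinite(self.d)):
            raise InputError("distance matrix has non-finite entries")
        if np.any(self.d < 0):
            raise InputError("distance matrix has negative entries")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise InputError("distance matrix diagonal is not zero")
        if np.any(np.abs(self.d - self.d.T) > 1e-12):
            raise InputError("distance matrix is not symmetric")


def pairwise_distance(msa: MarkerAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances over shared (both non-gap, unambiguous) columns.

    ``p`` is the raw mismatch fraction; ``poisson`` applies -ln(1-p);
    ``jc69`` (nucleotide) applies -(3/4) ln(1 - 4p/3).  Saturated pairs
    (p >= 1 for poisson, p >= 3/4 for jc69) are capped at
    ``SATURATION_CAP`` with a warning.
    """
    if model not in DISTANCE_MODELS:
        raise InputError(f"unknown distance model {model!r}; expected one of {DISTANCE_MODELS}")
    if msa.n_taxa < 2:
        raise InputError("pairwise distances need at least two rows")
    alphabet = AMINO20 if msa.seqtype == "pep" else DNA4
    codes = residue_codes(msa.rows, alphabet)
    n = msa.n_taxa
    d = np.zeros((n, n))
    saturated = False
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            shared = int(ok.sum())
            if shared == 0:
                raise InputError(
                    f"{msa.marker_id}: taxa {msa.taxa[i]!r} and {msa.taxa[j]!r} share no comparable columns"
                )
            p = float((codes[i][ok] != codes[j][ok]).sum()) / shared
            if model == "p":
                dist = p
            elif model == "poisson":
                if p >= 1.0:
                    dist, saturated = SATURATION_CAP, True
                else:
                    dist = -math.log(1.0 - p)
            else:  # jc69
                if p >= 0.75:
                    dist, saturated = SATURATION_CAP, True
                else:
                    dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    if saturated:
        warnings.warn(f"{msa.marker_id}: saturated pairwise distance(s) capped at {SATURATION_CAP}")
    return DistanceMatrix(taxa=list(msa.taxa), d=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; negative branch lengths clamped to 0).

    NJ recovers any additive (tree-realisable) matrix exactly, topology and
    branch lengths both, which makes it a solid deterministic gene-tree
    builder at marker scale.  Ties in the Q criterion break toward the
    lexicographically first cluster pair.
    """
    dm.validate()
    n = len(dm.taxa)
    if n < 3:
        raise InputError("neighbor joining needs at least three taxa")
    # active clusters as (newick fragment, original order index)
    nodes = [(label, i) for i, label in enumerate(dm.taxa)]
    D = dm.d.copy()
    active = list(range(n))

    def brlen(v: float) -> str:
        return repr(max(float(v), 0.0))

    frags = {i: dendropy_safe(dm.taxa[i]) for i in range(n)}
    next_id = n
    Dfull = {(i, i): 0.0 for i in range(n)}
    for i in range(n):
        for j in range(n):
            Dfull[(i, j)] = D[i, j]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(Dfull[(i, k)] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * Dfull[(i, j)] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * Dfull[(i, j)] + (r[i] - r[j]) / (2 * (m - 2))
        vj = Dfull[(i, j)] - vi
        u = next_id
        next_id += 1
        frags[u] = f"({frags[i]}:{brlen(vi)},{frags[j]}:{brlen(vj)})"
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (Dfull[(i, k)] + Dfull[(j, k)] - Dfull[(i, j)])
            Dfull[(u, k)] = Dfull[(k, u)] = duk
        Dfull[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    va = 0.5 * (Dfull[(a, b)] + Dfull[(a, c)] - Dfull[(b, c)])
    vb = 0.5 * (Dfull[(a, b)] + Dfull[(b, c)] - Dfull[(a, c)])
    vc = 0.5 * (Dfull[(a, c)] + Dfull[(b, c)] - Dfull[(a, b)])
    newick = f"({frags[a]}:{brlen(va)},{frags[b]}:{brlen(vb)},{frags[c]}:{brlen(vc)});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def dendropy_safe(label: str) -> str:
    if any(ch in label for ch in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def treeness(tree: dendropy.Tree) -> float:
    """Sum of internal branch lengths over total tree length, in [0, 1].

    Works on the unrooted shape: a bifurcating root's two child edges count
    as the single unrooted edge they represent.  A tree with zero total
    length is defined to have treeness 0 (with a warning).
    """
    root = tree.seed_node
    root_children = root.child_nodes()
    basal_bifurcation = len(root_children) == 2
    total = 0.0
    internal = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        length = edge.length or 0.0
        if length < 0:
            raise InputError("treeness requires non-negative branch lengths")
        total += length
        head = edge.head_node
        if head.is_leaf():
            continue
        if basal_bifurcation and head.parent_node is root:
            continue  # handled as part of the merged root edge below
        internal += length
    if basal_bifurcation:
        c1, c2 = root_children
        if not c1.is_leaf() and not c2.is_leaf():
            internal += (c1.edge.length or 0.0) + (c2.edge.length or 0.0)
    if total <= 0.0:
        warnings.warn("tree has zero total branch length; treeness defined as 0")
        return 0.0
    return internal / total


def rcv(msa: MarkerAlignment) -> float:
    """Relative composition variability of an alignment.

    Mean absolute deviation of each taxon's residue counts from the
    across-taxa mean count, summed over states and normalised by
    (n taxa x alignment width).  Gaps and ambiguity codes are excluded
    from the counts.  Zero iff every taxon has identical state counts.
    """
    if msa.n_taxa == 0 or msa.width == 0:
        raise InputError("rcv needs a non-empty alignment")
    alphabet = AMINO20 if msa.seqtype == "pep" else DNA4
    codes = residue_codes(msa.rows, alphabet)
    n, t, K = msa.n_taxa, msa.width, len(alphabet)
    counts = np.vstack([np.bincount(row[row >= 0], minlength=K) for row in codes]).astype(float)
    mean = counts.mean(axis=0)
    return float(np.abs(counts - mean).sum() / (n * t))


@dataclass(frozen=True)
class MarkerScore:
    marker_id: str
    treeness: float
    rcv: float

    @property
    def score(self) -> float:
        return self.treeness / max(self.rcv, RCV_EPSILON)


def score_marker(msa: MarkerAlignment, model: str = "poisson",
                 gene_tree: dendropy.Tree | None = None) -> MarkerScore:
    """Treeness/RCV score for one marker.

    Builds an NJ gene tree from the alignment unless an externally computed
    tree is supplied (adapter for e.g. approximate-ML gene trees).
    """
    tree = gene_tree if gene_tree is not None else nj_tree(pairwise_distance(msa, model))
    return MarkerScore(marker_id=msa.marker_id, treeness=treeness(tree), rcv=rcv(msa))


def rank_markers(scores, top_n: int | None = None) -> list[str]:
    """Marker ids in descending treeness/RCV order (ties lexicographic),
    truncated to ``top_n`` when given."""
    if top_n is not None and top_n < 1:
        raise InputError("top_n must be >= 1")
    ordered = sorted(scores, key=lambda s: (-s.score, s.marker_id))
    ids = [s.marker_id for s in ordered]
    return ids if top_n is None else ids[:top_n]
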