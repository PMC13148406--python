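"""Species-tree inference, branch support, and tree-comparison statistics.

Two inference strategies are offered, mirroring standard phylogenomic
practice:

* **consensus** — build one gene tree per marker and return the species
  topology maximising the number of induced four-taxon (quartet) topologies
  shared with the gene trees (the ASTRAL-style objective).  The search is
  exhaustive over all unrooted binary topologies up to 8 taxa and a greedy
  start plus NNI hill-climbing beyond that.
* **concatenation** — join all marker alignments into a supermatrix with
  1-based inclusive partitions, infer a distance tree, and attach standard
  nonparametric bootstrap support and site concordance factors (sCF).

Also here: plain Robinson–Foulds distance and monophyly assessment, used to
benchmark inferred trees against a reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .alignment import MarkerAlignment, residue_codes
from .errors import InputError, ValidationError
from .informativeness import DistanceMatrix, dendropy_safe, nj_tree, pairwise_distance

# ---------------------------------------------------------------------------
# newick + split utilities
# ---------------------------------------------------------------------------


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a newick tree from a path or a literal newick string."""
    text = None
    if isinstance(source, Path) or "(" not in str(source):
        p = Path(source)
        if not p.exists():
            raise InputError(f"no such newick file: {source}")
        text = p.read_text()
    else:
        text = str(source)
    tree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree.as_string(schema="newick", suppress_rooting=True))


def tree_tips(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _adjacency(tree: dendropy.Tree) -> tuple[dict, dict]:
    """Undirected adjacency of the unrooted shape (a degree-2 root is
    collapsed).  Returns (adjacency, leaf label -> node)."""
    adj: dict = {}
    leaves: dict[str, object] = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(node, set())
        if node.is_leaf():
            if node.taxon is None:
                raise InputError("tree has an unlabeled leaf")
            leaves[node.taxon.label] = node
        for child in node.child_nodes():
            adj.setdefault(child, set())
            adj[node].add(child)
            adj[child].add(node)
    root = tree.seed_node
    if len(adj.get(root, ())) == 2:
        a, b = tuple(adj[root])
        adj[a].discard(root)
        adj[b].discard(root)
        adj[a].add(b)
        adj[b].add(a)
        del adj[root]
    return adj, leaves


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits of the unrooted tree, each canonicalised as the
    side not containing the alphabetically first tip."""
    tips = tree_tips(tree)
    if len(set(tips)) != len(tips):
        raise InputError("tree has duplicate tip labels")
    ref = tips[0]
    all_tips = frozenset(tips)
    adj, leaves = _adjacency(tree)
    splits: set[frozenset] = set()
    n = len(tips)
    for side in _edge_sides(adj, leaves):
        if 1 < len(side) < n - 1:  # both sides must hold >= 2 tips
            splits.add(side if ref not in side else all_tips - side)
    return splits


def _edge_sides(adj: dict, leaves: dict) -> list[frozenset]:
    """For every edge, the tip-label set on one side."""
    sides = []
    seen = set()
    for u in adj:
        for v in adj[u]:
            key = (id(u), id(v)) if id(u) < id(v) else (id(v), id(u))
            if key in seen:
                continue
            seen.add(key)
            sides.append(frozenset(_tips_beyond(adj, v, u, leaves)))
    return sides


def _tips_beyond(adj: dict, start, blocked, leaves: dict) -> list[str]:
    """Tip labels reachable from ``start`` without crossing ``blocked``."""
    label_of = {id(node): lab for lab, node in leaves.items()}
    out = []
    stack = [(start, blocked)]
    while stack:
        node, prev = stack.pop()
        lab = label_of.get(id(node))
        if lab is not None:
            out.append(lab)
        for nb in adj[node]:
            if nb is not prev:
                stack.append((nb, node))
    return out


def topo_distance_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Unit-branch-length (topological) leaf-to-leaf distances."""
    adj, leaves = _adjacency(tree)
    labels = sorted(leaves)
    n = len(labels)
    D = np.zeros((n, n))
    for i, lab in enumerate(labels):
        dist = {id(leaves[lab]): 0}
        frontier = [leaves[lab]]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj[node]:
                    if id(nb) not in dist:
                        dist[id(nb)] = dist[id(node)] + 1
                        nxt.append(nb)
            frontier = nxt
        for j, lab2 in enumerate(labels):
            D[i, j] = dist[id(leaves[lab2])]
    return labels, D


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Plain Robinson–Foulds distance: size of the symmetric difference of
    the two trees' non-trivial split sets, plus the 2(n-3) normalisation."""
    tips1, tips2 = tree_tips(t1), tree_tips(t2)
    if tips1 != tips2:
        raise InputError("trees have different tip sets")
    raw = len(bipartitions(t1) ^ bipartitions(t2))
    denom = 2 * (len(tips1) - 3)
    return raw, (raw / denom) if denom > 0 else 0.0


def check_monophyly(tree: dendropy.Tree, groups: Mapping[str, str]) -> dict[str, bool]:
    """Per-group monophyly on the unrooted tree.

    A group is monophyletic iff its tips form one side of some bipartition;
    singletons (and the full tip set) are monophyletic by convention.
    """
    tips = set(tree_tips(tree))
    missing = tips - set(groups)
    if missing:
        raise InputError(f"unlabeled tips: {sorted(missing)}")
    adj, leaves = _adjacency(tree)
    sides = {frozenset(s) for s in _edge_sides(adj, leaves)}
    all_tips = frozenset(tips)
    status: dict[str, bool] = {}
    for label in sorted(set(groups.values())):
        g = frozenset(t for t in tips if groups[t] == label)
        status[label] = len(g) <= 1 or g == all_tips or g in sides or (all_tips - g) in sides
    return status


# ---------------------------------------------------------------------------
# supermatrix
# ---------------------------------------------------------------------------


@dataclass
class Supermatrix:
    """Concatenated marker alignments with 1-based inclusive partitions."""

    alignment: MarkerAlignment
    partitions: list[tuple[str, int, int]]

    def validate(self) -> None:
        pos = 1
        for marker, start, end in self.partitions:
            if start != pos or end < start:
                raise ValidationError(f"partitions do not tile: {marker} spans {start}-{end}, expected start {pos}")
            pos = end + 1
        if pos != self.alignment.width + 1:
            raise ValidationError(f"partitions cover 1-{pos - 1} but the supermatrix has width {self.alignment.width}")

    def write_partitions(self, path: str | Path) -> None:
        kind = "PROT" if self.alignment.seqtype == "pep" else "DNA"
        lines = [f"{kind}, {m} = {s}-{e}" for m, s, e in self.partitions]
        Path(path).write_text("\n".join(lines) + "\n")

    @staticmethod
    def read_partitions(path: str | Path) -> list[tuple[str, int, int]]:
        parts = []
        for ln in Path(path).read_text().splitlines():
            if not ln.strip():
                continue
            _, rest = ln.split(",", 1)
            name, span = rest.split("=")
            start, end = span.split("-")
            parts.append((name.strip(), int(start), int(end)))
        return parts


def concat_supermatrix(msas: Sequence[MarkerAlignment], taxa: Sequence[str] | None = None) -> Supermatrix:
    """Concatenate marker alignments (sorted by marker id) into one matrix.

    Taxa absent from a marker are filled with gaps across that marker's
    partition, so every row spans the full width.
    """
    if not msas:
        raise InputError("no alignments to concatenate")
    seqtypes = {m.seqtype for m in msas}
    if len(seqtypes) > 1:
        raise InputError(f"conflicting sequence types in concatenation: {sorted(seqtypes)}")
    ordered = sorted(msas, key=lambda m: m.marker_id)
    if len({m.marker_id for m in ordered}) != len(ordered):
        raise InputError("duplicate marker ids in concatenation")
    for m in ordered:
        if m.width == 0:
            raise InputError(f"marker {m.marker_id} has zero width; drop it before concatenation")
    if taxa is None:
        taxa = sorted({t for m in ordered for t in m.taxa})
    else:
        taxa = list(taxa)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 1
    for m in ordered:
        parts.append((m.marker_id, pos, pos + m.width - 1))
        pos += m.width
        for t in taxa:
            chunks[t].append(m.row(t) if t in m.taxa else "-" * m.width)
    sm = Supermatrix(
        alignment=MarkerAlignment(
            marker_id="supermatrix",
            taxa=taxa,
            rows=["".join(chunks[t]) for t in taxa],
            seqtype=ordered[0].seqtype,
        ),
        partitions=parts,
    )
    sm.validate()
    return sm


# ---------------------------------------------------------------------------
# quartets and the consensus strategy
# ---------------------------------------------------------------------------


def _quartet_code(D: np.ndarray, a: int, b: int, c: int, d: int) -> int | None:
    """0 = ab|cd, 1 = ac|bd, 2 = ad|bc, None = unresolved."""
    s = (D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c])
    best = min(s)
    if sum(1 for x in s if x == best) > 1:
        return None
    return int(np.argmin(s))


def quartet_score(species: dendropy.Tree, gene_trees: Iterable[dendropy.Tree]) -> int:
    """Number of gene-tree quartet topologies induced (and matched) by the
    species tree, summed over gene trees.  Only quartets resolved in both
    trees count; gene trees may cover a subset of the species tips."""
    sp_labels, sp_D = topo_distance_matrix(species)
    sp_index = {lab: i for i, lab in enumerate(sp_labels)}
    total = 0
    for gt in gene_trees:
        g_labels, g_D = topo_distance_matrix(gt)
        unknown = [lab for lab in g_labels if lab not in sp_index]
        if unknown:
            raise InputError(f"gene-tree tips not in species tree: {unknown}")
        for quartet in itertools.combinations(range(len(g_labels)), 4):
            code_g = _quartet_code(g_D, *quartet)
            if code_g is None:
                continue
            si = [sp_index[g_labels[i]] for i in quartet]
            code_s = _quartet_code(sp_D, *si)
            if code_s is not None and code_s == code_g:
                total += 1
    return total


def _enumerate_edge_lists(n: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies on leaves 0..n-1 as edge lists.

    Internal nodes are numbered from n upward; leaf insertion order makes
    the enumeration deterministic.
    """
    trees = [[(0, n), (1, n), (2, n)]]
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                w = next_internal
                new_edges = edges[:i] + edges[i + 1 :] + [(u, w), (w, v), (leaf, w)]
                new_trees.append(new_edges)
        trees = new_trees
        next_internal += 1
    return trees


def _edges_to_dist(edges: Sequence[tuple[int, int]], n: int) -> np.ndarray:
    """Topological leaf distances for an edge-list tree on leaves 0..n-1."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    D = np.zeros((n, n), dtype=np.int16)
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for node in frontier:
                for nb in adj[node]:
                    if nb not in dist:
                        dist[nb] = dist[node] + 1
                        nxt.append(nb)
            frontier = nxt
        for t in range(n):
            D[s, t] = dist[t]
    return D


@lru_cache(maxsize=4)
def _topology_bank(n: int) -> tuple[tuple, tuple, np.ndarray]:
    """(edge lists, quartet index list, per-topology quartet codes).

    Cached per n: candidate topologies depend only on the number of tips,
    so repeated consensus searches (bootstraps, replicate seeds) reuse it.
    """
    edge_lists = _enumerate_edge_lists(n)
    quartets = tuple(itertools.combinations(range(n), 4))
    codes = np.empty((len(edge_lists), len(quartets)), dtype=np.int8)
    for t, edges in enumerate(edge_lists):
        D = _edges_to_dist(edges, n)
        for q, (a, b, c, d) in enumerate(quartets):
            codes[t, q] = _quartet_code(D, a, b, c, d)
    return tuple(map(tuple, edge_lists)), quartets, codes


def _edges_to_tree(edges: Sequence[tuple[int, int]], labels: Sequence[str]) -> dendropy.Tree:
    n = len(labels)
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = adj[0][0]  # internal neighbor of leaf 0

    def render(node: int, prev: int) -> str:
        if node < n:
            return dendropy_safe(labels[node])
        return "(" + ",".join(render(nb, node) for nb in adj[node] if nb != prev) + ")"

    newick = "(" + ",".join(render(nb, root) for nb in adj[root]) + ");"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def _quartet_counts(labels: Sequence[str], gene_trees: Sequence[dendropy.Tree]) -> np.ndarray:
    """counts[q, topo] = how many gene trees resolve quartet q as topo."""
    index = {lab: i for i, lab in enumerate(labels)}
    quartets = list(itertools.combinations(range(len(labels)), 4))
    qindex = {quartet: qi for qi, quartet in enumerate(quartets)}
    counts = np.zeros((len(quartets), 3), dtype=np.int64)
    for gt in gene_trees:
        g_labels, g_D = topo_distance_matrix(gt)
        gl = [index[lab] for lab in g_labels]
        for combo in itertools.combinations(range(len(g_labels)), 4):
            code = _quartet_code(g_D, *combo)
            if code is None:
                continue
            s = [gl[i] for i in combo]  # species indices, gene-local order
            pair_a = {s[0], s[(1, 2, 3)[code]]}
            sorted_s = sorted(s)
            t0 = sorted_s[0]
            # re-express the pairing as: which sorted element partners t0
            if t0 in pair_a:
                mate = (pair_a - {t0}).pop()
            else:
                mate = ((set(s) - pair_a) - {t0}).pop()
            new_code = sorted_s.index(mate) - 1
            counts[qindex[tuple(sorted_s)], new_code] += 1
    return counts


def _score_codes(codes: np.ndarray, counts: np.ndarray) -> np.ndarray:
    Q = counts.shape[0]
    return counts[np.arange(Q)[None, :], codes].sum(axis=1)


def infer_consensus_tree(gene_trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Species topology maximising the shared-quartet count.

    Exhaustive over all unrooted binary topologies for up to 8 tips; beyond
    that, a greedy distance start refined by NNI hill-climbing to a local
    optimum.  Multifurcating gene trees are accepted; their unresolved
    quartets simply contribute to no topology.
    """
    if not gene_trees:
        raise InputError("no gene trees given")
    labels = sorted({t for gt in gene_trees for t in tree_tips(gt)})
    n = len(labels)
    if n < 4:
        raise InputError(f"consensus inference needs >= 4 distinct tips, got {n}")
    counts = _quartet_counts(labels, gene_trees)
    if n <= 8:
        edge_lists, _, codes = _topology_bank(n)
        scores = _score_codes(codes, counts)
        best = int(np.argmax(scores))
        return _edges_to_tree(edge_lists[best], labels)
    return _greedy_nni_search(labels, gene_trees, counts)


def _greedy_nni_search(labels, gene_trees, counts) -> dendropy.Tree:
    n = len(labels)
    quartets = list(itertools.combinations(range(n), 4))

    def score_edges(edges) -> int:
        D = _edges_to_dist(edges, n)
        total = 0
        for qi, (a, b, c, d) in enumerate(quartets):
            code = _quartet_code(D, a, b, c, d)
            if code is not None:
                total += counts[qi, code]
        return total

    # greedy start: NJ on the average topological distance across gene trees
    sums = np.zeros((n, n))
    seen = np.zeros((n, n))
    index = {lab: i for i, lab in enumerate(labels)}
    for gt in gene_trees:
        g_labels, g_D = topo_distance_matrix(gt)
        gl = [index[lab] for lab in g_labels]
        for i, j in itertools.combinations(range(len(g_labels)), 2):
            sums[gl[i], gl[j]] += g_D[i, j]
            sums[gl[j], gl[i]] += g_D[i, j]
            seen[gl[i], gl[j]] += 1
            seen[gl[j], gl[i]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(seen > 0, sums / np.maximum(seen, 1), np.nan)
    fill = np.nanmax(avg) if np.isfinite(np.nanmax(avg)) else 1.0
    avg = np.where(np.isfinite(avg), avg, fill + 1.0)
    np.fill_diagonal(avg, 0.0)
    start = nj_tree(DistanceMatrix(taxa=list(labels), d=avg))
    edges = _tree_to_edge_list(start, labels)
    best_score = score_edges(edges)
    improved = True
    while improved:
        improved = False
        for alt in _nni_neighbors(edges, n):
            s = score_edges(alt)
            if s > best_score:
                edges, best_score, improved = alt, s, True
                break
    return _edges_to_tree(edges, labels)


def _tree_to_edge_list(tree: dendropy.Tree, labels: Sequence[str]) -> list[tuple[int, int]]:
    adj, leaves = _adjacency(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    ids: dict[int, int] = {}
    next_internal = len(labels)
    for node in adj:
        if node.is_leaf():
            ids[id(node)] = index[node.taxon.label]
    for node in adj:
        if id(node) not in ids:
            ids[id(node)] = next_internal
            next_internal += 1
    edges = set()
    for u in adj:
        for v in adj[u]:
            e = (ids[id(u)], ids[id(v)])
            edges.add(e if e[0] < e[1] else (e[1], e[0]))
    return sorted(edges)


def _nni_neighbors(edges: Sequence[tuple[int, int]], n: int):
    """The two NNI rearrangements of every internal edge."""
    adj: dict[int, set[int]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    for u, v in edges:
        if u < n or v < n:
            continue
        u_nb = [x for x in adj[u] if x != v]
        v_nb = [x for x in adj[v] if x != u]
        if len(u_nb) != 2 or len(v_nb) != 2:
            continue
        b = u_nb[1]
        for c in v_nb:
            swapped = []
            for e in edges:
                se = set(e)
                if se == {u, b}:
                    swapped.append(tuple(sorted((u, c))))
                elif se == {v, c}:
                    swapped.append(tuple(sorted((v, b))))
                else:
                    swapped.append(e)
            yield sorted(swapped)


# ---------------------------------------------------------------------------
# branch support
# ---------------------------------------------------------------------------


def default_tree_builder(msa: MarkerAlignment) -> dendropy.Tree:
    # Uncorrected p-distances: alignments reaching this stage are trimmed
    # to parsimony-informative sites, and log-corrections (poisson/jc69)
    # assume sites are an unbiased sample of the sequence — on
    # ascertainment-filtered columns they over-correct and distort
    # additivity, costing NJ short internal branches.
    return nj_tree(pairwise_distance(msa, "p"))


def _resample_columns(msa: MarkerAlignment, cols: np.ndarray) -> MarkerAlignment:
    rows = []
    for row in msa.rows:
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        rows.append(arr[cols].tobytes().decode())
    return MarkerAlignment(
        marker_id=msa.marker_id,
        taxa=list(msa.taxa),
        rows=rows,
        seqtype=msa.seqtype,
    )


def bootstrap_support(
    sm: Supermatrix,
    B: int = 100,
    seed: int = 0,
    builder: Callable[[MarkerAlignment], dendropy.Tree] | None = None,
) -> dendropy.Tree:
    """Nonparametric bootstrap: resample supermatrix columns with
    replacement B times and annotate each internal branch of the point
    tree with the percentage of replicate trees containing its split."""
    if B < 1:
        raise InputError("B must be >= 1")
    builder = builder or default_tree_builder
    msa = sm.alignment
    point = builder(msa)
    rng = np.random.default_rng(seed)
    split_counts: dict[frozenset, int] = {}
    for _ in range(B):
        cols = rng.integers(0, msa.width, msa.width)
        rep = builder(_resample_columns(msa, cols))
        for split in bipartitions(rep):
            split_counts[split] = split_counts.get(split, 0) + 1
    annotate_splits(point, {s: 100.0 * c / B for s, c in split_counts.items()}, default=0.0)
    return point


def annotate_splits(tree: dendropy.Tree, values: Mapping[frozenset, float | None], default=None) -> None:
    """Attach per-split values as internal node labels (in place)."""
    tips = tree_tips(tree)
    ref, all_tips = tips[0], frozenset(tips)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if not (1 < len(side) < len(tips) - 1):
            continue
        canon = side if ref not in side else all_tips - side
        val = values.get(canon, default)
        node.label = "" if val is None else f"{val:.4g}"


def site_concordance(
    tree: dendropy.Tree,
    sm: Supermatrix,
    q: int = 100,
    seed: int = 0,
) -> dict[frozenset, float | None]:
    """Site concordance factor per internal branch.

    For each internal branch, ``q`` quartets are sampled with one tip from
    each of the four subtrees surrounding the branch.  A site is decisive
    for a quartet when its four residues are present and fall into two
    states of two rows each; it supports the branch when the state pairing
    matches the branch's own split.  The branch sCF is the mean percentage
    of supporting decisive sites over quartets; branches with no decisive
    site in any sampled quartet are reported as None.
    """
    if q < 1:
        raise InputError("q must be >= 1")
    msa = sm.alignment
    taxa_index = {t: i for i, t in enumerate(msa.taxa)}
    tips = tree_tips(tree)
    if sorted(taxa_index) != tips:
        raise InputError("tree tips and supermatrix taxa differ")
    alphabet = "ACDEFGHIKLMNPQRSTVWY" if msa.seqtype == "pep" else "ACGT"
    codes = residue_codes(msa.rows, alphabet)
    rng = np.random.default_rng(seed)
    adj, leaves = _adjacency(tree)
    ref, all_tips = tips[0], frozenset(tips)
    out: dict[frozenset, float | None] = {}
    seen_edges = set()
    for u in adj:
        for v in adj[u]:
            key = (id(u), id(v)) if id(u) < id(v) else (id(v), id(u))
            if key in seen_edges or u.is_leaf() or v.is_leaf():
                continue
            seen_edges.add(key)
            u_nb = [x for x in adj[u] if x is not v]
            v_nb = [x for x in adj[v] if x is not u]
            if len(u_nb) != 2 or len(v_nb) != 2:
                continue  # polytomy: sCF undefined for this branch here
            groups = [sorted(_tips_beyond(adj, nb, u, leaves)) for nb in u_nb]
            groups += [sorted(_tips_beyond(adj, nb, v, leaves)) for nb in v_nb]
            side = frozenset(groups[0]) | frozenset(groups[1])
            canon = side if ref not in side else all_tips - side
            vals = []
            for _ in range(q):
                quartet = [g[rng.integers(0, len(g))] for g in groups]
                rows = codes[[taxa_index[t] for t in quartet]]
                present = np.all(rows >= 0, axis=0)
                r = rows[:, present]
                ab = r[0] == r[1]
                cd = r[2] == r[3]
                ac = r[0] == r[2]
                ad = r[0] == r[3]
                bc = r[1] == r[2]
                bd = r[1] == r[3]
                concord = ab & cd & ~ac
                disc1 = ac & bd & ~ab
                disc2 = ad & bc & ~ab
                decisive = concord | disc1 | disc2
                nd = int(decisive.sum())
                if nd > 0:
                    vals.append(100.0 * float(concord.sum()) / nd)
            out[canon] = float(np.mean(vals)) if vals else None
    return out
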