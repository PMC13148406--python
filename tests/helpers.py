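"""Shared test utilities: independent oracles and random generators.

The oracles here deliberately re-derive quantities by brute force
(path enumeration, all-quartets comparison, explicit column classification)
so the fast implementations in the package are checked against independent
code paths.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np

from markerphylo.profile_hmm import ProfileHMM, encode_sequence


def random_profile(rng: np.random.Generator, M: int, alphabet: str = "dna4") -> ProfileHMM:
    """A random, strictly positive, valid profile HMM."""
    K = 4 if alphabet == "dna4" else 20

    def simplex(n):
        x = rng.random(n) + 0.05
        return x / x.sum()

    match = np.vstack([simplex(K) for _ in range(M)])
    insert = np.vstack([simplex(K) for _ in range(M)])
    trans = np.zeros((M + 1, 7))
    for r in range(1, M):
        m3, i2, d2 = simplex(3), simplex(2), simplex(2)
        trans[r] = [m3[0], m3[1], m3[2], i2[0], i2[1], d2[0], d2[1]]
    bm = simplex(2)
    trans[0] = [bm[0], 0.0, bm[1], 1, 0, 1, 0]
    trans[M] = [1, 0, 0, 1, 0, 1, 0]
    model = ProfileHMM("toy", alphabet, match, insert, trans, np.full(K, 1.0 / K))
    model.validate()
    return model


def enumerate_glocal_scores(model: ProfileHMM, seq: str) -> tuple[float, float]:
    """Brute-force (viterbi, forward) bit scores over all glocal state paths."""
    codes = encode_sequence(seq, model.alphabet)
    L, M = len(codes), model.model_length
    t = model.transitions
    lnull = np.log(model.null_freq)
    lm = np.log(np.where(model.match_emission > 0, model.match_emission, 1e-300)) - lnull
    li = np.log(np.where(model.insert_emission > 0, model.insert_emission, 1e-300)) - lnull
    paths: list[float] = []

    def rec(state: str, k: int, pos: int, j: int, logp: float) -> None:
        if k == M:
            if state == "M":
                if t[M, 0] <= 0:
                    return
                logp += math.log(t[M, 0])
            elif state == "D":
                if t[M, 5] <= 0:
                    return
                logp += math.log(t[M, 5])
            else:
                return
            if pos == j:
                paths.append(logp)
            return
        row = t[k]
        if state == "M":
            opts = [("M", row[0]), ("I", row[1]), ("D", row[2])]
        elif state == "I":
            opts = [("M", row[3]), ("I", row[4])]
        else:
            opts = [("M", row[5]), ("D", row[6])]
        for nxt, p in opts:
            if p <= 0:
                continue
            lp = logp + math.log(p)
            if nxt == "M" and pos < j:
                rec("M", k + 1, pos + 1, j, lp + lm[k, codes[pos]])
            elif nxt == "I" and pos < j:
                rec("I", k, pos + 1, j, lp + li[k - 1, codes[pos]])
            elif nxt == "D":
                rec("D", k + 1, pos, j, lp)

    for i in range(L + 1):
        for j in range(i, L + 1):
            if t[0, 0] > 0 and j > i:
                rec("M", 1, i + 1, j, math.log(t[0, 0]) + lm[0, codes[i]])
            if t[0, 2] > 0:
                rec("D", 1, i, j, math.log(t[0, 2]))
    if not paths:
        return -math.inf, -math.inf
    arr = np.array(paths)
    ln2 = math.log(2.0)
    return float(arr.max()) / ln2, float(np.logaddexp.reduce(arr)) / ln2


# ---------------------------------------------------------------------------
# random trees and additive matrices
# ---------------------------------------------------------------------------


def random_binary_newick(rng: np.random.Generator, labels: list[str],
                         min_len: float = 0.1, max_len: float = 1.0) -> str:
    """Random unrooted binary topology with uniform branch lengths."""
    # random pair joins on newick fragments (independent of package code)
    frags = {i: labels[i] for i in range(len(labels))}
    active = list(range(len(labels)))
    nxt = len(labels)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la = rng.uniform(min_len, max_len)
        lb = rng.uniform(min_len, max_len)
        frags[nxt] = f"({frags[a]}:{la!r},{frags[b]}:{lb!r})"
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    a, b, c = active
    parts = [f"{frags[x]}:{rng.uniform(min_len, max_len)!r}" for x in (a, b, c)]
    return f"({parts[0]},{parts[1]},{parts[2]});"


def tree_path_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf patristic distances via dendropy (independent route)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return labels, D


def split_length_map(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map each split (canonical side, incl. trivial) to its branch length,
    merging the two edges of a bifurcating root."""
    tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref, all_tips = tips[0], frozenset(tips)
    root = tree.seed_node
    rc = root.child_nodes()
    out: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        canon = side if ref not in side else all_tips - side
        if len(canon) == 0 or canon == all_tips:
            continue
        out[canon] = out.get(canon, 0.0) + (node.edge.length or 0.0)
    return out


def induced_quartet_split(tree_splits: set[frozenset], all_tips: frozenset,
                          a: str, b: str, c: str, d: str) -> frozenset | None:
    """Which pairing of {a,b,c,d} the tree induces, via split separation
    (independent of any distance computation).  Returns the pair containing
    ``a`` as a frozenset, or None if unresolved."""
    quartet = {a, b, c, d}
    for split in tree_splits:
        other = all_tips - split
        inside = quartet & split
        outside = quartet & other
        if len(inside) == 2 and len(outside) == 2:
            return frozenset(inside) if a in inside else frozenset(outside)
    return None


def all_topologies_newick(labels: list[str]) -> list[str]:
    """Every unrooted binary topology as a newick string (no lengths).

    Independent enumeration (string surgery) used as the exhaustive oracle
    for the consensus search.
    """
    assert len(labels) >= 3
    trees = [f"({labels[0]},{labels[1]},{labels[2]});"]
    for lab in labels[3:]:
        new_trees = []
        for nwk in trees:
            # insert the new leaf on every edge = next to every taxon or clade
            positions = _insertable_spans(nwk)
            for start, end in positions:
                sub = nwk[start:end]
                new_trees.append(nwk[:start] + f"({sub},{lab})" + nwk[end:])
        trees = new_trees
    return trees


def _insertable_spans(nwk: str) -> list[tuple[int, int]]:
    """Spans of every subtree (leaf or parenthesised clade) except the
    outermost, i.e. one span per edge of the unrooted tree."""
    body = nwk
    spans = []
    i = 0
    n = len(body)
    depth = 0
    while i < n:
        ch = body[i]
        if ch == "(":
            if depth >= 1:
                # find matching close
                d = 0
                j = i
                while j < n:
                    if body[j] == "(":
                        d += 1
                    elif body[j] == ")":
                        d -= 1
                        if d == 0:
                            break
                    j += 1
                spans.append((i, j + 1))
            depth += 1
            i += 1
        elif ch == ")":
            depth -= 1
            i += 1
        elif ch in ",;":
            i += 1
        else:
            j = i
            while j < n and body[j] not in "(),;":
                j += 1
            if depth >= 1:
                spans.append((i, j))
            i = j
    # drop spans nested inside another span only when they equal the whole
    # outer clade? No: every span is a distinct edge; keep all.
    return spans
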