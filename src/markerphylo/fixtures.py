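"""Synthetic study systems: known trees, evolved marker families, proteomes.

Everything the pipeline consumes can be generated here with a known ground
truth and no downloads: a Yule species tree, per-marker gene families
evolved along it under an equal-rate 20-state substitution process (the
protein analogue of Jukes–Cantor), per-sample proteome FASTA files salted
with random decoy sequences and, optionally, injected near-identical
paralogs, plus an HMMER3 marker database built from the true alignments.

Every artifact is a pure function of a :class:`SimulationSpec`; the seed
fixes all draws.  The equal-rate model trades realism (no indels, no
across-site rate variation, uniform composition) for closed-form
checkability and speed; what that implies for interpreting pipeline tests
is spelled out in the package docs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .alignment import MarkerAlignment
from .errors import InputError
from .informativeness import dendropy_safe
from .profile_hmm import AMINO20, build_hmm, write_hmm

#: default mean and floor for exponential branch lengths (substitutions/site
#: at rate 1); the floor keeps internal branches away from the degenerate
#: zero-length regime no real species tree occupies
BRANCH_MEAN = 0.05
BRANCH_FLOOR = 0.01

_CODONS_FOR_AA: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS_FOR_AA:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS_FOR_AA.setdefault(aa, []).append(codon)
        for aa in _CODONS_FOR_AA:
            _CODONS_FOR_AA[aa].sort()
    return _CODONS_FOR_AA


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    n_taxa: int = 8
    n_markers: int = 50
    marker_length: int = 200
    substitution_rate: float = 1.0  # expected substitutions/site per unit branch length
    n_decoys: int = 5
    paralogs: tuple[tuple[str, str], ...] = ()  # (sample, marker) pairs to duplicate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_markers < 1 or self.marker_length < 1:
            raise InputError("n_taxa, n_markers and marker_length must be positive (n_taxa >= 2)")
        if self.n_decoys < 0 or self.substitution_rate < 0:
            raise InputError("n_decoys and substitution_rate must be non-negative")

    def taxa(self) -> list[str]:
        return [f"t{i + 1}" for i in range(self.n_taxa)]

    def marker_ids(self) -> list[str]:
        return [f"mk{i + 1:04d}" for i in range(self.n_markers)]


def simulate_species_tree(
    n_taxa: int,
    seed: int,
    branch_mean: float = BRANCH_MEAN,
    branch_floor: float = BRANCH_FLOOR,
) -> dendropy.Tree:
    """Yule (pure-birth) tree: at each step a uniformly chosen extant
    lineage splits; every branch gets a floor-shifted exponential length."""
    if n_taxa < 2:
        raise InputError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("children", "length", "label")

        def __init__(self):
            self.children, self.length, self.label = [], 0.0, None

    root = _N()
    tips = [root]
    while len(tips) < n_taxa:
        idx = int(rng.integers(0, len(tips)))
        parent = tips.pop(idx)
        kids = [_N(), _N()]
        parent.children = kids
        tips.extend(kids)
    for i, tip in enumerate(tips):
        tip.label = f"t{i + 1}"

    def draw_len() -> float:
        return branch_floor + float(rng.exponential(max(branch_mean - branch_floor, 1e-9)))

    def render(node: _N) -> str:
        if not node.children:
            return f"{dendropy_safe(node.label)}:{draw_len()!r}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{draw_len()!r}"

    newick = render(root).rsplit(":", 1)[0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def _substitution_prob(rate: float, branch_length: float, k: int = 20) -> float:
    """Equal-rate K-state model: probability a site shows a different state
    after a branch, p(b) = ((K-1)/K) * (1 - exp(-K*rate*b/(K-1)))."""
    return (k - 1) / k * (1.0 - math.exp(-k * rate * branch_length / (k - 1)))


def evolve_marker_alignments(tree: dendropy.Tree, spec: SimulationSpec) -> list[MarkerAlignment]:
    """Evolve one gap-free alignment per marker along the tree.

    The root sequence is drawn from the (uniform) null frequencies; along
    each branch each site substitutes, independently, to a uniformly chosen
    different residue with the closed-form probability above.  Columns are
    homologous by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    K = len(AMINO20)
    L = spec.marker_length
    out: list[MarkerAlignment] = []
    aa = np.frombuffer(AMINO20.encode(), dtype=np.uint8)
    for marker in spec.marker_ids():
        root_seq = rng.integers(0, K, L)
        rows: dict[str, np.ndarray] = {}

        def walk(node, seq):
            for child in node.child_nodes():
                b = child.edge.length or 0.0
                p = _substitution_prob(spec.substitution_rate, b, K)
                mask = rng.random(L) < p
                child_seq = seq.copy()
                n_mut = int(mask.sum())
                if n_mut:
                    child_seq[mask] = (child_seq[mask] + rng.integers(1, K, n_mut)) % K
                if child.is_leaf():
                    rows[child.taxon.label] = child_seq
                else:
                    walk(child, child_seq)
            if node is tree.seed_node and node.is_leaf():  # pragma: no cover
                rows[node.taxon.label] = seq

        walk(tree.seed_node, root_seq)
        taxa = sorted(rows)
        out.append(MarkerAlignment(
            marker_id=marker,
            taxa=taxa,
            rows=[aa[rows[t]].tobytes().decode() for t in taxa],
            seqtype="pep",
        ))
    return out


def _mutate_sequence(seq: str, rng: np.random.Generator, rate: float = 0.01) -> str:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lookup = {ord(c): i for i, c in enumerate(AMINO20)}
    idx = np.array([lookup[c] for c in codes])
    mask = rng.random(len(seq)) < rate
    n = int(mask.sum())
    if n:
        idx[mask] = (idx[mask] + rng.integers(1, 20, n)) % 20
    aa = np.frombuffer(AMINO20.encode(), dtype=np.uint8)
    return aa[idx].tobytes().decode()


def emit_sample_proteomes(
    alignments: list[MarkerAlignment],
    spec: SimulationSpec,
    out_dir: str | Path,
    *,
    cds: bool = False,
) -> dict[str, Path]:
    """Write one FASTA per sample: its marker genes (shuffled order, opaque
    ids) plus ``n_decoys`` null-background decoys, plus a near-identical
    duplicate (1% point mutations) for each requested paralog.

    With ``cds=True`` the file holds nucleotide coding sequences obtained by
    back-translating each protein with uniformly random synonymous codons
    (suffix ``.fna`` instead of ``.faa``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # separate streams: sequence content must be identical between the
    # peptide and back-translated (cds=True) renderings of one spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    rng_codon = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    taxa = spec.taxa()
    aa = np.frombuffer(AMINO20.encode(), dtype=np.uint8)
    table = _codon_table()
    paths: dict[str, Path] = {}
    for taxon in taxa:
        records: list[tuple[str, str]] = []  # (kind:marker, peptide)
        for msa in alignments:
            if taxon in msa.taxa:
                records.append((msa.marker_id, msa.row(taxon)))
        for _ in range(spec.n_decoys):
            decoy = aa[rng.integers(0, 20, spec.marker_length)].tobytes().decode()
            records.append(("decoy", decoy))
        for sample, marker in spec.paralogs:
            if sample == taxon:
                src = next((seq for mid, seq in records if mid == marker), None)
                if src is None:
                    raise InputError(f"paralog requested for absent marker {marker!r} in {taxon!r}")
                records.append((marker + "_paralog", _mutate_sequence(src, rng)))
        order = rng.permutation(len(records))
        suffix = ".fna" if cds else ".faa"
        path = out_dir / f"{taxon}{suffix}"
        with open(path, "w") as fh:
            for j, ridx in enumerate(order):
                _, pep = records[ridx]
                seq_id = f"g_{rng.integers(0, 10**9):09d}"
                if cds:
                    codons = [table[c][rng_codon.integers(0, len(table[c]))] for c in pep]
                    fh.write(f">{seq_id}\n{''.join(codons)}\n")
                else:
                    fh.write(f">{seq_id}\n{pep}\n")
        paths[taxon] = path
    return paths


def build_marker_db(
    alignments: list[MarkerAlignment],
    pseudocount: float = 1.0,
    out_dir: str | Path = "markers",
) -> Path:
    """Write one HMMER3 profile per marker plus a digest manifest.

    The profiles are built from the *true* simulated alignments — the local
    stand-in for a curated single-copy marker database.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}
    for msa in alignments:
        model = build_hmm(msa, pseudocount, alphabet="amino20")
        path = out_dir / f"{msa.marker_id}.hmm"
        write_hmm(model, path)
        digests[msa.marker_id] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "markers": digests,
        "marker_set_digest": hashlib.sha256(
            json.dumps(digests, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir


def simulate_dataset(spec: SimulationSpec, out_dir: str | Path, *, cds: bool = False) -> dict:
    """One-call fixture: tree + alignments + proteomes + marker db.

    Returns a dict with the true tree, the alignments, and the on-disk
    layout (samples/, markers/, true_tree.nwk).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree = simulate_species_tree(spec.n_taxa, spec.seed)
    alignments = evolve_marker_alignments(tree, spec)
    samples = emit_sample_proteomes(alignments, spec, out_dir / "samples", cds=cds)
    markers = build_marker_db(alignments, 1.0, out_dir / "markers")
    tree_path = out_dir / "true_tree.nwk"
    tree_path.write_text(tree.as_string(schema="newick", suppress_rooting=True))
    return {
        "tree": tree,
        "alignments": alignments,
        "samples": samples,
        "marker_dir": markers,
        "tree_path": tree_path,
    }
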