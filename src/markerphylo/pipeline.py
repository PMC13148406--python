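"""Stage orchestration: align -> filter -> tree, with checkpoint wiring.

Each stage is a pure function of (input files, :class:`RunConfig`): two
runs with the same configuration and inputs produce identical outputs.
The align stage is checkpointed — sample files are identified by content
hash, so reruns only search what actually changed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import alignment as aln
from . import informativeness as info
from . import orthology as orth
from . import profile_hmm as phmm
from . import speciestree as st
from .errors import InputError, UnsatisfiableRunError

log = logging.getLogger("markerphylo")

MIN_SAMPLES = 4

#: distance model for gene/species tree estimation.  Trimmed alignments
#: contain only parsimony-informative sites, and log-corrections assume an
#: unbiased site sample — they over-correct on ascertainment-filtered
#: columns and cost NJ short internal branches, so topology estimation
#: uses raw mismatch fractions.
TREE_DISTANCE_MODEL = "p"


@dataclass
class RunConfig:
    marker_dir: Path
    inputs: list[Path]
    output_dir: Path
    seqtype: str = "pep"  # "pep" | "cds"
    threshold: float = 10.0
    min_taxa: int = 4
    top_n: int | None = None  # None = keep all markers (filtering is opt-in)
    mode: str = "consensus"  # "consensus" | "concat"
    threads: int = 1
    seed: int = 0
    checkpoint: Path | None = None
    force: bool = False
    bootstrap_replicates: int = 100
    scf_quartets: int = 100
    prefilter: bool = True

    def __post_init__(self) -> None:
        self.marker_dir = Path(self.marker_dir)
        self.inputs = [Path(p) for p in self.inputs]
        self.output_dir = Path(self.output_dir)
        if self.seqtype not in ("pep", "cds"):
            raise InputError(f"seqtype must be 'pep' or 'cds', got {self.seqtype!r}")
        if self.mode not in ("consensus", "concat"):
            raise InputError(f"mode must be 'consensus' or 'concat', got {self.mode!r}")
        if self.checkpoint is None:
            self.checkpoint = self.output_dir / "checkpoint.jsonl"
        else:
            self.checkpoint = Path(self.checkpoint)


def load_marker_set(marker_dir: str | Path) -> tuple[list[phmm.ProfileHMM], str]:
    """Read every ``*.hmm`` in a directory; returns (models, set digest)."""
    import hashlib

    marker_dir = Path(marker_dir)
    paths = sorted(marker_dir.glob("*.hmm"))
    if not paths:
        raise InputError(f"no .hmm files in marker directory {marker_dir}")
    models: list[phmm.ProfileHMM] = []
    h = hashlib.sha256()
    for p in paths:
        models.extend(phmm.read_hmm(p))
        h.update(orth.hash_file(p).encode())
    ids = [m.marker_id for m in models]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate marker ids in {marker_dir}")
    return models, h.hexdigest()


def _translate_cds(seq: str) -> str:
    from Bio.Seq import Seq

    nt = seq.upper().replace("U", "T")
    nt = nt[: len(nt) - len(nt) % 3]
    pep = str(Seq(nt).translate())
    if pep.endswith("*"):
        pep = pep[:-1]
    return pep


def run_align(cfg: RunConfig) -> tuple[dict[str, aln.MarkerAlignment], orth.Checkpoint]:
    """Search, single-copy filter, extract, profile-align and trim.

    Returns the per-marker trimmed alignments and the updated checkpoint.
    Requires at least four input samples.
    """
    if len(cfg.inputs) < MIN_SAMPLES:
        raise InputError(
            f"at least {MIN_SAMPLES} samples are required for species-tree "
            f"inference; got {len(cfg.inputs)}"
        )
    labels = [p.stem for p in cfg.inputs]
    if len(set(labels)) != len(labels):
        raise InputError("duplicate sample labels (file stems) among inputs")
    cfg.output_dir.mkdir(parents=True, exist_ok=True)

    markers, set_digest = load_marker_set(cfg.marker_dir)
    fingerprint = orth.params_fingerprint(set_digest, cfg.threshold, cfg.seqtype)

    ckpt = None
    if cfg.checkpoint.exists():
        ckpt = orth.Checkpoint.load(cfg.checkpoint)
    sample_hashes = {label: orth.hash_file(p) for label, p in zip(labels, cfg.inputs)}
    diff = orth.checkpoint_diff(ckpt, sample_hashes, fingerprint, force=cfg.force)
    if ckpt is None or (cfg.force and ckpt.params_fingerprint != fingerprint):
        ckpt = orth.Checkpoint(params_fingerprint=fingerprint)

    plan = phmm.plan_search_workers(max(cfg.threads, 1))
    log.info(
        "search plan: %d instance(s) x %d core(s); %d to search, %d reusable, %d removed",
        plan.n_instances, plan.cores_per_instance,
        len(diff.to_search), len(diff.reusable), len(diff.removed),
    )

    hash_to_label = {h: lab for lab, h in sample_hashes.items()}
    hash_to_path = {sample_hashes[lab]: p for lab, p in zip(labels, cfg.inputs)}
    threshold = phmm.ScoreThreshold(floor_bits=cfg.threshold)

    new_entries: dict[str, tuple[str, list[phmm.SearchHit]]] = {}
    for chash in diff.to_search:
        label, path = hash_to_label[chash], hash_to_path[chash]
        search_path = path
        if cfg.seqtype == "cds":
            search_path = cfg.output_dir / f"{label}.translated.faa"
            with open(search_path, "w") as fh:
                for rid, seq in phmm.read_fasta(path):
                    pep = _translate_cds(seq)
                    if pep:
                        fh.write(f">{rid}\n{pep}\n")
        hits = phmm.search_sample(
            markers, search_path, threshold, sample_id=label, prefilter=cfg.prefilter
        )
        new_entries[chash] = (label, hits)
    ckpt = orth.merge_checkpoint(ckpt, new_entries)
    ckpt.save(cfg.checkpoint)

    table = orth.assemble_hit_table(ckpt, {h: lab for lab, h in sample_hashes.items()})
    table.to_tsv(cfg.output_dir / "hits.tsv")
    single = orth.enforce_single_copy(table)
    dropped = {k for k in table.cells if k not in single.cells}
    for marker, sample in sorted(dropped):
        log.info("excluded %s for marker %s (multiple hits)", sample, marker)
    kept_markers = orth.select_markers(single, cfg.min_taxa)
    log.info("kept %d/%d markers with >= %d samples", len(kept_markers), len(table.markers()), cfg.min_taxa)
    single.cells = {k: v for k, v in single.cells.items() if k[0] in kept_markers}

    # extract + align + trim
    if cfg.seqtype == "cds":
        pep_fastas = {lab: cfg.output_dir / f"{lab}.translated.faa" for lab in labels}
        for lab, p in zip(labels, cfg.inputs):
            if not pep_fastas[lab].exists():  # reused from checkpoint: retranslate
                with open(pep_fastas[lab], "w") as fh:
                    for rid, seq in phmm.read_fasta(p):
                        pep = _translate_cds(seq)
                        if pep:
                            fh.write(f">{rid}\n{pep}\n")
        seqs_by_marker = aln.extract_hit_sequences(pep_fastas, single)
        cds_by_marker = _extract_cds(dict(zip(labels, cfg.inputs)), single)
    else:
        seqs_by_marker = aln.extract_hit_sequences(dict(zip(labels, cfg.inputs)), single)
        cds_by_marker = {}

    model_by_id = {m.marker_id: m for m in markers}
    msa_dir = cfg.output_dir / "alignments"
    msa_dir.mkdir(exist_ok=True)
    trimmed: dict[str, aln.MarkerAlignment] = {}
    kept_cols_rows = []
    for marker in kept_markers:
        seqs = seqs_by_marker.get(marker, [])
        if len(seqs) < 2:
            continue
        msa = aln.align_to_profile(model_by_id[marker], seqs)
        msa.to_fasta(msa_dir / f"{marker}.aln.faa")
        trim, kept = aln.trim_parsimony_informative(msa)
        if cfg.seqtype == "cds":
            # thread the codons that actually sit behind each aligned residue
            # (insert/flank residues were discarded by the profile alignment)
            eff_cds: dict[str, str] = {}
            for taxon, idxs in zip(msa.taxa, msa.residue_index):
                nt = cds_by_marker[marker][taxon].upper().replace("U", "T")
                eff_cds[taxon] = "".join(nt[3 * i : 3 * i + 3] for i in idxs if i >= 0)
            codon_full = aln.backthread_codons(msa, eff_cds)
            trim = aln.MarkerAlignment(
                marker_id=marker,
                taxa=list(codon_full.taxa),
                rows=["".join(r[3 * (j - 1) : 3 * j] for j in kept) for r in codon_full.rows],
                seqtype="cds-codon",
                column_source=list(kept),
            )
        if trim.width == 0:
            log.info("marker %s has no parsimony-informative sites; flagged uninformative", marker)
            continue
        suffix = ".trim.fna" if cfg.seqtype == "cds" else ".trim.faa"
        trim.to_fasta(msa_dir / f"{marker}{suffix}")
        kept_cols_rows.append((marker, ",".join(map(str, kept))))
        trimmed[marker] = trim
    if not trimmed:
        raise UnsatisfiableRunError("no marker produced an informative trimmed alignment")
    with open(cfg.output_dir / "kept_columns.tsv", "w") as fh:
        fh.write("marker\tkept_columns\n")
        for marker, cols in kept_cols_rows:
            fh.write(f"{marker}\t{cols}\n")
    return trimmed, ckpt


def _extract_cds(sample_fastas: dict[str, Path], hits: orth.HitTable) -> dict[str, dict[str, str]]:
    from pyfaidx import Fasta

    indexes = {lab: Fasta(str(p)) for lab, p in sample_fastas.items()}
    out: dict[str, dict[str, str]] = {}
    for (marker, sample), cell in hits.cells.items():
        for hit in cell:
            out.setdefault(marker, {})[sample] = str(indexes[sample][hit.seq_id][:]).upper()
    return out


def run_filter(
    cfg: RunConfig, msas: dict[str, aln.MarkerAlignment]
) -> tuple[list[str], pd.DataFrame]:
    """Score every marker by treeness/RCV and keep the top n (default all)."""
    model = TREE_DISTANCE_MODEL
    scores = []
    tree_dir = cfg.output_dir / "gene_trees"
    tree_dir.mkdir(parents=True, exist_ok=True)
    for marker, msa in sorted(msas.items()):
        if msa.n_taxa < 3:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gtree = info.nj_tree(info.pairwise_distance(msa, model))
        st.write_newick(gtree, tree_dir / f"{marker}.nwk")
        scores.append(info.score_marker(msa, model, gene_tree=gtree))
    ranked = info.rank_markers(scores, cfg.top_n)
    df = pd.DataFrame(
        [{"marker": s.marker_id, "treeness": s.treeness, "rcv": s.rcv, "score": s.score}
         for s in scores]
    ).sort_values(["score", "marker"], ascending=[False, True], ignore_index=True)
    df["rank"] = range(1, len(df) + 1)
    df.to_csv(cfg.output_dir / "marker_scores.tsv", sep="\t", index=False)
    return ranked, df


def run_tree(cfg: RunConfig, msas: dict[str, aln.MarkerAlignment]):
    """Infer the species tree from the (possibly filtered) marker set."""
    taxa = sorted({t for m in msas.values() for t in m.taxa})
    if len(taxa) < 4:
        raise UnsatisfiableRunError(f"species-tree inference needs >= 4 taxa, got {len(taxa)}")
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    model = TREE_DISTANCE_MODEL
    if cfg.mode == "consensus":
        gene_trees = []
        for marker, msa in sorted(msas.items()):
            if msa.n_taxa < 3:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gene_trees.append(info.nj_tree(info.pairwise_distance(msa, model)))
        tree = st.infer_consensus_tree(gene_trees)
        st.write_newick(tree, cfg.output_dir / "species_tree.nwk")
        return tree
    # concatenation
    sm = st.concat_supermatrix(list(msas.values()), taxa)
    suffix = "fna" if cfg.seqtype == "cds" else "faa"
    sm.alignment.to_fasta(cfg.output_dir / f"supermatrix.{suffix}")
    sm.write_partitions(cfg.output_dir / "supermatrix.partitions")
    tree = st.bootstrap_support(sm, B=cfg.bootstrap_replicates, seed=cfg.seed)
    scf = st.site_concordance(tree, sm, q=cfg.scf_quartets, seed=cfg.seed + 1)
    _write_support_report(tree, scf, cfg.output_dir / "branch_support.tsv")
    st.write_newick(tree, cfg.output_dir / "species_tree.nwk")
    return tree


def _write_support_report(tree, scf: dict, path: Path) -> None:
    tips = st.tree_tips(tree)
    ref, all_tips = tips[0], frozenset(tips)
    lines = ["split\tbootstrap\tscf"]
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if not (1 < len(side) < len(tips) - 1):
            continue
        canon = side if ref not in side else all_tips - side
        scf_val = scf.get(canon)
        lines.append(
            f"{'|'.join(sorted(canon))}\t{node.label or ''}\t"
            f"{'' if scf_val is None else f'{scf_val:.2f}'}"
        )
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: RunConfig):
    """align -> filter -> tree in one call; returns the species tree."""
    msas, _ = run_align(cfg)
    ranked, _ = run_filter(cfg, msas)
    subset = {m: msas[m] for m in ranked}
    return run_tree(cfg, subset)
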