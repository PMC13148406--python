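"""Marker alignments: extraction, profile alignment, trimming, codon back-threading.

Sequences that survive single-copy filtering are threaded onto their
marker's profile via the Viterbi path, which yields a fixed-width multiple
alignment in *match-state coordinates*: column k holds whatever each
sequence emitted at match state k (or a gap where the path deleted the
state), and insert-state residues are discarded.  Every marker alignment
therefore has width M regardless of input sequence lengths.

Trimming keeps only parsimony-informative columns: at least two distinct
non-gap, non-ambiguous states, each present in at least two rows.
Ambiguity codes (X/B/Z for peptides, anything outside ACGT for
nucleotides) count as missing — the conservative reading of parsimony
informativeness.

Internally columns are 0-based; everything user-facing (kept-column
reports, partition files) is 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .errors import InputError, ValidationError
from .profile_hmm import AMINO20, DNA4, ProfileHMM, viterbi

GAP_CHARS = "-."
PEP_AMBIGUOUS = set("XBZJUO*")


def residue_codes(rows, symbols: str):
    """Encode rows of residues as an int8 matrix; -1 marks gaps/ambiguity."""
    import numpy as np

    table = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate(symbols):
        table[ord(c)] = i
        table[ord(c.lower())] = i
    return np.vstack([table[np.frombuffer(r.encode(), dtype=np.uint8)] for r in rows])

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass
class MarkerAlignment:
    """Fixed-width MSA for one marker.

    ``column_source`` records, per column, the 1-based match-state index the
    column came from (surviving trimming as the original indices).
    """

    marker_id: str
    taxa: list[str]
    rows: list[str]
    seqtype: str = "pep"  # "pep" | "cds-codon"
    column_source: list[int] | None = None
    #: per row, the 0-based residue position in the original (unaligned)
    #: sequence behind each column, -1 at gaps; set by align_to_profile
    residue_index: list[list[int]] | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValidationError(f"{self.marker_id}: {len(self.taxa)} taxa but {len(self.rows)} rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError(f"{self.marker_id}: duplicate taxon labels")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValidationError(f"{self.marker_id}: unequal row lengths {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for taxon, row in zip(self.taxa, self.rows):
                fh.write(f">{taxon}\n{row}\n")

    @classmethod
    def from_fasta(cls, path: str | Path, marker_id: str | None = None, seqtype: str = "pep") -> "MarkerAlignment":
        from .profile_hmm import read_fasta

        records = read_fasta(path)
        return cls(
            marker_id=marker_id or Path(path).stem,
            taxa=[rid for rid, _ in records],
            rows=[seq for _, seq in records],
            seqtype=seqtype,
        )


def extract_hit_sequences(
    sample_fastas: Mapping[str, str | Path],
    hits,
) -> dict[str, list[tuple[str, str]]]:
    """Pull each surviving hit's sequence out of its sample file.

    ``sample_fastas`` maps sample label -> FASTA path; ``hits`` is a
    single-copy :class:`~markerphylo.orthology.HitTable`.  Returns
    marker_id -> list of (sample label, sequence), relabelled by sample.
    """
    from pyfaidx import Fasta

    labels = list(sample_fastas)
    if len(set(labels)) != len(labels):
        raise InputError("duplicate sample labels")
    indexes: dict[str, Fasta] = {}
    for label, path in sample_fastas.items():
        indexes[label] = Fasta(str(path))
    out: dict[str, list[tuple[str, str]]] = {}
    for (marker, sample), cell in sorted(hits.cells.items()):
        if sample not in indexes:
            raise InputError(f"hit for unknown sample {sample!r}")
        for hit in cell:
            idx = indexes[sample]
            if hit.seq_id not in idx:
                raise InputError(
                    f"sequence {hit.seq_id!r} (marker {marker}) not found in sample {sample!r}"
                )
            out.setdefault(marker, []).append((sample, str(idx[hit.seq_id][:]).upper()))
    return out


def align_to_profile(model: ProfileHMM, seqs: Sequence[tuple[str, str]]) -> MarkerAlignment:
    """Thread each sequence through its Viterbi path against the profile.

    Column k of the result holds the residue emitted at match state k, or
    ``-`` where the path used D_k; insert-state and flanking residues are
    discarded.  Sequences that fail to align (score -inf) are dropped with
    a warning.
    """
    if len(seqs) < 2:
        raise InputError("profile alignment needs at least two sequences")
    M = model.model_length
    taxa: list[str] = []
    rows: list[str] = []
    indices: list[list[int]] = []
    for label, seq in seqs:
        bits, path = viterbi(model, seq)
        if bits == float("-inf"):
            warnings.warn(f"sequence {label!r} failed to align to {model.marker_id}; dropped")
            continue
        row = ["-"] * M
        idx = [-1] * M
        pos = path.seq_start
        for state, k in path.steps:
            if state == "M":
                row[k - 1] = seq[pos]
                idx[k - 1] = pos
                pos += 1
            elif state == "I":
                pos += 1  # insert residues are not representable in match coordinates
        taxa.append(label)
        rows.append("".join(row))
        indices.append(idx)
    return MarkerAlignment(
        marker_id=model.marker_id,
        taxa=taxa,
        rows=rows,
        seqtype="pep" if model.alphabet == "amino20" else "cds-codon",
        column_source=list(range(1, M + 1)),
        residue_index=indices,
    )


def _informative_columns(msa: MarkerAlignment) -> list[int]:
    alphabet = set(AMINO20) if msa.seqtype == "pep" else set(DNA4)
    kept = []
    for j in range(msa.width):
        counts: dict[str, int] = {}
        for r in msa.rows:
            c = r[j].upper()
            if c in alphabet:
                counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            kept.append(j)
    return kept


def trim_parsimony_informative(msa: MarkerAlignment) -> tuple[MarkerAlignment, list[int]]:
    """Keep only parsimony-informative columns.

    Returns the trimmed alignment and the kept column indices, 1-based
    ascending.  An empty result is allowed (the marker is then
    uninformative); trimming is idempotent.
    """
    kept0 = _informative_columns(msa)
    source = msa.column_source or list(range(1, msa.width + 1))
    trimmed = MarkerAlignment(
        marker_id=msa.marker_id,
        taxa=list(msa.taxa),
        rows=["".join(r[j] for j in kept0) for r in msa.rows],
        seqtype=msa.seqtype,
        column_source=[source[j] for j in kept0],
    )
    return trimmed, [j + 1 for j in kept0]


def backthread_codons(
    pep_msa: MarkerAlignment,
    cds: Mapping[str, str],
    *,
    allow_internal_stop: bool = False,
) -> MarkerAlignment:
    """Replace each peptide column with the corresponding codon triple.

    ``cds`` maps taxon -> ungapped coding sequence whose translation is the
    taxon's ungapped peptide row (a trailing stop codon is tolerated and
    dropped).  Peptide gaps become ``---``; any trimming already applied to
    the peptide alignment carries over as whole column triples.
    """
    if pep_msa.seqtype != "pep":
        raise InputError("backthread_codons expects a peptide alignment")
    rows: list[str] = []
    for taxon, pep_row in zip(pep_msa.taxa, pep_msa.rows):
        if taxon not in cds:
            raise InputError(f"no coding sequence provided for taxon {taxon!r}")
        nt = cds[taxon].upper().replace("U", "T")
        n_res = sum(1 for c in pep_row if c not in GAP_CHARS)
        if len(nt) == 3 * (n_res + 1) and nt[-3:] in _STOP_CODONS:
            nt = nt[:-3]
        if len(nt) != 3 * n_res:
            raise InputError(
                f"taxon {taxon!r}: coding sequence length {len(nt)} does not match "
                f"3 x {n_res} peptide residues"
            )
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        for i, codon in enumerate(codons):
            if codon in _STOP_CODONS:
                if not allow_internal_stop:
                    raise InputError(f"taxon {taxon!r}: internal stop codon at codon {i + 1}")
                continue
        out: list[str] = []
        it = iter(codons)
        for c in pep_row:
            if c in GAP_CHARS:
                out.append("---")
            else:
                codon = next(it)
                aa = _CODON_TO_AA.get(codon)
                if aa is not None and c.upper() in AMINO20 and aa != c.upper():
                    raise InputError(
                        f"taxon {taxon!r}: codon {codon} translates to {aa}, "
                        f"but the aligned peptide residue is {c}"
                    )
                out.append(codon)
        rows.append("".join(out))
    return MarkerAlignment(
        marker_id=pep_msa.marker_id,
        taxa=list(pep_msa.taxa),
        rows=rows,
        seqtype="cds-codon",
        column_source=list(pep_msa.column_source) if pep_msa.column_source else None,
    )
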