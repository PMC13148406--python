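"""Single-copy orthology filtering and the content-hash checkpoint.

Raw profile-search hits are organised in a :class:`HitTable` keyed by
(marker, sample).  Strict orthology is enforced by dropping every
(marker, sample) cell with more than one passing hit: multiple copies in a
genome indicate duplication or contamination and would poison a
single-copy marker.

Search results are persisted in a :class:`Checkpoint` keyed by the SHA-256
of each sample file's raw bytes, never by file name or path, so reruns can
add or remove samples without repeating finished searches and checkpoint
files stay portable across machines and renames.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import CheckpointMismatchError, FormatError, InputError, UnsatisfiableRunError
from .profile_hmm import SearchHit

CHECKPOINT_FORMAT = "markerphylo-checkpoint"
CHECKPOINT_VERSION = 1


def hash_file(path: str | Path) -> str:
    """SHA-256 hex digest of a file's raw bytes (compressed files are
    hashed as-is, without decompression)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def params_fingerprint(marker_set_digest: str, threshold_bits: float, seqtype: str) -> str:
    """Digest of the search parameters a checkpoint is only valid under."""
    payload = json.dumps(
        {"markers": marker_set_digest, "threshold": float(threshold_bits), "seqtype": seqtype},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


class HitTable:
    """Mapping (marker_id, sample_id) -> list of :class:`SearchHit`."""

    def __init__(self, hits: Iterable[SearchHit] = ()) -> None:
        self.cells: dict[tuple[str, str], list[SearchHit]] = {}
        for hit in hits:
            self.add(hit)

    def add(self, hit: SearchHit) -> None:
        self.cells.setdefault((hit.marker_id, hit.sample_id), []).append(hit)

    def markers(self) -> list[str]:
        return sorted({m for m, _ in self.cells})

    def samples(self) -> list[str]:
        return sorted({s for _, s in self.cells})

    def __len__(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.cells

    def __getitem__(self, key: tuple[str, str]) -> list[SearchHit]:
        return self.cells[key]

    def canonical(self) -> list[SearchHit]:
        out: list[SearchHit] = []
        for key in sorted(self.cells):
            out.extend(sorted(self.cells[key], key=lambda h: (h.seq_id, -h.bit_score)))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HitTable):
            return NotImplemented
        return self.canonical() == other.canonical()

    def validate(self) -> None:
        for (marker, sample), hits in self.cells.items():
            for h in hits:
                if (h.marker_id, h.sample_id) != (marker, sample):
                    raise InputError(
                        f"hit ({h.marker_id}, {h.sample_id}) filed under cell ({marker}, {sample})"
                    )

    def to_tsv(self, path: str | Path) -> None:
        lines = ["sample\tseq\tmarker\tbits\tspan_start\tspan_end"]
        for h in self.canonical():
            lines.append(
                f"{h.sample_id}\t{h.seq_id}\t{h.marker_id}\t{h.bit_score:.4f}\t{h.model_span[0]}\t{h.model_span[1]}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def enforce_single_copy(hits: HitTable) -> HitTable:
    """Drop every (marker, sample) cell holding two or more hits.

    A sample with multiple hits to the same profile is excluded *for that
    marker only*; its single-copy hits on other markers are untouched.
    Idempotent, and only ever removes cells.
    """
    out = HitTable()
    for key, cell in hits.cells.items():
        if len(cell) == 1:
            out.cells[key] = list(cell)
    return out


def select_markers(hits: HitTable, min_taxa: int = 4) -> list[str]:
    """Markers represented (post single-copy filtering) in >= ``min_taxa`` samples."""
    if min_taxa < 1:
        raise InputError("min_taxa must be >= 1")
    counts: dict[str, int] = {}
    for marker, _ in hits.cells:
        counts[marker] = counts.get(marker, 0) + 1
    kept = sorted(m for m, c in counts.items() if c >= min_taxa)
    if not kept:
        raise UnsatisfiableRunError(
            f"no marker is represented in >= {min_taxa} samples after single-copy "
            "filtering; consider a different marker set or lower --min-taxa"
        )
    return kept


@dataclass
class Checkpoint:
    """Persisted search results keyed by sample-file content hash."""

    params_fingerprint: str
    format_version: int = CHECKPOINT_VERSION
    # content_hash -> (labels seen for this content, hits)
    entries: dict[str, tuple[list[str], list[SearchHit]]] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        lines = [json.dumps({
            "format": CHECKPOINT_FORMAT,
            "version": self.format_version,
            "params_fingerprint": self.params_fingerprint,
        }, sort_keys=True)]
        for chash in sorted(self.entries):
            labels, hits = self.entries[chash]
            lines.append(json.dumps({
                "content_hash": chash,
                "labels": sorted(labels),
                "hits": [h.to_record() for h in sorted(hits, key=lambda h: (h.marker_id, h.seq_id))],
            }, sort_keys=True))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such checkpoint file: {path}")
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if not lines:
            raise FormatError(f"checkpoint {path} is empty")
        try:
            header = json.loads(lines[0])
        except json.JSONDecodeError as exc:
            raise FormatError(f"checkpoint {path} line 1: {exc}")
        if header.get("format") != CHECKPOINT_FORMAT:
            raise FormatError(f"checkpoint {path} has unknown format {header.get('format')!r}")
        if header.get("version") != CHECKPOINT_VERSION:
            raise FormatError(
                f"checkpoint {path} is version {header.get('version')}, expected {CHECKPOINT_VERSION}"
            )
        ckpt = cls(params_fingerprint=header["params_fingerprint"])
        for i, ln in enumerate(lines[1:], start=2):
            try:
                rec = json.loads(ln)
            except json.JSONDecodeError as exc:
                raise FormatError(f"checkpoint {path} line {i}: {exc}")
            hits = [SearchHit.from_record(r) for r in rec["hits"]]
            ckpt.entries[rec["content_hash"]] = (list(rec["labels"]), hits)
        return ckpt


@dataclass(frozen=True)
class CheckpointDiff:
    to_search: tuple[str, ...]  # content hashes needing a fresh search
    reusable: tuple[str, ...]  # content hashes served from the checkpoint
    removed: tuple[str, ...]  # checkpoint entries with no matching input file


def checkpoint_diff(
    ckpt: Checkpoint | None,
    sample_hashes: Mapping[str, str],
    fingerprint: str,
    *,
    force: bool = False,
) -> CheckpointDiff:
    """Classify input samples against an existing checkpoint.

    ``sample_hashes`` maps sample label -> content hash for this run's
    inputs.  A fingerprint mismatch is refused unless ``force`` is set, in
    which case the checkpoint is ignored and everything is re-searched.
    """
    hashes = set(sample_hashes.values())
    if ckpt is None:
        return CheckpointDiff(tuple(sorted(hashes)), (), ())
    if ckpt.params_fingerprint != fingerprint:
        if not force:
            raise CheckpointMismatchError(
                "checkpoint was produced under different search parameters "
                "(marker set, threshold, or sequence type); rerun with --force "
                "to discard it and search from scratch"
            )
        return CheckpointDiff(tuple(sorted(hashes)), (), ())
    reusable = tuple(sorted(hashes & set(ckpt.entries)))
    to_search = tuple(sorted(hashes - set(ckpt.entries)))
    removed = tuple(sorted(set(ckpt.entries) - hashes))
    return CheckpointDiff(to_search, reusable, removed)


def merge_checkpoint(
    ckpt: Checkpoint,
    new_entries: Mapping[str, tuple[str, Sequence[SearchHit]]],
) -> Checkpoint:
    """Fold newly searched samples into a checkpoint (pure; idempotent).

    ``new_entries`` maps content hash -> (sample label, hits).  A hash
    already present keeps its hits; a new label for known content is
    recorded alongside the old one with a warning.
    """
    merged = Checkpoint(params_fingerprint=ckpt.params_fingerprint)
    merged.entries = {h: (list(labels), list(hits)) for h, (labels, hits) in ckpt.entries.items()}
    for chash, (label, hits) in new_entries.items():
        if chash in merged.entries:
            labels, old_hits = merged.entries[chash]
            if label not in labels:
                warnings.warn(
                    f"content hash {chash[:12]} already checkpointed under label(s) "
                    f"{labels}; also recording label {label!r}"
                )
                merged.entries[chash] = (sorted({*labels, label}), old_hits)
        else:
            merged.entries[chash] = ([label], list(hits))
    return merged


def assemble_hit_table(ckpt: Checkpoint, run_labels: Mapping[str, str]) -> HitTable:
    """Build this run's hit table from a checkpoint.

    ``run_labels`` maps content hash -> the label the sample carries in this
    run; hits are relabelled accordingly (checkpointed sample_ids may come
    from a previous file name).  Checkpoint entries absent from
    ``run_labels`` are left out of the run.
    """
    table = HitTable()
    for chash, label in run_labels.items():
        if chash not in ckpt.entries:
            raise InputError(f"content hash {chash[:12]} not present in checkpoint")
        _, hits = ckpt.entries[chash]
        for h in hits:
            table.add(SearchHit(
                sample_id=label,
                seq_id=h.seq_id,
                marker_id=h.marker_id,
                bit_score=h.bit_score,
                model_span=h.model_span,
            ))
    return table
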