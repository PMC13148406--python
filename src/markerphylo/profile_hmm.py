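"""Profile hidden Markov models: HMMER3 text I/O, construction, and scoring.

This module is the computational core of the ortholog search step.  A
:class:`ProfileHMM` is a position-specific model of a single-copy marker
family with match (M), insert (I) and delete (D) states.  Sequences are
scored in *glocal* mode: the model is traversed in full (via M/D states)
while flanking sequence residues are absorbed by free N/C loop states that
emit at the null frequencies, so they contribute nothing to the log-odds
score.  This is the natural contract for single-domain, BUSCO-style
markers; multihit local alignment is deliberately out of scope.

Scores are log-odds against the null model, reported in bits (log base 2).
All dynamic programming is carried out in natural-log space; a probability
of zero is floored at ``LOG_FLOOR`` internally so vectorised scan tricks
stay NaN-free, and any score that can only be reached through such a
floored step is reported as ``-inf``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, InputError, ValidationError

AMINO20 = "ACDEFGHIKLMNPQRSTVWY"
DNA4 = "ACGT"

ALPHABETS = {"amino20": AMINO20, "dna4": DNA4}

#: natural-log floor standing in for log(0) during DP
LOG_FLOOR = -1.0e6
#: scores below this (nats) are unreachable without a zero-probability step
_IMPOSSIBLE = -5.0e5

_LN2 = math.log(2.0)

# indices into a 7-element transition row, HMMER3 column order
_MM, _MI, _MD, _IM, _II, _DM, _DD = range(7)

#: default per-node core transitions used by :func:`build_hmm`
DEFAULT_CORE_TRANSITIONS = (0.9, 0.05, 0.05, 0.8, 0.2, 0.8, 0.2)
#: begin-node row: B->M1, (no I0), B->D1
DEFAULT_BEGIN_TRANSITIONS = (0.95, 0.0, 0.05, 1.0, 0.0, 1.0, 0.0)
#: last node: M_M->E, -, -, and D_M->E in the d->m slot
DEFAULT_END_TRANSITIONS = (1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0)


def alphabet_symbols(alphabet: str) -> str:
    try:
        return ALPHABETS[alphabet]
    except KeyError:
        raise InputError(f"unknown alphabet {alphabet!r}; expected one of {sorted(ALPHABETS)}")


def encode_sequence(seq: str, alphabet: str, *, strict: bool = True) -> np.ndarray:
    """Encode a residue string as integer codes.

    With ``strict=False`` out-of-alphabet residues (ambiguity codes such as
    ``X``) are mapped to a sentinel ``-1`` which scores as the null model
    (log-odds zero) rather than raising.
    """
    symbols = alphabet_symbols(alphabet)
    lookup = {c: i for i, c in enumerate(symbols)}
    codes = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq.upper()):
        code = lookup.get(c, -1)
        if code < 0 and strict:
            raise InputError(f"residue {c!r} at position {i + 1} is not in alphabet {alphabet}")
        codes[i] = code
    return codes


@dataclass
class ProfileHMM:
    """One marker's profile HMM.

    ``transitions`` has shape ``(M + 1, 7)`` in HMMER3 column order
    ``m->m  m->i  m->d  i->m  i->i  d->m  d->d``.  Row 0 is the begin node
    (``m->m`` is B->M1, ``m->d`` is B->D1; there is no I0 state).  Row M's
    ``m->m`` slot holds M_M->E and its ``d->m`` slot holds D_M->E.
    """

    marker_id: str
    alphabet: str
    match_emission: np.ndarray  # (M, K)
    insert_emission: np.ndarray  # (M, K)
    transitions: np.ndarray  # (M + 1, 7)
    null_freq: np.ndarray  # (K,)
    gathering_cutoff_bits: float | None = None

    def __post_init__(self) -> None:
        self.match_emission = np.asarray(self.match_emission, dtype=float)
        self.insert_emission = np.asarray(self.insert_emission, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.null_freq = np.asarray(self.null_freq, dtype=float)

    @property
    def model_length(self) -> int:
        return self.match_emission.shape[0]

    # spec shorthand
    M = model_length

    @property
    def n_symbols(self) -> int:
        return len(alphabet_symbols(self.alphabet))

    def validate(self, atol: float = 1e-6) -> None:
        M, K = self.match_emission.shape
        if M < 1:
            raise ValidationError("model length must be >= 1")
        if K != self.n_symbols:
            raise ValidationError(f"emission width {K} does not match alphabet {self.alphabet}")
        if self.insert_emission.shape != (M, K):
            raise ValidationError("insert_emission shape mismatch")
        if self.transitions.shape != (M + 1, 7):
            raise ValidationError("transitions must have shape (M+1, 7)")
        if self.null_freq.shape != (K,):
            raise ValidationError("null_freq shape mismatch")
        for name, rows in (
            ("match_emission", self.match_emission),
            ("insert_emission", self.insert_emission),
            ("null_freq", self.null_freq[None, :]),
        ):
            if np.any(rows < -atol):
                raise ValidationError(f"{name} has negative entries")
            sums = rows.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > atol):
                raise ValidationError(f"{name} rows do not sum to 1 (max dev {np.abs(sums - 1).max():.2e})")
        t = self.transitions
        for name, cols in (("m->*", (_MM, _MI, _MD)), ("i->*", (_IM, _II)), ("d->*", (_DM, _DD))):
            sums = t[:, list(cols)].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > atol):
                raise ValidationError(f"transition triplet {name} does not sum to 1")
        if t[0, _MI] > atol:
            raise ValidationError("begin node may not transition to an insert state (no I0)")

    # ---- derived log-space parameters -------------------------------------

    def _log_params(self) -> dict[str, np.ndarray]:
        if not hasattr(self, "_log_cache"):
            def slog(p: np.ndarray) -> np.ndarray:
                p = np.asarray(p, dtype=float)
                with np.errstate(divide="ignore"):
                    out = np.log(np.where(p > 0, p, 1.0))
                return np.where(p > 0, out, LOG_FLOOR)

            lnull = slog(self.null_freq)
            # log-odds emissions with a trailing null column for unknown residues
            lm = slog(self.match_emission) - lnull[None, :]
            li = slog(self.insert_emission) - lnull[None, :]
            lm = np.hstack([lm, np.zeros((lm.shape[0], 1))])
            li = np.hstack([li, np.zeros((li.shape[0], 1))])
            lt = slog(self.transitions)
            self._log_cache = {"lm": lm, "li": li, "lt": lt}
        return self._log_cache


@dataclass(frozen=True)
class SearchHit:
    """A sequence passing the reporting threshold for one marker."""

    sample_id: str
    seq_id: str
    marker_id: str
    bit_score: float
    model_span: tuple[int, int]  # 1-based inclusive match-state range

    def to_record(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "seq_id": self.seq_id,
            "marker_id": self.marker_id,
            "bit_score": self.bit_score,
            "span_start": self.model_span[0],
            "span_end": self.model_span[1],
        }

    @classmethod
    def from_record(cls, rec: dict) -> "SearchHit":
        return cls(
            sample_id=rec["sample_id"],
            seq_id=rec["seq_id"],
            marker_id=rec["marker_id"],
            bit_score=float(rec["bit_score"]),
            model_span=(int(rec["span_start"]), int(rec["span_end"])),
        )


@dataclass(frozen=True)
class ScoreThreshold:
    """Reporting threshold: a profile's gathering cutoff when present,
    otherwise a flat bit-score floor (default 10 bits)."""

    floor_bits: float = 10.0
    prefer_gathering: bool = True

    def resolve(self, model: ProfileHMM) -> float:
        if self.prefer_gathering and model.gathering_cutoff_bits is not None:
            return model.gathering_cutoff_bits
        return self.floor_bits


@dataclass(frozen=True)
class WorkerPlan:
    n_instances: int
    cores_per_instance: int


def plan_search_workers(n_cpus: int) -> WorkerPlan:
    """CPU allocation for parallel profile search.

    Below eight CPUs a single instance uses every available core; at eight
    or more the pool is divided into ``floor(n_cpus / 4)`` instances of four
    cores each (large single instances scale poorly).
    """
    if n_cpus < 1:
        raise InputError("n_cpus must be >= 1")
    if n_cpus < 8:
        return WorkerPlan(1, n_cpus)
    return WorkerPlan(n_cpus // 4, 4)


# ---------------------------------------------------------------------------
# HMMER3 text format
# ---------------------------------------------------------------------------

_HMM_ALPH = {"amino20": "amino", "dna4": "DNA"}
_ALPH_HMM = {"amino": "amino20", "dna": "dna4", "rna": "dna4"}


def _fmt(p: float) -> str:
    return "*" if p <= 0 else f"{-math.log(p):.5f}"


def _parse_prob(tok: str, lineno: int) -> float:
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError:
        raise FormatError(f"line {lineno}: non-numeric emission/transition field {tok!r}")


def write_hmm(models: ProfileHMM | Iterable[ProfileHMM], path: str | Path) -> None:
    """Write one or more models as HMMER3/f-style text.

    Probabilities are written as negative natural logs; probability zero is
    written as ``*``.
    """
    if isinstance(models, ProfileHMM):
        models = [models]
    lines: list[str] = []
    for model in models:
        model.validate()
        K = model.n_symbols
        symbols = alphabet_symbols(model.alphabet)
        M = model.model_length
        lines.append("HMMER3/f [markerphylo 0.1.0]")
        lines.append(f"NAME  {model.marker_id}")
        lines.append(f"LENG  {M}")
        lines.append(f"ALPH  {_HMM_ALPH[model.alphabet]}")
        if model.gathering_cutoff_bits is not None:
            ga = model.gathering_cutoff_bits
            lines.append(f"GA    {ga:.2f} {ga:.2f};")
        lines.append("HMM      " + "  ".join(f"{c:>7s}" for c in symbols))
        lines.append("        " + "  ".join(f"{t:>7s}" for t in ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")))
        lines.append("  COMPO  " + "  ".join(f"{_fmt(p):>7s}" for p in model.null_freq))
        # node 0: insert-0 emissions (unused; written as null) + begin transitions
        lines.append("         " + "  ".join(f"{_fmt(p):>7s}" for p in model.null_freq))
        lines.append("         " + "  ".join(f"{_fmt(p):>7s}" for p in model.transitions[0]))
        for k in range(1, M + 1):
            lines.append(f"{k:>7d}  " + "  ".join(f"{_fmt(p):>7s}" for p in model.match_emission[k - 1]) + f"  {k:>6d} - - - -")
            lines.append("         " + "  ".join(f"{_fmt(p):>7s}" for p in model.insert_emission[k - 1]))
            lines.append("         " + "  ".join(f"{_fmt(p):>7s}" for p in model.transitions[k]))
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def read_hmm(path: str | Path) -> list[ProfileHMM]:
    """Parse HMMER3 text (one or more records) into :class:`ProfileHMM` s.

    Handles files written by :func:`write_hmm` as well as ``hmmbuild``
    output: extra header fields and STATS lines are parsed and ignored, and
    annotation columns after the match emissions are skipped.  A ``COMPO``
    line, when present, supplies the null frequencies; otherwise the null is
    uniform.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such HMM file: {path}")
    raw = path.read_text().splitlines()
    models: list[ProfileHMM] = []
    i = 0
    n = len(raw)

    def skip_blank(j: int) -> int:
        while j < n and not raw[j].strip():
            j += 1
        return j

    while True:
        i = skip_blank(i)
        if i >= n:
            break
        if not raw[i].startswith("HMMER3"):
            raise FormatError(f"line {i + 1}: expected 'HMMER3/...' header, got {raw[i]!r}")
        i += 1
        header: dict[str, str] = {}
        while i < n and not raw[i].startswith("HMM "):
            key = raw[i].split(None, 1)
            if len(key) == 2:
                header.setdefault(key[0], key[1].strip())
            i += 1
        if i >= n:
            raise FormatError(f"line {n}: record truncated before 'HMM' emission header")
        if "LENG" not in header or "ALPH" not in header:
            raise FormatError(f"line {i + 1}: record is missing LENG or ALPH header line")
        try:
            M = int(header["LENG"])
        except ValueError:
            raise FormatError(f"LENG value {header['LENG']!r} is not an integer")
        alph_token = header["ALPH"].lower()
        if alph_token not in _ALPH_HMM:
            raise FormatError(f"unsupported alphabet {header['ALPH']!r}")
        alphabet = _ALPH_HMM[alph_token]
        K = len(alphabet_symbols(alphabet))
        name = header.get("NAME", path.stem)
        ga = None
        if "GA" in header:
            m = re.match(r"([-\d.]+)", header["GA"])
            if m:
                ga = float(m.group(1))
        i += 1  # past 'HMM' symbol line
        if i < n and "m->m" in raw[i]:
            i += 1  # transition header line

        def grab(j: int, count: int, what: str) -> tuple[list[float], int]:
            j = skip_blank(j)
            if j >= n or raw[j].strip() == "//":
                raise FormatError(f"line {j + 1}: record truncated before '//' terminator ({what} missing)")
            toks = raw[j].split()
            if len(toks) < count:
                raise FormatError(f"line {j + 1}: expected {count} fields for {what}, got {len(toks)}")
            return [_parse_prob(t, j + 1) for t in toks[:count]], j + 1

        null = np.full(K, 1.0 / K)
        j = skip_blank(i)
        if j < n and raw[j].split()[:1] == ["COMPO"]:
            toks = raw[j].split()[1:]
            if len(toks) < K:
                raise FormatError(f"line {j + 1}: COMPO line has {len(toks)} fields, expected {K}")
            null = np.array([_parse_prob(t, j + 1) for t in toks[:K]])
            null = null / null.sum()
            i = j + 1
        _, i = grab(i, K, "insert-0 emissions")  # I0 emissions, unused
        t0, i = grab(i, 7, "begin-node transitions")
        match = np.zeros((M, K))
        insert = np.zeros((M, K))
        trans = np.zeros((M + 1, 7))
        trans[0] = t0
        for k in range(1, M + 1):
            i = skip_blank(i)
            if i >= n or raw[i].strip() == "//":
                raise FormatError(f"line {i + 1}: record truncated before '//' terminator (node {k} missing)")
            toks = raw[i].split()
            try:
                node = int(toks[0])
            except (ValueError, IndexError):
                raise FormatError(f"line {i + 1}: expected node index {k}, got {toks[:1]!r}")
            if node != k:
                raise FormatError(f"line {i + 1}: node index {node} out of order (expected {k})")
            if len(toks) < 1 + K:
                raise FormatError(f"line {i + 1}: node {k} match line has too few fields")
            match[k - 1] = [_parse_prob(t, i + 1) for t in toks[1 : 1 + K]]
            i += 1
            row, i = grab(i, K, f"node {k} insert emissions")
            insert[k - 1] = row
            row, i = grab(i, 7, f"node {k} transitions")
            trans[k] = row
        i = skip_blank(i)
        if i >= n or raw[i].strip() != "//":
            raise FormatError(f"line {min(i, n - 1) + 1}: missing '//' record terminator")
        i += 1
        # no I0 state in this architecture: fold any begin->insert mass
        # (present in hmmbuild output) into B->M1 / B->D1
        if trans[0, _MI] > 0:
            rest = trans[0, _MM] + trans[0, _MD]
            if rest <= 0:
                raise FormatError("begin node transitions place all mass on the insert state")
            trans[0, _MM] /= rest
            trans[0, _MD] /= rest
            trans[0, _MI] = 0.0
        # renormalise away -ln rounding drift
        match /= match.sum(axis=1, keepdims=True)
        ins_sums = insert.sum(axis=1, keepdims=True)
        insert = np.where(ins_sums > 0, insert / np.where(ins_sums > 0, ins_sums, 1.0), insert)
        for cols in ((_MM, _MI, _MD), (_IM, _II), (_DM, _DD)):
            s = trans[:, list(cols)].sum(axis=1, keepdims=True)
            trans[:, list(cols)] = np.where(s > 0, trans[:, list(cols)] / np.where(s > 0, s, 1.0), trans[:, list(cols)])
        model = ProfileHMM(
            marker_id=name,
            alphabet=alphabet,
            match_emission=match,
            insert_emission=insert,
            transitions=trans,
            null_freq=null,
            gathering_cutoff_bits=ga,
        )
        model.validate(atol=1e-3)
        models.append(model)
    if not models:
        raise FormatError(f"{path}: no HMM records found")
    return models


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def build_hmm(seed_alignment, pseudocount: float = 1.0, *, alphabet: str = "amino20", marker_id: str | None = None) -> ProfileHMM:
    """Build a fixture-grade profile from a seed alignment.

    Match states are the columns with gap fraction <= 0.5.  Match emissions
    use Laplace-style pseudocounts, ``(count_a + a) / (n_obs + K*a)``; insert
    emissions are the (uniform) null; transitions are fixed documented
    defaults.  ``seed_alignment`` may be a MarkerAlignment or a plain
    sequence of equal-length rows.
    """
    rows = list(getattr(seed_alignment, "rows", seed_alignment))
    if marker_id is None:
        marker_id = getattr(seed_alignment, "marker_id", "marker")
    if not rows:
        raise InputError("seed alignment is empty")
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InputError("seed alignment rows have unequal lengths")
    symbols = alphabet_symbols(alphabet)
    K = len(symbols)
    lookup = {c: i for i, c in enumerate(symbols)}
    nrows = len(rows)
    cols = [[r[j].upper() for r in rows] for j in range(width)]
    match_cols = [j for j, col in enumerate(cols) if sum(c in "-." for c in col) / nrows <= 0.5]
    if not match_cols:
        raise InputError("seed alignment has no match columns (every column is >50% gaps)")
    M = len(match_cols)
    null = np.full(K, 1.0 / K)
    match = np.zeros((M, K))
    for k, j in enumerate(match_cols):
        counts = np.zeros(K)
        for c in cols[j]:
            idx = lookup.get(c)
            if idx is not None:
                counts[idx] += 1
        n_obs = counts.sum()
        denom = n_obs + K * pseudocount
        if denom == 0:
            match[k] = null
        else:
            match[k] = (counts + pseudocount) / denom
    insert = np.tile(null, (M, 1))
    trans = np.tile(np.asarray(DEFAULT_CORE_TRANSITIONS, dtype=float), (M + 1, 1))
    trans[0] = DEFAULT_BEGIN_TRANSITIONS
    trans[M] = DEFAULT_END_TRANSITIONS
    model = ProfileHMM(marker_id=marker_id, alphabet=alphabet, match_emission=match,
                       insert_emission=insert, transitions=trans, null_freq=null)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViterbiPath:
    """Best-scoring glocal state path.

    ``steps`` covers the core states in order, as ("M"|"I"|"D", k) pairs
    with 1-based node index k.  ``seq_start`` residues are absorbed by the
    free N-terminal flank before the core begins; residues from
    ``seq_end`` onward are absorbed by the C-terminal flank (0-based,
    half-open).  ``states`` renders the full path B ... E as strings.
    """

    bit_score: float
    steps: tuple[tuple[str, int], ...]
    seq_start: int
    seq_end: int

    @property
    def states(self) -> list[str]:
        return ["B"] + [f"{s}{k}" for s, k in self.steps] + ["E"]

    @property
    def match_span(self) -> tuple[int, int]:
        ks = [k for s, k in self.steps if s == "M"]
        if ks:
            return (min(ks), max(ks))
        if self.steps:
            return (1, max(k for _, k in self.steps))
        return (1, 1)


def _check_seq(model: ProfileHMM, seq: str) -> np.ndarray:
    if not seq:
        raise InputError("sequence is empty")
    return encode_sequence(seq, model.alphabet, strict=True)


def _core_vectors(model: ProfileHMM):
    p = model._log_params()
    lt = p["lt"]
    M = model.model_length
    return {
        "lm": p["lm"], "li": p["li"],
        "tBM": lt[0, _MM], "tBD": lt[0, _MD],
        "tMM": lt[1:M, _MM], "tMI": lt[1:, _MI], "tMD": lt[1:M, _MD],
        "tIM": lt[1:M, _IM], "tII": lt[1:, _II],
        "tDM": lt[1:M, _DM], "tDD": lt[1:M, _DD],
        "tME": lt[M, _MM], "tDE": lt[M, _DM],
    }


def _d_scan(incoming: np.ndarray, tDD: np.ndarray, op) -> np.ndarray:
    """Solve D[k] = op(incoming[k], D[k-1] + tDD[k-1]) along the last axis."""
    M = incoming.shape[-1]
    if M == 1:
        return incoming.copy()
    cum = np.concatenate([[0.0], np.cumsum(tDD)])  # (M,)
    g = op.accumulate(incoming - cum, axis=-1)
    return g + cum


def _row0_D(cv, shape, op) -> np.ndarray:
    incoming = np.full(shape, LOG_FLOOR)
    incoming[..., 0] = cv["tBD"]
    return _d_scan(incoming, cv["tDD"], op)


def forward_bits(model: ProfileHMM, seq: str) -> float:
    """Total glocal log-odds over all state paths, in bits."""
    codes = _check_seq(model, seq)
    return float(forward_bits_coded(model, [codes])[0])


def forward_bits_coded(model: ProfileHMM, coded: Sequence[np.ndarray]) -> np.ndarray:
    """Batched forward scores for pre-encoded sequences (bits).

    Sequences are grouped by length and scored with one vectorised DP per
    group; out-of-alphabet codes (-1) emit at the null frequencies.
    """
    scores = np.empty(len(coded))
    by_len: dict[int, list[int]] = {}
    for idx, c in enumerate(coded):
        if len(c) == 0:
            raise InputError("sequence is empty")
        by_len.setdefault(len(c), []).append(idx)
    cv = _core_vectors(model)
    M = model.model_length
    lse = np.logaddexp
    for L, idxs in by_len.items():
        X = np.stack([coded[i] for i in idxs])  # (n, L)
        n = X.shape[0]
        Dm = _row0_D(cv, (n, M), lse)
        Mm = np.full((n, M), LOG_FLOOR)
        Im = np.full((n, M), LOG_FLOOR)
        total = lse(Mm[:, -1] + cv["tME"], Dm[:, -1] + cv["tDE"])
        for i in range(L):
            x = X[:, i]
            em = cv["lm"][:, x].T  # (n, M)
            ei = cv["li"][:, x].T
            newM = np.full((n, M), LOG_FLOOR)
            newM[:, 0] = cv["tBM"]
            if M > 1:
                newM[:, 1:] = lse(lse(Mm[:, :-1] + cv["tMM"], Im[:, :-1] + cv["tIM"]), Dm[:, :-1] + cv["tDM"])
            newM += em
            Im = ei + lse(Mm + cv["tMI"], Im + cv["tII"])
            Mm = newM
            incoming = np.full((n, M), LOG_FLOOR)
            incoming[:, 0] = cv["tBD"]
            if M > 1:
                incoming[:, 1:] = Mm[:, :-1] + cv["tMD"]
            Dm = _d_scan(incoming, cv["tDD"], lse)
            total = lse(total, lse(Mm[:, -1] + cv["tME"], Dm[:, -1] + cv["tDE"]))
        for j, idx in enumerate(idxs):
            scores[idx] = total[j]
    scores = np.where(scores < _IMPOSSIBLE, -np.inf, scores)
    return scores / _LN2


def viterbi(model: ProfileHMM, seq: str) -> tuple[float, ViterbiPath]:
    """Maximum-probability glocal alignment of ``seq`` to the model.

    Returns the bit score and the best state path (B at the start, E at the
    end; flanking residues are outside the core path).
    """
    codes = _check_seq(model, seq)
    return viterbi_coded(model, codes)


def viterbi_coded(model: ProfileHMM, codes: np.ndarray) -> tuple[float, ViterbiPath]:
    if len(codes) == 0:
        raise InputError("sequence is empty")
    cv = _core_vectors(model)
    M = model.model_length
    L = len(codes)
    NEG = LOG_FLOOR
    Mm = np.full(M, NEG)
    Im = np.full(M, NEG)
    Dm = _row0_D(cv, (M,), np.maximum)
    rowsM = [Mm.copy()]
    rowsI = [Im.copy()]
    rowsD = [Dm.copy()]
    ptrM = [np.zeros(M, dtype=np.int8)]
    ptrI = [np.zeros(M, dtype=np.int8)]
    # row 0: D1 enters from B, deeper deletes only via the D chain
    ptrD0 = np.ones(M, dtype=np.int8)
    ptrD0[0] = 2
    ptrD = [ptrD0]
    for i in range(L):
        x = codes[i]
        em = cv["lm"][:, x]
        ei = cv["li"][:, x]
        newM = np.full(M, NEG)
        pM = np.full(M, 3, dtype=np.int8)  # 3 = from B
        if M > 1:
            a = Mm[:-1] + cv["tMM"]
            b = Im[:-1] + cv["tIM"]
            c = Dm[:-1] + cv["tDM"]
            stacked = np.stack([a, b, c])
            pM[1:] = np.argmax(stacked, axis=0)
            newM[1:] = stacked[pM[1:], np.arange(M - 1)]
        newM[0] = cv["tBM"]
        newM = newM + em
        aI = Mm + cv["tMI"]
        bI = Im + cv["tII"]
        pI = np.where(aI >= bI, 0, 1).astype(np.int8)
        newI = ei + np.maximum(aI, bI)
        incoming = np.full(M, NEG)
        incoming[0] = cv["tBD"]
        if M > 1:
            incoming[1:] = newM[:-1] + cv["tMD"]
        newD = _d_scan(incoming, cv["tDD"], np.maximum)
        pD = np.full(M, 2, dtype=np.int8)  # from B (only valid at k=1)
        if M > 1:
            chain = newD[:-1] + cv["tDD"]
            pD[1:] = np.where(incoming[1:] >= chain, 0, 1)
        Mm, Im, Dm = newM, newI, newD
        rowsM.append(Mm.copy())
        rowsI.append(Im.copy())
        rowsD.append(Dm.copy())
        ptrM.append(pM)
        ptrI.append(pI)
        ptrD.append(pD)
    endM = np.array([rowsM[i][-1] + cv["tME"] for i in range(L + 1)])
    endD = np.array([rowsD[i][-1] + cv["tDE"] for i in range(L + 1)])
    best_end = np.maximum(endM, endD)
    i_star = int(np.argmax(best_end))
    score = float(best_end[i_star])
    if score < _IMPOSSIBLE:
        return -math.inf, ViterbiPath(-math.inf, (), 0, 0)
    # traceback
    steps: list[tuple[str, int]] = []
    state = "M" if endM[i_star] >= endD[i_star] else "D"
    k, i = M - 1, i_star
    seq_start = 0
    while True:
        steps.append((state, k + 1))
        if state == "M":
            choice = ptrM[i][k]
            if choice == 3:
                seq_start = i - 1
                break
            state = "MID"[choice]
            k, i = k - 1, i - 1
        elif state == "I":
            choice = ptrI[i][k]
            state = "M" if choice == 0 else "I"
            i = i - 1
        else:  # D
            choice = ptrD[i][k]
            if choice == 2:
                seq_start = i
                break
            state = "M" if choice == 0 else "D"
            k = k - 1
    steps.reverse()
    bits = score / _LN2
    return bits, ViterbiPath(bits, tuple(steps), seq_start, i_star)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def diagonal_screen_bits(model: ProfileHMM, codes: np.ndarray) -> float:
    """Best full-length ungapped (single-diagonal) match score, in bits.

    Cheap screen used to skip hopeless (sequence, marker) pairs before the
    full DP, in the spirit of HMMER's acceleration filters.  Returns +inf
    when the sequence is shorter than the model (no full diagonal exists).
    """
    M = model.model_length
    L = len(codes)
    if L < M:
        return math.inf
    lm = _core_vectors(model)["lm"]
    windows = np.lib.stride_tricks.sliding_window_view(codes, M)  # (L-M+1, M)
    scores = lm[np.arange(M)[None, :], windows].sum(axis=1)
    return float(scores.max()) / _LN2


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Minimal-strictness FASTA reader returning (id, sequence) pairs."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such FASTA file: {path}")
    try:
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    except Exception as exc:  # pragma: no cover - biopython raises rarely
        raise FormatError(f"unreadable FASTA {path}: {exc}")
    if not records:
        raise InputError(f"FASTA file {path} contains no sequences")
    if any(not seq for _, seq in records):
        raise FormatError(f"FASTA file {path} contains an empty sequence record")
    return records


def search_sample(
    markers: Sequence[ProfileHMM],
    proteome: str | Path,
    threshold: ScoreThreshold | float | None = None,
    *,
    sample_id: str | None = None,
    prefilter: bool = True,
    prefilter_margin_bits: float = 30.0,
) -> list[SearchHit]:
    """Score every sequence in ``proteome`` against every marker profile.

    Reports every (sequence, marker) pair whose forward bit score passes the
    threshold; multiple passing sequences per marker are all retained here
    (single-copy exclusion happens downstream).  ``prefilter`` enables the
    diagonal screen; pairs whose screen score plus the safety margin cannot
    reach the cutoff are skipped without the full DP.
    """
    if threshold is None:
        threshold = ScoreThreshold()
    elif isinstance(threshold, (int, float)):
        threshold = ScoreThreshold(floor_bits=float(threshold), prefer_gathering=False)
    path = Path(proteome)
    if sample_id is None:
        sample_id = path.stem
    records = read_fasta(path)
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate sequence ids in {path}")
    hits: list[SearchHit] = []
    for model in markers:
        cutoff = threshold.resolve(model)
        coded = [encode_sequence(seq, model.alphabet, strict=False) for _, seq in records]
        if prefilter:
            cand = [j for j, c in enumerate(coded)
                    if diagonal_screen_bits(model, c) + prefilter_margin_bits >= cutoff]
        else:
            cand = list(range(len(coded)))
        if not cand:
            continue
        fwd = forward_bits_coded(model, [coded[j] for j in cand])
        for j, bits in zip(cand, fwd):
            if bits >= cutoff:
                _, vpath = viterbi_coded(model, coded[j])
                hits.append(SearchHit(
                    sample_id=sample_id,
                    seq_id=ids[j],
                    marker_id=model.marker_id,
                    bit_score=float(bits),
                    model_span=vpath.match_span,
                ))
    return hits
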