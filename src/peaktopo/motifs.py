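"""Position frequency matrices, log-odds scoring and motif scanning.

A transcription-factor binding profile is handled in two forms: the raw
:class:`PositionFrequencyMatrix` (per-position base counts over aligned
binding sites) and the :class:`PositionWeightMatrix` derived from it
(base-2 log-odds against a background distribution).  Scores are reported
on the *relative* 0-100 scale, an affine rescaling of the raw log-odds sum
between the matrix's minimal and maximal attainable scores, so thresholds
are comparable across motifs of different width and information content.

Scanning scores every offset on both strands.  When a list of discrete
hits is requested, hits are selected greedily by descending score and two
accepted hits may overlap by at most ``floor(w/5)`` bp (a 7 bp motif may
overlap a neighbour by 1 bp).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as _bio_motifs

__all__ = [
    "BASES",
    "PositionFrequencyMatrix",
    "PositionWeightMatrix",
    "MotifHit",
    "parse_jaspar_pfm",
    "pfm_gc_content",
    "pfm_to_pwm",
    "relative_score",
    "scan_sequence",
    "best_hit_in_interval",
    "top_hit",
    "encode_sequence",
    "score_positions",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# encoding: A=0 C=1 G=2 T=3, anything else (N, IUPAC ambiguity) = 4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Observed base counts of aligned binding sites, rows A, C, G, T."""

    matrix_id: str
    counts: np.ndarray  # shape (4, w), non-negative
    name: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"PFM {self.matrix_id!r}: counts must be 4 x w with w >= 1")
        if (counts < 0).any():
            raise ValueError(f"PFM {self.matrix_id!r}: negative counts")
        if (counts.sum(axis=0) < 1).any():
            raise ValueError(f"PFM {self.matrix_id!r}: every column must total >= 1")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def gc_content(self) -> float:
        return pfm_gc_content(self)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def column_probabilities(self) -> np.ndarray:
        """Per-column base probabilities (counts normalised), shape (4, w)."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Base-2 log-odds weights with the raw-score range for relative scoring.

    ``weights`` has an appended 5th row holding each column's minimum so
    that non-ACGT bases score as the worst base of the column.
    """

    matrix_id: str
    weights: np.ndarray  # shape (4, w)
    background: np.ndarray  # shape (4,)
    name: str = ""
    _ext: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "_ext", np.vstack([w, w.min(axis=0)]))

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def min_raw(self) -> float:
        return float(self.weights.min(axis=0).sum())

    @property
    def max_raw(self) -> float:
        return float(self.weights.max(axis=0).sum())

    def reverse_complement(self) -> "PositionWeightMatrix":
        # complement = swap A<->T and C<->G rows; reverse column order
        rc = self.weights[::-1, ::-1]
        return PositionWeightMatrix(self.matrix_id, rc, self.background, self.name)

    def raw_score(self, subsequence: str) -> float:
        codes = encode_sequence(subsequence)
        if codes.size != self.width:
            raise ValueError(
                f"subsequence length {codes.size} != motif width {self.width}"
            )
        return float(self._ext[codes, np.arange(self.width)].sum())

    def rel_from_raw(self, raw) -> np.ndarray:
        return 100.0 * (np.asarray(raw) - self.min_raw) / (self.max_raw - self.min_raw)


def parse_jaspar_pfm(text: str) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR-style matrix text into a list of PFMs.

    Accepts one or more records of the form::

        >MA0004.1 Arnt
        A  [ 4 19  0  0  0  0 ]
        C  [16  0 20  0  0  0 ]
        G  [ 0  1  0 20  0 20 ]
        T  [ 0  0  0  0 20  0 ]

    Row labels are honoured, so rows may appear in any order; output rows
    are always A, C, G, T.  Ragged rows or negative counts raise
    ``ValueError``.
    """
    try:
        records = _bio_motifs.parse(io.StringIO(text), "jaspar")
    except Exception as exc:  # biopython raises bare Exception subclasses
        raise ValueError(f"could not parse JASPAR matrix text: {exc}") from exc
    pfms = []
    for record in records:
        counts = np.array([record.counts[b] for b in BASES], dtype=float)
        pfms.append(
            PositionFrequencyMatrix(
                matrix_id=record.matrix_id or record.name or f"PFM{len(pfms) + 1}",
                counts=counts,
                name=record.name or "",
            )
        )
    return pfms


def pfm_gc_content(pfm: PositionFrequencyMatrix) -> float:
    """Fraction of the PFM's total counts in the C and G rows."""
    totals = pfm.counts.sum(axis=1)
    return float((totals[1] + totals[2]) / totals.sum())


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    background: np.ndarray | None = None,
    pseudocount: str | float = "sqrt",
) -> PositionWeightMatrix:
    """Convert counts to base-2 log-odds weights.

    With the default square-root pseudocount rule, column *i* with total
    ``N_i`` yields::

        weight[b, i] = log2( ((counts[b, i] + sqrt(N_i) * p_b) / (N_i + sqrt(N_i))) / p_b )

    where ``p_b`` is the background probability of base *b* (uniform 0.25
    by default).  A numeric ``pseudocount`` is used as a flat per-base
    addition ``counts + c * p_b`` over ``N + c`` instead.
    """
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1) > 1e-9:
            raise ValueError("background must be 4 positive probabilities summing to 1")
    totals = pfm.counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-sum PFM column")
    pc = np.sqrt(totals) if pseudocount == "sqrt" else float(pseudocount) * np.ones_like(totals)
    probs = (pfm.counts + pc * bg[:, None]) / (totals + pc)
    weights = np.log2(probs / bg[:, None])
    return PositionWeightMatrix(pfm.matrix_id, weights, bg, pfm.name)


def relative_score(pwm: PositionWeightMatrix, subsequence: str) -> float:
    """Score a width-w subsequence on the 0-100 relative scale."""
    return float(pwm.rel_from_raw(pwm.raw_score(subsequence)))


@dataclass(frozen=True)
class MotifHit:
    """One scored motif placement within a peak sequence."""

    peak_id: str
    offset: int  # 0-based start within the peak sequence
    strand: str  # "+" or "-"
    raw_score: float
    rel_score: float
    dist_to_peakmax: int  # motif center - sequence center, bp
    rank: int = 0  # 1 = best hit in the peak; 0 = unranked
    width: int = 0

    @property
    def center(self) -> int:
        """Offset of the motif center base within the sequence."""
        return self.offset + self.width // 2


def _hit(peak_id, offset, strand, raw, rel, w, seq_len, rank=0):
    center = offset + w // 2
    dist = center - (seq_len - 1) // 2
    return MotifHit(peak_id, int(offset), strand, float(raw), float(rel), int(dist), rank, int(w))


def score_positions(pwm: PositionWeightMatrix, codes: np.ndarray) -> np.ndarray:
    """Raw log-odds score at every offset on both strands.

    ``codes`` is an encoded sequence array of shape (L,) or a batch
    (n, L).  Returns raw scores of shape (..., L - w + 1, 2); index 0 of
    the last axis is the forward strand, 1 the reverse strand (the score
    of the reverse complement of the window).
    """
    single = codes.ndim == 1
    codes = np.atleast_2d(codes)
    n, L = codes.shape
    w = pwm.width
    if L < w:
        raise ValueError(f"sequence length {L} < motif width {w}")
    npos = L - w + 1
    fwd = np.zeros((n, npos))
    rev = np.zeros((n, npos))
    ext_f = pwm._ext
    ext_r = pwm.reverse_complement()._ext
    for i in range(w):
        col = codes[:, i : i + npos]
        fwd += ext_f[col, i]
        rev += ext_r[col, i]
    out = np.stack([fwd, rev], axis=-1)
    return out[0] if single else out


def _rel_matrix(pwm: PositionWeightMatrix, sequence: str) -> np.ndarray:
    codes = encode_sequence(sequence)
    raw = score_positions(pwm, codes)
    return np.asarray(pwm.rel_from_raw(raw)), raw


def _candidate_order(rel: np.ndarray):
    """Offsets/strands sorted by rel score desc, then offset asc, then + strand."""
    npos = rel.shape[0]
    offs, strands = np.meshgrid(np.arange(npos), np.arange(2), indexing="ij")
    flat_rel = rel.ravel()
    order = np.lexsort((strands.ravel(), offs.ravel(), -flat_rel))
    return offs.ravel()[order], strands.ravel()[order], flat_rel[order]


def scan_sequence(
    pwm: PositionWeightMatrix,
    sequence: str,
    floor_rel_score: float = 60.0,
    max_hits: int | None = None,
    peak_id: str = "",
) -> list[MotifHit]:
    """Greedy non-overlapping scan of one sequence on both strands.

    Candidates at every offset on both strands are visited in descending
    relative score (ties: leftmost offset, then + strand).  A candidate is
    rejected when it would overlap an already accepted hit by more than
    ``floor(w/5)`` bp.  Hits below ``floor_rel_score`` are dropped.
    Returned hits carry ranks 1..k in acceptance (score) order.
    """
    w = pwm.width
    if len(sequence) < w:
        warnings.warn(f"sequence shorter than motif width {w}; no hits")
        return []
    rel, raw = _rel_matrix(pwm, sequence)
    offs, strands, rels = _candidate_order(rel)
    keep = rels >= floor_rel_score
    offs, strands, rels = offs[keep], strands[keep], rels[keep]
    max_overlap = w // 5
    accepted: list[tuple[int, int, int]] = []  # (offset, strand, order index)
    for k in range(offs.size):
        o = int(offs[k])
        # overlap in bp between [o, o+w) and an accepted [a, a+w)
        if any(w - abs(o - a) > max_overlap for a, _, _ in accepted):
            continue
        accepted.append((o, int(strands[k]), k))
        if max_hits is not None and len(accepted) >= max_hits:
            break
    hits = []
    for rank, (o, s, k) in enumerate(accepted, start=1):
        hits.append(
            _hit(peak_id, o, "+-"[s], raw[o, s], rel[o, s], w, len(sequence), rank)
        )
    return hits


def top_hit(pwm: PositionWeightMatrix, sequence: str, peak_id: str = "") -> MotifHit | None:
    """The single best-scoring placement (rank 1), no score floor."""
    hits = scan_sequence(pwm, sequence, floor_rel_score=-np.inf, max_hits=1, peak_id=peak_id)
    return hits[0] if hits else None


def best_hit_in_interval(
    pwm: PositionWeightMatrix,
    sequence: str,
    interval: tuple[int, int],
    peak_id: str = "",
) -> MotifHit | None:
    """Best-scoring hit whose *center* lies in ``[interval[0], interval[1])``.

    Used for distal control windows: the full both-strand score matrix is
    restricted to offsets whose motif center falls in the interval.
    Returns ``None`` with a warning when the interval is shorter than the
    motif width or holds no scoreable center.
    """
    lo, hi = interval
    w = pwm.width
    if hi - lo < w:
        warnings.warn(f"interval {interval} shorter than motif width {w}")
        return None
    rel, raw = _rel_matrix(pwm, sequence)
    centers = np.arange(rel.shape[0]) + w // 2
    mask = (centers >= lo) & (centers < hi)
    if not mask.any():
        warnings.warn(f"no motif center fits in interval {interval}")
        return None
    sub = np.where(mask[:, None], rel, -np.inf)
    offs, strands, rels = _candidate_order(sub)
    o, s = int(offs[0]), int(strands[0])
    return _hit(peak_id, o, "+-"[s], raw[o, s], rel[o, s], w, len(sequence), 1)
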