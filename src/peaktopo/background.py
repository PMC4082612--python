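"""Composition-matched background sequence generation.

Motif over-representation statistics are exquisitely sensitive to the
nucleotide composition of the background set: a GC-rich foreground scored
against a genome-average background inflates GC-rich profiles regardless
of binding.  This module provides six background models that match a
target set's composition at different granularities:

1. ``mono_shuffle``       - per-sequence mononucleotide shuffle
2. ``di_shuffle``         - per-sequence dinucleotide-preserving shuffle
                            (uniform random Eulerian path)
3. ``gc_match``           - genomic pool members matched on global GC
4. ``mono_shuffle_window``- mononucleotide shuffle in sliding windows
5. ``di_shuffle_window``  - dinucleotide shuffle in sliding windows
6. ``gc_match_window``    - pool members matched on the window-GC profile

plus a k-th order Markov chain generator trained on the targets
(``markov``), and construction of the fixed-length genomic sequence pool
the GC-matching models draw from.

N is treated as a fifth symbol in shuffles (so runs of N stay runs of N
counts-wise) and is excluded from both numerator and denominator of GC
content.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .motifs import encode_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicPool",
    "BackgroundSet",
    "gc_fraction",
    "window_gc_profile",
    "build_pool",
    "pool_from_sequences",
    "shuffle_mono",
    "shuffle_di",
    "shuffle_windows",
    "match_gc",
    "match_gc_windows",
    "markov_background",
    "generate_background",
]

MODELS = (
    "mono_shuffle",
    "di_shuffle",
    "gc_match",
    "mono_shuffle_window",
    "di_shuffle_window",
    "gc_match_window",
    "markov",
)


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases; N excluded from both sides."""
    codes = encode_sequence(seq)
    acgt = int((codes < 4).sum())
    if acgt == 0:
        return 0.0
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / acgt


def _gc_bin(gc: float, bin_width: float = 1.0) -> int:
    return int(round(100.0 * gc / bin_width))


def window_gc_profile(seq: str, window: int, step: int) -> np.ndarray:
    """GC fraction in successive windows (last partial window included)."""
    vals = []
    for start in range(0, max(len(seq) - window, 0) + 1, step):
        vals.append(gc_fraction(seq[start : start + window]))
    if not vals:
        vals = [gc_fraction(seq)]
    return np.array(vals)


@dataclass
class GenomicPool:
    """Fixed-length candidate background sequences indexed by GC percent bin."""

    sequences: dict[str, str]
    length: int
    bin_width: float = 1.0
    gc_index: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if len(seq) != self.length:
                raise ValueError(f"pool member {sid!r} has length {len(seq)} != {self.length}")
        if not self.gc_index:
            index: dict[int, list[str]] = defaultdict(list)
            for sid, seq in self.sequences.items():
                index[_gc_bin(gc_fraction(seq), self.bin_width)].append(sid)
            self.gc_index = dict(index)

    def __len__(self) -> int:
        return len(self.sequences)


def _merge_intervals(intervals):
    merged = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return merged


def build_pool(region_bed, genome, piece_length: int, bin_width: float = 1.0) -> GenomicPool:
    """Tile merged BED regions into a fixed-length background pool.

    Overlapping or abutting regions are merged, each merged region is cut
    left-to-right into non-overlapping ``piece_length`` pieces and the
    remainder is discarded.  Sequences are sliced from ``genome`` (path or
    open :class:`pyfaidx.Fasta`).
    """
    from pyfaidx import Fasta

    if piece_length <= 0:
        raise ValueError("piece_length must be positive")
    intervals = []
    with open(region_bed) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{region_bed}:{lineno}: not a BED interval") from exc
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    sequences: dict[str, str] = {}
    for chrom, start, end in _merge_intervals(intervals):
        if chrom not in fasta:
            logger.warning("pool region on %s absent from FASTA; skipped", chrom)
            continue
        for k in range((end - start) // piece_length):
            s = start + k * piece_length
            seq = str(fasta[chrom][s : s + piece_length]).upper()
            sequences[f"{chrom}:{s}-{s + piece_length}"] = seq
    if not sequences:
        raise ValueError(f"no pool region yields a full {piece_length} bp piece")
    return GenomicPool(sequences, piece_length, bin_width)


def pool_from_sequences(sequences: dict[str, str], bin_width: float = 1.0) -> GenomicPool:
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError(f"pool sequences must share one length, got {sorted(lengths)}")
    return GenomicPool(dict(sequences), lengths.pop(), bin_width)


@dataclass
class BackgroundSet:
    sequences: dict[str, str]
    model: str
    parameters: dict
    pairing: dict[str, list[str]]  # target id -> background id(s)


def shuffle_mono(sequence: str, rng: np.random.Generator) -> str:
    """Uniformly random permutation of the characters."""
    chars = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return rng.permutation(chars).tobytes().decode("ascii")


def shuffle_di(sequence: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle via a uniform random Eulerian path.

    The sequence is viewed as an Eulerian path in the multigraph whose
    vertices are symbols (A, C, G, T, and N as a fifth symbol) and whose
    edges are the overlapping dinucleotides.  A uniform random Eulerian
    path with the same start and end vertex is constructed by drawing a
    random last-exit edge per vertex until those last edges form an
    arborescence toward the end vertex, then walking randomly ordered
    remaining edges.  All 16 (25 with N) overlapping pair counts, the
    length, and the first and last characters are preserved exactly.
    """
    if len(sequence) < 2:
        return sequence
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)!r}")
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(sequence, sequence[1:]):
        edges[a].append(b)
    start, end = sequence[0], sequence[-1]
    vertices = list(edges)
    if all(len(set(edges[v])) == 1 for v in vertices):
        # single forced successor everywhere -> unique Eulerian sequence
        return sequence
    # choose random last-exit edges forming an arborescence toward `end`
    while True:
        # the walk terminates at `end`, which therefore gets no last-exit edge
        last_exit = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != end
        }
        if _is_arborescence(last_exit, end, vertices):
            break
    out = [start]
    remaining = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_exit:
            pool.remove(last_exit[v])
        order = rng.permutation(len(pool))
        remaining[v] = [pool[i] for i in order]
    cursor = start
    while True:
        rem = remaining.get(cursor)
        if rem:
            nxt = rem.pop()
        elif last_exit.get(cursor) is not None:
            nxt = last_exit[cursor]
            last_exit[cursor] = None
        else:
            break
        out.append(nxt)
        cursor = nxt
    return "".join(out)


def _is_arborescence(last_exit: dict[str, str], root: str, vertices) -> bool:
    for v in vertices:
        if v == root and v not in last_exit:
            continue
        seen = {v}
        cur = v
        while cur != root:
            cur = last_exit.get(cur)
            if cur is None or cur in seen:
                return False
            seen.add(cur)
    return True


def shuffle_windows(
    sequence: str,
    unit: str,
    window: int = 100,
    step: int = 50,
    rng: np.random.Generator | None = None,
) -> str:
    """Shuffle successive windows in place with the chosen unit.

    Windows start every ``step`` bp; with ``step < window`` later windows
    re-shuffle the overlap, mixing composition locally while leaving the
    large-scale composition profile intact.  The final partial window is
    shuffled as-is.
    """
    if unit not in ("mono", "di"):
        raise ValueError(f"unit must be 'mono' or 'di', got {unit!r}")
    if step > window or step <= 0:
        raise ValueError("require 0 < step <= window")
    rng = np.random.default_rng() if rng is None else rng
    if window > len(sequence):
        logger.warning("window %d > sequence length %d; whole-sequence shuffle", window, len(sequence))
        window = len(sequence)
    shuffle = shuffle_mono if unit == "mono" else shuffle_di
    chars = list(sequence)
    starts = list(range(0, max(len(sequence) - window, 0) + 1, step))
    if starts[-1] + window < len(sequence):
        starts.append(starts[-1] + step)
    for s in starts:
        seg = "".join(chars[s : s + window])
        chars[s : s + window] = shuffle(seg, rng)
    return "".join(chars)


def match_gc(
    targets: dict[str, str],
    pool: GenomicPool,
    bin_width: float = 1.0,
    multiple: int = 1,
    rng: np.random.Generator | None = None,
) -> BackgroundSet:
    """Draw pool members matching each target's global GC content.

    For each target, ``multiple`` members are drawn without replacement
    from the target's GC percent bin; when the bin is exhausted the
    nearest non-empty bin is used (ties broken toward lower GC) and the
    substitution is counted.
    """
    if not pool.sequences:
        raise ValueError("empty pool")
    rng = np.random.default_rng() if rng is None else rng
    available = {b: list(ids) for b, ids in pool.gc_index.items()}
    chosen: dict[str, list[str]] = {}
    substitutions = 0
    for tid, seq in targets.items():
        want = _gc_bin(gc_fraction(seq), bin_width)
        picks = []
        for _ in range(multiple):
            bins = [b for b, ids in available.items() if ids]
            if not bins:
                raise ValueError("pool exhausted before all targets matched")
            best = min(bins, key=lambda b: (abs(b - want), b))
            if best != want:
                substitutions += 1
            ids = available[best]
            picks.append(ids.pop(int(rng.integers(len(ids)))))
        chosen[tid] = picks
    if substitutions:
        logger.info("match_gc: %d draws fell back to a neighbouring GC bin", substitutions)
    sequences = {bid: pool.sequences[bid] for picks in chosen.values() for bid in picks}
    return BackgroundSet(
        sequences,
        "gc_match",
        {"bin_width": bin_width, "multiple": multiple, "substitutions": substitutions},
        chosen,
    )


def match_gc_windows(
    targets: dict[str, str],
    pool: GenomicPool,
    window: int = 100,
    step: int = 50,
    bin_width: float = 1.0,
    multiple: int = 1,
    rng: np.random.Generator | None = None,
) -> BackgroundSet:
    """Match pool members on the profile of window GC values.

    Candidates within ``bin_width`` percentage points of the target's
    global GC are ranked by Euclidean distance between window-GC vectors;
    the closest unused candidate wins (ties broken by id).  Falls back to
    the globally closest window profile when no candidate sits within the
    GC band.
    """
    if not pool.sequences:
        raise ValueError("empty pool")
    rng = np.random.default_rng() if rng is None else rng
    profiles = {sid: window_gc_profile(s, window, step) for sid, s in pool.sequences.items()}
    global_gc = {sid: gc_fraction(s) for sid, s in pool.sequences.items()}
    used: set[str] = set()
    chosen: dict[str, list[str]] = {}
    for tid, seq in targets.items():
        tprof = window_gc_profile(seq, window, step)
        tgc = gc_fraction(seq)
        picks = []
        for _ in range(multiple):
            cands = [
                sid
                for sid in pool.sequences
                if sid not in used and abs(global_gc[sid] - tgc) * 100.0 <= bin_width
            ]
            if not cands:
                cands = [sid for sid in pool.sequences if sid not in used]
            if not cands:
                raise ValueError("pool exhausted before all targets matched")
            best = min(
                cands,
                key=lambda sid: (float(np.linalg.norm(profiles[sid] - tprof)), sid),
            )
            used.add(best)
            picks.append(best)
        chosen[tid] = picks
    sequences = {bid: pool.sequences[bid] for picks in chosen.values() for bid in picks}
    return BackgroundSet(
        sequences,
        "gc_match_window",
        {"window": window, "step": step, "bin_width": bin_width, "multiple": multiple},
        chosen,
    )


def markov_background(
    targets: dict[str, str],
    order: int = 3,
    rng: np.random.Generator | None = None,
) -> BackgroundSet:
    """Generate one background per target from a k-th order Markov chain.

    Transition probabilities are estimated from (order+1)-mer counts over
    the target strand as given (single strand), with add-one smoothing;
    the initial state is drawn from the observed k-mer distribution.  A
    3rd-order model (trained on 4 bp words) matches local composition
    without memorising whole binding sites, which higher orders would.
    K-mers containing ambiguous bases are excluded from training and never
    emitted.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    k = order
    total_len = sum(len(s) for s in targets.values())
    if total_len < 4 ** (k + 1):
        logger.warning(
            "markov_background: %d bp of training data for order %d (< 4^%d); estimates will be coarse",
            total_len,
            k,
            k + 1,
        )
    n_states = 4**k
    counts = np.ones((n_states, 4))  # add-one smoothing
    init_counts = np.zeros(n_states)
    pow4 = 4 ** np.arange(k - 1, -1, -1) if k else np.array([], dtype=int)
    for seq in targets.values():
        codes = encode_sequence(seq)
        valid = codes < 4
        for i in range(len(codes) - k):
            if not valid[i : i + k + 1].all():
                continue
            state = int(codes[i : i + k] @ pow4) if k else 0
            counts[state, codes[i + k]] += 1
            init_counts[state] += 1
    trans = counts / counts.sum(axis=1, keepdims=True)
    if init_counts.sum() == 0:
        init_counts[:] = 1.0
    init_p = init_counts / init_counts.sum()
    sequences: dict[str, str] = {}
    pairing: dict[str, list[str]] = {}
    bases = np.array(list("ACGT"))
    for tid, seq in targets.items():
        L = len(seq)
        out = np.empty(L, dtype="<U1")
        if k == 0:
            out[:] = bases[rng.choice(4, size=L, p=trans[0])]
        else:
            state = int(rng.choice(n_states, p=init_p))
            # emit the initial k-mer from the state index
            for j in range(k - 1, -1, -1):
                if j < L:
                    out[j] = bases[(state // int(4 ** (k - 1 - j))) % 4]
            pos = min(k, L)
            while pos < L:
                nxt = int(rng.choice(4, p=trans[state]))
                out[pos] = bases[nxt]
                state = (state * 4 + nxt) % n_states
                pos += 1
        bid = f"{tid}_markov{k}"
        sequences[bid] = "".join(out[:L])
        pairing[tid] = [bid]
    return BackgroundSet(sequences, "markov", {"order": order}, pairing)


def generate_background(
    targets: dict[str, str],
    model: str,
    pool: GenomicPool | None = None,
    window: int = 100,
    step: int = 50,
    bin_width: float = 1.0,
    order: int = 3,
    multiple: int = 1,
    seed: int | None = None,
) -> BackgroundSet:
    """Dispatch to one of the background models by name."""
    rng = np.random.default_rng(seed)
    if model in ("gc_match", "gc_match_window"):
        if pool is None:
            raise ValueError(f"model {model!r} requires a genomic pool")
        if model == "gc_match":
            return match_gc(targets, pool, bin_width, multiple, rng)
        return match_gc_windows(targets, pool, window, step, bin_width, multiple, rng)
    if model == "markov":
        return markov_background(targets, order, rng)
    if model not in ("mono_shuffle", "di_shuffle", "mono_shuffle_window", "di_shuffle_window"):
        raise ValueError(f"unknown background model {model!r}; expected one of {MODELS}")
    sequences: dict[str, str] = {}
    pairing: dict[str, list[str]] = {}
    for tid, seq in targets.items():
        ids = []
        for j in range(multiple):
            if model == "mono_shuffle":
                bg = shuffle_mono(seq, rng)
            elif model == "di_shuffle":
                bg = shuffle_di(seq, rng)
            elif model == "mono_shuffle_window":
                bg = shuffle_windows(seq, "mono", window, step, rng)
            else:
                bg = shuffle_windows(seq, "di", window, step, rng)
            bid = f"{tid}_{model}_{j}"
            sequences[bid] = bg
            ids.append(bid)
        pairing[tid] = ids
    params = {"window": window, "step": step, "multiple": multiple, "seed": seed}
    return BackgroundSet(sequences, model, params, pairing)
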