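"""Synthetic peak, pool and motif data with recorded ground truth.

Every generator here emulates a feature of real ChIP-Seq analysis inputs
so the rest of the package can be exercised with known answers:

* a genomic background pool with a controllable per-sequence GC
  distribution (standing in for mappable / DNase-accessible region pools),
* fixed-length peak collections in which a known fraction of peaks carry
  one PFM-sampled binding site at a controlled signed offset from the
  peakMax (the directly-bound fraction the zone heuristic should recover),
* peak collections with a planted secondary motif at controlled spacing,
* GC-biased foreground/background pairs with *no* planted motifs, which
  reproduce composition-driven over-representation bias.

All generators are driven by a single :class:`numpy.random.Generator`
seed and are byte-reproducible.  Truth tables record exactly what was
planted where.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import GenomicPool, pool_from_sequences
from .motifs import PositionFrequencyMatrix, pfm_to_pwm, relative_score
from .peaks import Peak, PeakSet

__all__ = [
    "SyntheticTruth",
    "make_pool",
    "sample_site",
    "make_peak_dataset",
    "make_bimotif_dataset",
    "make_gc_biased_collection",
    "gc_spanning_pfms",
    "example_pfm",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SyntheticTruth:
    """What was planted: one row per peak plus collection-level parameters."""

    per_peak: pd.DataFrame
    parameters: dict = field(default_factory=dict)

    @property
    def direct_fraction(self) -> float:
        return float(self.per_peak["has_planted_motif"].mean())


def _random_bases(rng: np.random.Generator, n: int, length: int, gc) -> np.ndarray:
    """(n, length) base matrix; ``gc`` is a scalar or per-sequence vector."""
    gc = np.broadcast_to(np.asarray(gc, dtype=float), (n,))
    # P(base) given gc: A and T share (1-gc)/2, C and G share gc/2
    u = rng.random((n, length))
    p = np.empty((n, 4))
    p[:, 0] = (1 - gc) / 2  # A
    p[:, 1] = gc / 2  # C
    p[:, 2] = gc / 2  # G
    p[:, 3] = (1 - gc) / 2  # T
    cum = np.cumsum(p, axis=1)
    idx = (u[..., None] > cum[:, None, :]).sum(axis=-1)
    return _BASES[idx]


def _draw_gc(rng: np.random.Generator, n: int, gc_law) -> np.ndarray:
    """Per-sequence GC values from a (kind, *params) law."""
    kind, *params = gc_law
    if kind == "fixed":
        return np.full(n, float(params[0]))
    if kind == "beta":
        a, b = params
        if a <= 0 or b <= 0:
            raise ValueError(f"beta parameters must be positive, got {gc_law}")
        return rng.beta(a, b, size=n)
    if kind == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size=n)
    raise ValueError(f"unknown gc law {gc_law!r}")


def make_pool(
    n: int, length: int, gc_law=("uniform", 0.2, 0.8), seed: int | None = None
) -> GenomicPool:
    """I.i.d. pool sequences whose per-sequence GC follows ``gc_law``."""
    if n <= 0 or length <= 0:
        raise ValueError("n and length must be positive")
    rng = np.random.default_rng(seed)
    gc = _draw_gc(rng, n, gc_law)
    mat = _random_bases(rng, n, length, gc)
    seqs = {f"pool_{i:06d}": "".join(row) for i, row in enumerate(mat)}
    return pool_from_sequences(seqs)


def sample_site(
    pfm: PositionFrequencyMatrix,
    rng: np.random.Generator,
    min_site_score: float = 0.0,
    max_attempts: int = 5000,
) -> tuple[str, float]:
    """Draw one binding site from the PFM's column distributions.

    Each column's base is sampled from the normalized counts; draws are
    rejected until the site's relative score reaches
    ``min_site_score``.
    """
    pwm = pfm_to_pwm(pfm)
    probs = pfm.column_probabilities()
    for _ in range(max_attempts):
        idx = [int(rng.choice(4, p=probs[:, j])) for j in range(pfm.width)]
        site = "".join(_BASES[idx])
        score = relative_score(pwm, site)
        if score >= min_site_score:
            return site, score
    raise RuntimeError(
        f"no site reached score {min_site_score} in {max_attempts} draws; lower min_site_score"
    )


def _placement_offsets(rng: np.random.Generator, n: int, placement) -> np.ndarray:
    kind, param = placement
    if kind == "uniform":
        return rng.integers(-int(param), int(param) + 1, size=n)
    if kind == "normal":
        return np.round(rng.normal(0.0, float(param), size=n)).astype(int)
    raise ValueError(f"unknown placement law {placement!r}")


def make_peak_dataset(
    n: int,
    pfm: PositionFrequencyMatrix,
    f: float = 0.6,
    length: int = 1001,
    placement=("uniform", 100),
    min_site_score: float = 90.0,
    gc: float = 0.40,
    seed: int | None = None,
    chrom: str = "chrS",
) -> tuple[PeakSet, dict[str, str], SyntheticTruth]:
    """Peak collection with a planted site in a fraction ``f`` of peaks.

    The site's *center* offset from the peakMax (the sequence center) is
    drawn from ``placement`` — ``("uniform", d)`` for Uniform(-d, d) or
    ``("normal", sigma)`` — on a random strand; the remaining peaks are
    pure background with genome-like GC (default 0.40).  Peaks are laid
    out non-overlapping on a synthetic chromosome with peakMax at the
    center, mirroring summit-normalized real data.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    if length % 2 == 0:
        raise ValueError("length must be odd")
    rng = np.random.default_rng(seed)
    w = pfm.width
    half = (length - 1) // 2
    kind, param = placement
    if kind == "uniform" and int(param) + w // 2 + w > half:
        raise ValueError("placement range would push sites outside the sequence")
    mat = _random_bases(rng, n, length, gc)
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=int(round(f * n)), replace=False)] = True
    offsets = np.full(n, np.nan)
    scores = np.full(n, np.nan)
    strands = np.full(n, "", dtype=object)
    which = np.flatnonzero(planted)
    offs = _placement_offsets(rng, which.size, placement)
    for i, off in zip(which, offs):
        site, score = sample_site(pfm, rng, min_site_score)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            site = site.translate(_COMPLEMENT)[::-1]
        start = half + int(off) - w // 2  # site center lands at center + off
        start = int(np.clip(start, 0, length - w))
        mat[i, start : start + w] = list(site)
        offsets[i], scores[i], strands[i] = off, score, strand
    ids = [f"peak_{i:05d}" for i in range(n)]
    seqs = {pid: "".join(row) for pid, row in zip(ids, mat)}
    gap = length + 100
    peaks = PeakSet(
        [
            Peak(chrom, i * gap, i * gap + length, peak_max=i * gap + half, id=pid)
            for i, pid in enumerate(ids)
        ],
        length=length,
        provenance={"generator": "make_peak_dataset", "seed": seed},
    )
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "peak_id": ids,
                "has_planted_motif": planted,
                "planted_offset": offsets,
                "planted_score": scores,
                "planted_strand": strands,
            }
        ),
        parameters={
            "n": n,
            "f": f,
            "length": length,
            "placement": list(placement),
            "min_site_score": min_site_score,
            "gc": gc,
            "pfm": pfm.matrix_id,
            "seed": seed,
        },
    )
    return peaks, seqs, truth


def make_bimotif_dataset(
    n: int,
    pfm1: PositionFrequencyMatrix,
    pfm2: PositionFrequencyMatrix,
    spacing: int = 20,
    jitter: int = 0,
    length: int = 1001,
    min_site_score: float = 90.0,
    gc: float = 0.40,
    seed: int | None = None,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Plant a primary site at the peakMax and a second site ``spacing`` bp away.

    The signed center-to-center spacing gets integer jitter drawn from
    Uniform(-jitter, jitter).  ``pfm1 is pfm2`` exercises the homotypic
    mode.  Raises when the geometry cannot fit both sites without overlap.
    """
    rng = np.random.default_rng(seed)
    w1, w2 = pfm1.width, pfm2.width
    min_gap = (w1 + w2) / 2 - min(w1, w2) // 5
    if abs(spacing) - jitter < min_gap:
        raise ValueError(
            f"spacing {spacing} (jitter {jitter}) cannot keep a {w1} bp and a {w2} bp site from overlapping"
        )
    half = (length - 1) // 2
    if abs(spacing) + jitter + w2 > half:
        raise ValueError("second site would fall outside the sequence")
    mat = _random_bases(rng, n, length, gc)
    ids = [f"peak_{i:05d}" for i in range(n)]
    sec_offsets = np.zeros(n, dtype=int)
    for i in range(n):
        site1, _ = sample_site(pfm1, rng, min_site_score)
        site2, _ = sample_site(pfm2, rng, min_site_score)
        off2 = spacing + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
        s1 = half - w1 // 2
        s2 = half + off2 - w2 // 2
        mat[i, s1 : s1 + w1] = list(site1)
        mat[i, s2 : s2 + w2] = list(site2)
        sec_offsets[i] = off2
    seqs = {pid: "".join(row) for pid, row in zip(ids, mat)}
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "peak_id": ids,
                "has_planted_motif": True,
                "planted_offset": 0,
                "secondary_offset": sec_offsets,
            }
        ),
        parameters={
            "n": n,
            "spacing": spacing,
            "jitter": jitter,
            "length": length,
            "pfm1": pfm1.matrix_id,
            "pfm2": pfm2.matrix_id,
            "seed": seed,
        },
    )
    return seqs, truth


def make_gc_biased_collection(
    n: int = 100,
    length: int = 201,
    fg_gc_law=("beta", 12, 8),
    bg_gc_law=("beta", 8, 12),
    pool_size: int | None = None,
    pool_gc_law=("uniform", 0.2, 0.8),
    seed: int | None = None,
):
    """GC-rich foreground vs genome-like background, no motifs planted.

    The foreground's mean GC (~0.60 under the default Beta(12, 8)) sits
    well above the background's (~0.40), so any over-representation run
    against the *naive* background shows composition-driven skew toward
    GC-rich profiles; drawing the background from the returned pool with
    GC matching removes the composition difference and with it the skew.
    Returns ``(fg, naive_bg, pool, truth)``.
    """
    rng = np.random.default_rng(seed)
    pool_size = 20 * n if pool_size is None else pool_size
    fg_gc = _draw_gc(rng, n, fg_gc_law)
    bg_gc = _draw_gc(rng, n, bg_gc_law)
    fg = {f"fg_{i:05d}": "".join(r) for i, r in enumerate(_random_bases(rng, n, length, fg_gc))}
    bg = {f"bg_{i:05d}": "".join(r) for i, r in enumerate(_random_bases(rng, n, length, bg_gc))}
    pool_gc = _draw_gc(rng, pool_size, pool_gc_law)
    pool_seqs = {
        f"pool_{i:06d}": "".join(r)
        for i, r in enumerate(_random_bases(rng, pool_size, length, pool_gc))
    }
    truth = SyntheticTruth(
        pd.DataFrame({"peak_id": list(fg), "has_planted_motif": False}),
        parameters={
            "n": n,
            "length": length,
            "fg_gc_law": list(fg_gc_law),
            "bg_gc_law": list(bg_gc_law),
            "pool_size": pool_size,
            "seed": seed,
        },
    )
    return fg, bg, pool_from_sequences(pool_seqs), truth


# fixed per-column deviations around the mean specificity, and uneven splits of
# the non-consensus mass: real profiles have heterogeneous columns, which gives
# the near-continuous score distribution the score-threshold heuristic relies on
_SPECIFICITY_PATTERN = (0.12, -0.05, -0.20, 0.05, -0.12, 0.00, -0.08, 0.10)
_OFFBASE_SPLITS = ((0.5, 0.3, 0.2), (0.2, 0.5, 0.3), (0.3, 0.2, 0.5))


def example_pfm(
    consensus: str = "TGACGTCA", matrix_id: str = "SYN0001", depth: int = 100, specificity: float = 0.85
) -> PositionFrequencyMatrix:
    """A synthetic PFM concentrated on ``consensus``.

    ``specificity`` is the *mean* per-column probability mass on the
    consensus base; individual columns deviate by a fixed pattern and
    the remaining mass is split unevenly over the other bases, so the
    columns are heterogeneous the way curated profiles are (and raw
    scores take many distinct values instead of a few).
    """
    counts = np.zeros((4, len(consensus)))
    for j, base in enumerate(consensus):
        s = float(np.clip(specificity + _SPECIFICITY_PATTERN[j % len(_SPECIFICITY_PATTERN)], 0.40, 0.97))
        split = _OFFBASE_SPLITS[j % len(_OFFBASE_SPLITS)]
        others = [b for b in range(4) if b != "ACGT".index(base)]
        counts["ACGT".index(base), j] = depth * s
        for b, frac in zip(others, split):
            counts[b, j] = depth * (1 - s) * frac
    return PositionFrequencyMatrix(matrix_id, np.round(counts, 1), name=f"syn_{consensus}")


def gc_spanning_pfms(width: int = 8, depth: int = 100, specificity: float = 0.70):
    """Profiles whose consensus GC content spans 0..1 in steps of 1/width.

    Used for composition-bias demonstrations: moderately specific
    profiles (default 70% mass on the consensus base) whose match rate
    in random sequence tracks the sequence's GC content.
    """
    pfms = []
    for k in range(width + 1):
        consensus = "G" * ((k + 1) // 2) + "A" * (width - k) + "C" * (k // 2)
        pfms.append(
            example_pfm(consensus, matrix_id=f"SYNGC{k:02d}", depth=depth, specificity=specificity)
        )
    return pfms
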