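"""Spatial visualization computations for motif topology in peaks.

Each view is computed as a plain data table first (exported as TSV) and
rendered with matplotlib second, so figures are reproducible from their
numbers.  "Density" means a normalized histogram at the stated bin
resolution (2 / 5 / 10 bp) rather than a kernel estimate; an optional
smoothing flag is available for multi-profile overlays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import MotifHit

__all__ = [
    "LandscapeData",
    "BiMotifData",
    "DinucProfile",
    "landscape_view",
    "bimotif_view",
    "dinuc_environment_view",
    "overlay_densities",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


def _hist_density(values: np.ndarray, bin_width: float, lo: float, hi: float):
    edges = np.arange(lo, hi + bin_width, bin_width)
    density, edges = np.histogram(values, bins=edges, density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, density


@dataclass
class LandscapeData:
    """Scatter + distance densities for the top motif of every peak."""

    points: pd.DataFrame  # peak_id, dist, rel_score
    density_all: pd.DataFrame  # dist (2 bp bins), density
    density_strong: pd.DataFrame | None  # dist (5 bp bins), density; None if no strong peak
    strong_cutoff: float
    peak_length: int

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False)


def landscape_view(
    top_hits: pd.DataFrame,
    strong_cutoff: float = 85.0,
    peak_length: int = 1001,
    make_figure: bool = True,
):
    """Motif-score landscape around the peakMax.

    ``top_hits`` holds one rank-1 hit per peak with columns ``peak_id``,
    ``dist`` (signed bp to the peakMax) and ``rel_score``.  The left
    panel scatters score against signed distance (peakMax at x = 0); the
    right panel shows the distance density of all peaks (2 bp bins) and
    of the subset whose top motif scores >= ``strong_cutoff`` (5 bp
    bins), the conventional strong-site cut-off being 85.
    """
    pts = top_hits[["peak_id", "dist", "rel_score"]].copy()
    half = peak_length // 2
    c_all, d_all = _hist_density(pts["dist"].to_numpy(), 2, -half, half)
    density_all = pd.DataFrame({"dist": c_all, "density": d_all})
    strong = pts[pts["rel_score"] >= strong_cutoff]
    if strong.empty:
        density_strong = None
    else:
        c_s, d_s = _hist_density(strong["dist"].to_numpy(), 5, -half, half)
        density_strong = pd.DataFrame({"dist": c_s, "density": d_s})
    data = LandscapeData(pts, density_all, density_strong, strong_cutoff, peak_length)
    if not make_figure:
        return data, None
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.scatter(pts["dist"], pts["rel_score"], s=4, alpha=0.4, color="#2b6ca3")
    ax1.axvline(0, color="grey", lw=0.5)
    ax1.set_xlabel("distance to peakMax (bp)")
    ax1.set_ylabel("top motif relative score")
    ax2.plot(density_all["dist"], density_all["density"], label="all peaks", color="#2b6ca3")
    if density_strong is not None:
        ax2.plot(
            density_strong["dist"],
            density_strong["density"],
            label=f"score >= {strong_cutoff:g}",
            color="#c0392b",
        )
    else:
        ax2.set_title(f"no peak reaches score {strong_cutoff:g}", fontsize=8)
    ax2.set_xlabel("distance to peakMax (bp)")
    ax2.set_ylabel("probability density")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    return data, fig


@dataclass
class BiMotifData:
    """Spacing of a second motif relative to a primary motif."""

    points: pd.DataFrame  # peak_id, x (second - primary, bp), y (primary dist to peakMax)
    histogram: pd.DataFrame  # bin_center, count at hist_resolution
    n_dropped: int  # peaks lacking a usable pair
    hist_resolution: int

    def to_tsv(self, path) -> None:
        self.points.to_csv(path, sep="\t", index=False)


def bimotif_view(
    primary_hits: dict[str, MotifHit],
    secondary_hits: dict[str, MotifHit],
    hist_resolution: int = 10,
    peak_length: int = 1001,
    make_figure: bool = True,
):
    """Inter-motif spacing view.

    For every peak with both hits, x is the second motif's center minus
    the primary's center and y the primary's distance to the peakMax.
    Homotypic (second-best of the same profile) and heterotypic (best of
    another profile) pairs use this same computation.  Because the
    scanner restricts overlap, a gap appears around x = 0.  The right
    panel is a ``hist_resolution`` bp histogram of x.
    """
    rows = []
    dropped = 0
    for pid, prim in primary_hits.items():
        sec = secondary_hits.get(pid)
        if prim is None or sec is None:
            dropped += 1
            continue
        rows.append(
            {"peak_id": pid, "x": sec.dist_to_peakmax - prim.dist_to_peakmax, "y": prim.dist_to_peakmax}
        )
    dropped += sum(1 for pid in secondary_hits if pid not in primary_hits)
    if not rows:
        raise ValueError("no peak has both a primary and a second motif")
    pts = pd.DataFrame(rows)
    half = peak_length
    edges = np.arange(
        hist_resolution * np.floor(pts["x"].min() / hist_resolution),
        hist_resolution * (np.floor(pts["x"].max() / hist_resolution) + 2),
        hist_resolution,
    )
    counts, edges = np.histogram(pts["x"], bins=edges)
    hist = pd.DataFrame({"bin_center": (edges[:-1] + edges[1:]) / 2, "count": counts})
    data = BiMotifData(pts, hist, dropped, hist_resolution)
    if not make_figure:
        return data, None
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.scatter(pts["x"], pts["y"], s=4, alpha=0.4, color="#2b6ca3")
    ax1.axhline(0, color="grey", lw=0.5)
    ax1.axvline(0, color="grey", lw=0.5)
    ax1.set_xlabel("second motif - primary motif (bp)")
    ax1.set_ylabel("primary motif to peakMax (bp)")
    ax2.bar(hist["bin_center"], hist["count"], width=hist_resolution * 0.9, color="#2b6ca3")
    ax2.set_xlabel("inter-motif distance (bp)")
    ax2.set_ylabel("peaks")
    fig.tight_layout()
    return data, fig


@dataclass
class DinucProfile:
    """Per-position dinucleotide proportions around an aligned motif."""

    matrix: pd.DataFrame  # index: 16 dinucleotides; columns: offsets from motif center
    n_sequences: int

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def dinuc_environment_view(
    sequences: dict[str, str],
    anchor_hits: dict[str, MotifHit],
    flank: int = 400,
    make_figure: bool = True,
    top_k_plot: int = 6,
):
    """Dinucleotide composition around motif-aligned sequences.

    Sequences are aligned on the anchor motif's center and oriented so
    the motif reads in one direction (minus-strand anchors are
    reverse-complemented).  At each offset p from the motif center the
    proportion of sequences whose dinucleotide starting at p equals each
    of the 16 pairs is recorded; pairs containing N are excluded from
    both numerator and denominator, and shorter flanks contribute only
    the positions they cover.
    """
    if not anchor_hits:
        raise ValueError("empty anchor set")
    offsets = np.arange(-flank, flank)  # dinucleotide starting at offset p
    counts = {dn: np.zeros(offsets.size) for dn in DINUCLEOTIDES}
    coverage = np.zeros(offsets.size)
    n_used = 0
    for pid, hit in anchor_hits.items():
        seq = sequences.get(pid)
        if seq is None or hit is None:
            continue
        center = hit.center
        if hit.strand == "-":
            seq = seq.translate(_COMPLEMENT)[::-1]
            # mirrored motif start, then the same center convention
            center = (len(seq) - hit.offset - hit.width) + hit.width // 2
        n_used += 1
        for j, p in enumerate(offsets):
            pos = center + int(p)
            if pos < 0 or pos + 2 > len(seq):
                continue
            dn = seq[pos : pos + 2]
            if "N" in dn:
                continue
            coverage[j] += 1
            counts[dn][j] += 1
    if n_used == 0:
        raise ValueError("no anchor hit matches a sequence")
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = pd.DataFrame(
            {p: {dn: (counts[dn][j] / coverage[j] if coverage[j] else 0.0) for dn in DINUCLEOTIDES}
             for j, p in enumerate(offsets)}
        )
    matrix = matrix.loc[DINUCLEOTIDES]
    data = DinucProfile(matrix, n_used)
    if not make_figure:
        return data, None
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    # plot the dinucleotides with the highest peak proportion to keep the view readable
    ranked = matrix.max(axis=1).sort_values(ascending=False).index[:top_k_plot]
    for dn in ranked:
        ax.plot(matrix.columns, matrix.loc[dn], label=dn, lw=1)
    ax.set_xlabel("position relative to motif center (bp)")
    ax.set_ylabel("proportion of sequences")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    return data, fig


def overlay_densities(curves: list[pd.DataFrame], labels: list[str], smooth: int = 0):
    """Overlay motif-to-peakMax distance densities for several profiles.

    Each curve is a DataFrame with ``dist`` and ``density`` columns (as
    produced by :func:`landscape_view`); ``smooth`` > 1 applies a moving
    average of that many bins.
    """
    if not curves:
        raise ValueError("no density curves to overlay")
    if len(curves) != len(labels):
        raise ValueError("need one label per curve")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for curve, label in zip(curves, labels):
        y = curve["density"].to_numpy()
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            y = np.convolve(y, kernel, mode="same")
        ax.plot(curve["dist"], y, label=label, lw=1)
    ax.set_xlabel("distance to peakMax (bp)")
    ax.set_ylabel("probability density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig
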