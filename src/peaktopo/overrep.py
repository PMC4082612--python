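"""Motif over-representation scoring and composition-bias diagnostics.

For each binding profile, foreground and background sequence sets are
scanned and each sequence is flagged as a *hit* when it contains at least
one placement at or above a relative-score threshold (default 85, the
conventional cut-off separating known binding sites from background).
The over-representation score is the -log10 one-tailed Fisher exact
p-value of the 2x2 table (hit / no-hit x foreground / background),
testing foreground enrichment.  Scores that overflow to infinity are
capped at ``max(500, largest finite score + 100)``.

Because the score is monotone in enrichment, it supports the bias
diagnostics even though its absolute scale is specific to this scorer:

* **skew** - the negative slope of the least-squares line of score vs
  profile GC content; a GC-mismatched background drags GC-rich (or
  AT-rich) profiles up regardless of binding, which the slope exposes.
* **top-5 recovery** - whether the ChIP'd TF's own profile ranks among
  the five largest scores.
* **non-outlier mean/SD** - the mean and SD of scores after removing
  scores above mean + 1 SD; a good background leaves most profiles near 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import PositionWeightMatrix, encode_sequence, pfm_to_pwm, score_positions

__all__ = [
    "OverrepTable",
    "BiasEvaluation",
    "sequence_has_hit",
    "score_overrepresentation",
    "cap_infinite",
    "eval_skew",
    "eval_top5",
    "eval_nonoutlier",
    "evaluate_bias",
    "cb_plot",
]


@dataclass
class OverrepTable:
    """Per-profile over-representation scores plus profile GC content."""

    rows: pd.DataFrame  # pfm_id, pfm_gc, fg_hit_seqs, fg_total, bg_hit_seqs, bg_total, score
    chipped_tf_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"pfm_id", "pfm_gc", "score"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"OverrepTable missing columns: {sorted(missing)}")

    def ranked(self) -> pd.DataFrame:
        """Rows sorted by score descending, ties broken by id for determinism."""
        return self.rows.sort_values(["score", "pfm_id"], ascending=[False, True], kind="mergesort")

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, chipped_tf_ids=()) -> "OverrepTable":
        return cls(pd.read_csv(path, sep="\t"), tuple(chipped_tf_ids))


@dataclass
class BiasEvaluation:
    skew: float
    top5_contains_chipped: bool
    nonoutlier_mean: float
    nonoutlier_sd: float


def sequence_has_hit(pwm: PositionWeightMatrix, sequence: str, rel_threshold: float) -> bool:
    """True when any offset on either strand scores >= rel_threshold."""
    if len(sequence) < pwm.width:
        return False
    raw = score_positions(pwm, encode_sequence(sequence))
    return bool(pwm.rel_from_raw(raw).max() >= rel_threshold)


def _hit_count(pwm, sequences, rel_threshold) -> int:
    return sum(sequence_has_hit(pwm, s, rel_threshold) for s in sequences)


def score_overrepresentation(
    pfms,
    fg_seqs: dict[str, str],
    bg_seqs: dict[str, str],
    rel_threshold: float = 85.0,
    chipped_tf_ids=(),
) -> OverrepTable:
    """Fisher-based enrichment score for each profile, capped.

    ``pfms`` is an iterable of PFMs (converted with default uniform
    background) or ready PWMs.
    """
    if not (0.0 <= rel_threshold <= 100.0):
        raise ValueError(f"rel_threshold must be in [0, 100], got {rel_threshold}")
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must be non-empty")
    fg = list(fg_seqs.values())
    bg = list(bg_seqs.values())
    records = []
    for pfm in pfms:
        if isinstance(pfm, PositionWeightMatrix):
            pwm, gc = pfm, float("nan")
        else:
            pwm, gc = pfm_to_pwm(pfm), pfm.gc_content
        fg_hits = _hit_count(pwm, fg, rel_threshold)
        bg_hits = _hit_count(pwm, bg, rel_threshold)
        p = fisher_one_tailed(fg_hits, len(fg) - fg_hits, bg_hits, len(bg) - bg_hits)
        score = -math.log10(p) if p > 0 else math.inf
        records.append(
            {
                "pfm_id": pwm.matrix_id,
                "pfm_gc": gc,
                "fg_hit_seqs": fg_hits,
                "fg_total": len(fg),
                "bg_hit_seqs": bg_hits,
                "bg_total": len(bg),
                "score": score,
            }
        )
    rows = pd.DataFrame.from_records(records)
    rows["score"] = cap_infinite(rows["score"].to_numpy())
    return OverrepTable(rows, tuple(chipped_tf_ids))


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """One-tailed Fisher exact p for enrichment of the first row.

    Table rows are (hit, no-hit) for foreground ``(a, b)`` and background
    ``(c, d)``; the alternative is a greater foreground hit proportion.
    """
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def cap_infinite(scores) -> np.ndarray:
    """Replace infinite scores by ``max(500, max finite score + 100)``.

    Idempotent and order-independent; finite entries pass through.  When
    every entry is infinite the cap degenerates to 500.
    """
    scores = np.asarray(scores, dtype=float)
    infinite = np.isinf(scores)
    if not infinite.any():
        return scores
    finite = scores[~infinite]
    max_finite = float(finite.max()) if finite.size else 0.0
    if not finite.size:
        warnings.warn("all over-representation scores infinite; capped at 500")
    out = scores.copy()
    out[infinite] = max(500.0, max_finite + 100.0)
    return out


def eval_skew(table: OverrepTable) -> float:
    """Negative slope of the least-squares fit of score on profile GC."""
    x = table.rows["pfm_gc"].to_numpy(dtype=float)
    y = table.rows["score"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        warnings.warn("skew undefined: all profiles share one GC content")
        return float("nan")
    slope = stats.linregress(x, y).slope
    return -float(slope)


def eval_top5(table: OverrepTable, top_n: int = 5) -> bool:
    """True when any ChIP'd-TF profile ranks in the ``top_n`` scores."""
    if not table.chipped_tf_ids:
        raise ValueError("no ChIP'd TF profile ids set on the table")
    top = table.ranked().head(top_n)["pfm_id"]
    return bool(set(top) & set(table.chipped_tf_ids))


def eval_nonoutlier(table: OverrepTable) -> tuple[float, float]:
    """Mean and SD after removing scores above mean + 1 SD of all scores."""
    scores = table.rows["score"].to_numpy(dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 scores")
    cut = scores.mean() + scores.std(ddof=1)
    kept = scores[scores <= cut]
    if kept.size == 0:
        raise ValueError("no scores remain below mean + 1 SD")
    sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    return float(kept.mean()), sd


def evaluate_bias(table: OverrepTable) -> BiasEvaluation:
    mean, sd = eval_nonoutlier(table)
    return BiasEvaluation(eval_skew(table), eval_top5(table), mean, sd)


def cb_plot(
    table: OverrepTable,
    top_n_labels: int = 5,
    reference_line: float = 100.0,
    ax=None,
    tsv_path=None,
):
    """Composition-bias scatter of score against profile GC content.

    The ``top_n_labels`` highest-scoring profiles are annotated, a dotted
    horizontal reference line is drawn at ``reference_line`` (an arbitrary
    visual anchor), and the skew is printed in the title.  Returns the
    matplotlib axes; the underlying numbers are written as TSV when
    ``tsv_path`` is given.
    """
    import matplotlib.pyplot as plt

    if table.rows.empty:
        raise ValueError("empty over-representation table")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    rows = table.rows
    ax.scatter(rows["pfm_gc"], rows["score"], s=14, color="#2b6ca3", zorder=3)
    ax.axhline(reference_line, linestyle=":", color="grey", zorder=1)
    for _, row in table.ranked().head(top_n_labels).iterrows():
        ax.annotate(str(row["pfm_id"]), (row["pfm_gc"], row["score"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    skew = eval_skew(table)
    ax.set_xlabel("profile GC content")
    ax.set_ylabel("over-representation score")
    ax.set_title(f"Composition-bias plot (skew = {skew:.1f})", fontsize=10)
    if tsv_path is not None:
        table.to_tsv(tsv_path)
    return ax
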