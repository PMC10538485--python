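"""Recent-coalescence enrichment statistic for selective-sweep scanning.

A recent positive sweep forces carrier haplotypes to coalesce shortly before
the present, so the distribution of pairwise TMRCAs at the swept locus is
enriched for very recent times.  The scan statistic is simply the fraction
of haplotype pairs whose posterior-mean TMRCA falls below a threshold of T
generations, optionally averaged over a window around the focal position.
Detection performance is summarized by standard ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .engine import PosteriorTrack

__all__ = [
    "ScanConfig",
    "DEFAULT_THRESHOLDS",
    "recent_fraction",
    "recent_fraction_profile",
    "windowed_statistic",
    "evaluate_detection",
    "rank_windows",
]

#: threshold grid in generations used throughout the sweep evaluation
DEFAULT_THRESHOLDS = (500, 1000, 2000, 3000, 4000, 5000,
                      10_000, 20_000, 50_000, 100_000, 500_000)


@dataclass
class ScanConfig:
    """Thresholds (generations) and window sizes (bp) for the scan."""

    thresholds: Tuple[int, ...] = DEFAULT_THRESHOLDS
    windows: Tuple[int, ...] = (0, 10_000, 100_000)
    Ne: float = 15_000.0
    generation_time: float = 30.0

    def __post_init__(self) -> None:
        t = list(self.thresholds)
        if any(x <= 0 for x in t) or t != sorted(t):
            raise ValueError("thresholds must be positive and ascending")
        if any(w < 0 for w in self.windows):
            raise ValueError("windows must be non-negative")

    def threshold_from_years(self, years: float) -> float:
        return years / self.generation_time


def _means_matrix(tracks: Sequence[PosteriorTrack]) -> Tuple[np.ndarray, np.ndarray]:
    if not tracks:
        raise ValueError("no pairs provided")
    positions = tracks[0].positions
    for t in tracks[1:]:
        if not np.array_equal(t.positions, positions):
            raise ValueError("all tracks must share the same output positions")
    gens = np.stack([t.mean_generations for t in tracks])
    return positions, gens


def recent_fraction(tracks: Sequence[PosteriorTrack], T: float, position: int) -> float:
    """Fraction of pairs with posterior-mean TMRCA below T generations at a position."""
    positions, gens = _means_matrix(tracks)
    idx = np.searchsorted(positions, position)
    if idx >= len(positions) or positions[idx] != position:
        raise ValueError(f"position {position} is not an output position")
    return float((gens[:, idx] < T).mean())


def recent_fraction_profile(tracks: Sequence[PosteriorTrack], T: float) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position fraction of pairs more recent than T generations."""
    positions, gens = _means_matrix(tracks)
    return positions, (gens < T).mean(axis=0)


def windowed_statistic(fractions: np.ndarray, positions: np.ndarray,
                       W: int, focal: int) -> float:
    """Mean of per-position fractions within [focal - W/2, focal + W/2].

    ``W = 0`` returns the value at the output position nearest the focal
    coordinate.
    """
    positions = np.asarray(positions)
    fractions = np.asarray(fractions)
    if W == 0:
        idx = int(np.argmin(np.abs(positions - focal)))
        return float(fractions[idx])
    inside = (positions >= focal - W / 2) & (positions <= focal + W / 2)
    if not inside.any():
        raise ValueError(f"no output positions within {W} bp window around {focal}")
    return float(fractions[inside].mean())


def evaluate_detection(selected_scores: Sequence[float],
                       neutral_scores: Sequence[float]) -> Tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC for separating selected from neutral replicates.

    Returns (fpr, tpr, auc); higher scores are treated as more selected.
    """
    selected_scores = np.asarray(selected_scores, dtype=float)
    neutral_scores = np.asarray(neutral_scores, dtype=float)
    if len(selected_scores) == 0 or len(neutral_scores) == 0:
        raise ValueError("need at least one score in each class")
    from sklearn.metrics import roc_curve, auc

    y = np.concatenate([np.ones(len(selected_scores)), np.zeros(len(neutral_scores))])
    s = np.concatenate([selected_scores, neutral_scores])
    fpr, tpr, _ = roc_curve(y, s)
    return fpr, tpr, float(auc(fpr, tpr))


def rank_windows(tracks: Sequence[PosteriorTrack], threshold_gen: float,
                 window: int = 100_000, top_quantile: float = 0.001):
    """Genome-scan mode: rank non-overlapping windows by the recent fraction.

    Returns a DataFrame with one row per window (start, end, statistic) and a
    boolean ``candidate`` column marking the top ``top_quantile`` windows.
    """
    import pandas as pd

    positions, prof = recent_fraction_profile(tracks, threshold_gen)
    if window <= 0:
        raise ValueError("window must be positive for a genome scan")
    start = int(positions.min()) // window * window
    stop = int(positions.max()) + 1
    rows = []
    for w0 in range(start, stop, window):
        inside = (positions >= w0) & (positions < w0 + window)
        if inside.any():
            rows.append((w0, w0 + window, float(prof[inside].mean())))
    df = pd.DataFrame(rows, columns=["start", "end", "statistic"])
    cut = df["statistic"].quantile(1.0 - top_quantile)
    df["candidate"] = df["statistic"] >= cut
    return df.sort_values("statistic", ascending=False).reset_index(drop=True)
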