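"""Clonal-expansion calls at a fixed frequency threshold.

A clonotype is *expanded* when its within-sample frequency strictly exceeds
the threshold (default 1/1,000) — "exceeding" is a strict inequality, so a
clone at exactly the threshold is not expanded.  The expanded *proportion*
is taken over unique clonotypes (richness), matching a pie chart over TCR
sequences rather than reads; a read-weighted variant is exposed separately
as :func:`expanded_read_fraction`.

Expansion is computed on full-sample frequencies by default: under pure
subsampling the expected frequency of every clone is unchanged, so the call
is depth-invariant in expectation.  :func:`threshold_curve` additionally
supports a subsampled mode (per-iterate counts summarized across iterations)
for strict comparability across depth-matched samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Union

import numpy as np

from .depth_matching import IterateSummary, SubsampleSpec, iterate_subsamples, summarize_iterates
from .repertoire import KeyMode, Repertoire

DEFAULT_EXPANSION_THRESHOLD = 1.0 / 1000.0


def _check_threshold(threshold: float) -> None:
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"expansion threshold must lie in (0, 1), got {threshold}")


@dataclass(frozen=True)
class ExpansionResult:
    """Expanded clonotypes of one repertoire at one frequency threshold."""

    threshold: float
    expanded: Dict[object, float]  # clonotype key -> frequency
    n_expanded: int
    richness: int
    proportion_expanded: float


def expanded_clones(
    rep: Repertoire,
    threshold: float = DEFAULT_EXPANSION_THRESHOLD,
    key_mode: Optional[KeyMode] = None,
) -> ExpansionResult:
    """Clonotypes with frequency strictly above ``threshold``.

    The proportion denominator is the number of unique clonotypes.
    """
    _check_threshold(threshold)
    if not rep.clones:
        raise ValueError(f"repertoire {rep.sample_id!r} is empty")
    freqs = rep.frequencies
    keys = rep.keys(key_mode)
    expanded = {
        key: float(f) for key, f in zip(keys, freqs) if f > threshold
    }
    return ExpansionResult(
        threshold=threshold,
        expanded=expanded,
        n_expanded=len(expanded),
        richness=rep.richness,
        proportion_expanded=len(expanded) / rep.richness,
    )


def expanded_read_fraction(
    rep: Repertoire, threshold: float = DEFAULT_EXPANSION_THRESHOLD
) -> float:
    """Fraction of *reads* carried by expanded clones (read-weighted variant)."""
    _check_threshold(threshold)
    freqs = rep.frequencies
    return float(freqs[freqs > threshold].sum())


def count_above(rep: Repertoire, threshold: float) -> int:
    """Number of clones with frequency strictly above ``threshold``."""
    return int((rep.frequencies > threshold).sum())


def threshold_curve(
    rep: Repertoire,
    thresholds: Sequence[float],
    spec: Optional[SubsampleSpec] = None,
) -> Dict[float, Union[int, IterateSummary]]:
    """Clone counts above each of a strictly increasing threshold grid.

    With ``spec`` given, counts are computed per subsample iteration and
    summarized (mean/median/min/max) per threshold; otherwise they are
    single full-sample counts.  Counts are non-increasing in threshold.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold grid is empty")
    for t in thresholds:
        _check_threshold(t)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if spec is None:
        return {t: count_above(rep, t) for t in thresholds}
    counts = np.array(
        [
            [(sub.frequencies > t).sum() for t in thresholds]
            for sub in iterate_subsamples(rep, spec)
        ]
    )
    return {
        t: summarize_iterates(counts[:, j]) for j, t in enumerate(thresholds)
    }
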