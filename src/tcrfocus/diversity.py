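"""Rényi entropy spectra and repertoire richness.

The Rényi entropy of order :math:`q` of a frequency vector :math:`p` is

.. math::

    H_q = \\frac{1}{1-q} \\ln \\sum_i p_i^q

with the limits :math:`H_0 = \\ln S` (log-richness),
:math:`H_1 = -\\sum_i p_i \\ln p_i` (Shannon) and
:math:`H_\\infty = -\\ln \\max_i p_i` (dominance of the largest clone).
Entropies are in nats (natural log) throughout, and :math:`H_q` is
non-increasing in :math:`q` for every distribution.  The limit cases are
evaluated by their own closed forms, never by numerically approaching the
order.

A profile over a grid of orders, computed on iteratively subsampled
repertoires and summarized across iterations, gives a depth-controlled
diversity spectrum: order 0 weights rare clones maximally, high orders are
dominated by the most expanded clones, so one curve lying entirely below
another means lower diversity under every weighting of the clone-size
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .depth_matching import SubsampleSpec, iterate_subsamples
from .repertoire import Repertoire

#: Default order grid: 0, 1 and infinity plus a geometric ladder in between.
DEFAULT_ORDERS = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, np.inf)

_FREQ_TOL = 1e-9


def _validated_freqs(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("frequency vector is empty")
    if np.any(p <= 0):
        raise ValueError("all frequencies must be strictly positive")
    if abs(p.sum() - 1.0) > _FREQ_TOL:
        raise ValueError(f"frequencies must sum to 1 within {_FREQ_TOL}, got {p.sum()!r}")
    return p


def renyi_entropy(freqs, order: float) -> float:
    """Rényi entropy (nats) of a frequency vector at a single order."""
    p = _validated_freqs(freqs)
    if order < 0:
        raise ValueError(f"order must be non-negative, got {order}")
    if order == 0:
        return float(np.log(p.size))
    if order == 1:
        return float(-(p * np.log(p)).sum())
    if np.isinf(order):
        return float(-np.log(p.max()))
    return float(logsumexp(order * np.log(p)) / (1.0 - order))


def renyi_spectrum(freqs, orders: Sequence[float] = DEFAULT_ORDERS) -> np.ndarray:
    """Rényi entropies at every order of a grid."""
    return np.array([renyi_entropy(freqs, q) for q in orders])


@dataclass(frozen=True)
class RenyiProfile:
    """Per-order summary of Rényi entropy across subsample iterations."""

    orders: np.ndarray
    median: np.ndarray
    mean: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray
    spec: SubsampleSpec

    @property
    def entropy_nats(self) -> np.ndarray:
        """The per-order summary value (median across iterations)."""
        return self.median


def renyi_profile(
    rep: Repertoire,
    spec: SubsampleSpec,
    orders: Sequence[float] = DEFAULT_ORDERS,
) -> RenyiProfile:
    """Rényi spectrum per subsample iteration, summarized per order.

    A repertoire of exactly ``spec.depth`` reads yields the single-shot
    spectrum with minimum = maximum.
    """
    orders = np.asarray(orders, dtype=float)
    matrix = np.empty((spec.n_iterations, orders.size))
    for i, sub in enumerate(iterate_subsamples(rep, spec)):
        matrix[i] = renyi_spectrum(sub.frequencies, orders)
    return RenyiProfile(
        orders=orders,
        median=np.median(matrix, axis=0),
        mean=matrix.mean(axis=0),
        minimum=matrix.min(axis=0),
        maximum=matrix.max(axis=0),
        spec=spec,
    )


def richness(rep: Repertoire) -> int:
    """Number of unique clonotypes in the repertoire."""
    return rep.richness
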