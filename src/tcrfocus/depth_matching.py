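"""Read-depth matching by iterative subsampling.

Diversity statistics depend strongly on sequencing depth, so paired samples
are only comparable after equalizing read counts.  The scheme implemented
here subsamples the deeper member of a pair down to the shallower member's
depth, independently in each of ``n_iterations`` iterations (default 100),
and downstream statistics are summarized across iterations.

Subsampling is *without replacement at the read level*: drawing ``depth``
reads from the observed read multiset is a multivariate hypergeometric draw
over the clone count vector.  (Bootstrap-style sampling with replacement
would be a different estimator — it inflates the variance of clone counts
and can be emulated by a multinomial draw on the frequencies — and is
deliberately not what this module does.)

Per-iteration seeds derive deterministically from
``(master seed, iteration index, sample_id)``, so a cohort run is exactly
reproducible and insensitive to the order in which pairs are processed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterator, List, NamedTuple, Sequence, Tuple

import numpy as np

from .errors import DepthError, PairingError
from .repertoire import Repertoire


@dataclass(frozen=True)
class SubsampleSpec:
    """Target depth, iteration count and master seed for iterative subsampling."""

    depth: int
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise DepthError(f"depth must be positive, got {self.depth}")
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if self.seed < 0:
            raise ValueError("master seed must be non-negative")


def iteration_seed(master_seed: int, iteration: int, sample_id: str) -> np.random.SeedSequence:
    """Deterministic per-iteration seed from (master seed, iteration, sample id)."""
    tag = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.SeedSequence(entropy=(int(master_seed), int(iteration), tag))


def subsample(rep: Repertoire, depth: int, seed) -> Repertoire:
    """Draw ``depth`` reads without replacement (multivariate hypergeometric).

    Clones drawn zero times are dropped.  ``seed`` may be an integer, a
    :class:`numpy.random.SeedSequence` or a :class:`numpy.random.Generator`.
    Drawing the full depth returns a repertoire identical to the input.
    """
    total = rep.total_reads
    if depth > total:
        raise DepthError(
            f"depth {depth} exceeds total reads {total} of {rep.sample_id!r}; "
            "subsample the deeper member of a pair, never upsample"
        )
    if depth < 1:
        raise DepthError(f"depth must be positive, got {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(rep.counts, depth)
    from dataclasses import replace

    clones = tuple(
        replace(clone, count=int(k))
        for clone, k in zip(rep.clones, drawn)
        if k > 0
    )
    return rep.with_clones(clones)


def iterate_subsamples(rep: Repertoire, spec: SubsampleSpec) -> Iterator[Repertoire]:
    """Yield ``spec.n_iterations`` independent subsamples of ``rep`` at ``spec.depth``."""
    for i in range(spec.n_iterations):
        yield subsample(rep, spec.depth, iteration_seed(spec.seed, i, rep.sample_id))


def match_pair(
    rep_a: Repertoire,
    rep_b: Repertoire,
    n_iterations: int = 100,
    seed: int = 0,
) -> List[Tuple[Repertoire, Repertoire]]:
    """Depth-match a pair: subsample the deeper member to the shallower depth.

    Returns ``n_iterations`` pairs; the shallower member passes through
    unchanged in every iterate.  Equal depths pass both through unchanged.
    """
    if not rep_a.clones or not rep_b.clones:
        raise PairingError("cannot depth-match an empty repertoire")
    if rep_a.chain != rep_b.chain:
        raise PairingError(
            f"chain mismatch: {rep_a.sample_id!r} is {rep_a.chain}, "
            f"{rep_b.sample_id!r} is {rep_b.chain}"
        )
    depth_a, depth_b = rep_a.total_reads, rep_b.total_reads
    target = min(depth_a, depth_b)
    pairs = []
    for i in range(n_iterations):
        a = (
            rep_a
            if depth_a == target
            else subsample(rep_a, target, iteration_seed(seed, i, rep_a.sample_id))
        )
        b = (
            rep_b
            if depth_b == target
            else subsample(rep_b, target, iteration_seed(seed, i, rep_b.sample_id))
        )
        pairs.append((a, b))
    return pairs


class IterateSummary(NamedTuple):
    """Summary of a statistic across subsample iterations (display mirrors
    median with min/max whiskers; the mean is reported alongside)."""

    mean: float
    median: float
    minimum: float
    maximum: float


def summarize_iterates(values: Sequence[float]) -> IterateSummary:
    """Mean, median, min and max of a per-iterate statistic."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection of iterates")
    return IterateSummary(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )
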