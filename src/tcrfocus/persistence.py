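"""Paired clonotype tracking: baseline presence of post-treatment expansions.

For a patient sampled at baseline and after transplant, the question is what
fraction of the clonotypes expanded in the post-treatment repertoire were
already present at baseline — at *any* baseline frequency, since a clone
that was rare at baseline and expanded afterwards still pre-existed.  A high
shared fraction indicates a stable, persistent repertoire in the niche; a
low one indicates repertoire turnover.

Clonotype identity can be keyed two ways: ``nt`` mode on
``(v_call, j_call, cdr3_nt)`` is clonotype-faithful; ``aa`` mode on the CDR3
amino-acid string alone is coarser and can only merge clonotypes, so the
aa-mode shared fraction is always >= the nt-mode one.  The default is nt
when nucleotide junctions are available, aa otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from .errors import PairingError
from .expansion import DEFAULT_EXPANSION_THRESHOLD, expanded_clones
from .repertoire import KeyMode, Repertoire, clonotype_key

__all__ = ["clonotype_key", "OverlapResult", "shared_expanded_fraction"]


@dataclass(frozen=True)
class OverlapResult:
    """Baseline overlap of one patient's post-treatment expanded clonotypes."""

    patient_id: str
    chain: str
    key_mode: KeyMode
    threshold: float
    n_expanded_post: int
    n_shared: int
    shared_keys: Tuple[object, ...]

    @property
    def shared_fraction(self) -> float:
        """n_shared / n_expanded_post; NaN when nothing is expanded post."""
        if self.n_expanded_post == 0:
            return math.nan
        return self.n_shared / self.n_expanded_post


def shared_expanded_fraction(
    post: Repertoire,
    baseline: Repertoire,
    mode: Optional[KeyMode] = None,
    threshold: float = DEFAULT_EXPANSION_THRESHOLD,
) -> OverlapResult:
    """Fraction of post-treatment expanded clonotypes present at baseline.

    Baseline membership is tested at any baseline frequency.  The result is
    deterministic and independent of clone ordering in either repertoire.
    """
    if post.patient_id != baseline.patient_id:
        raise PairingError(
            f"patient mismatch: {post.patient_id!r} vs {baseline.patient_id!r}"
        )
    if post.chain != baseline.chain:
        raise PairingError(f"chain mismatch: {post.chain!r} vs {baseline.chain!r}")
    if mode is None:
        mode = "nt" if (post.has_nt and baseline.has_nt) else "aa"
    result = expanded_clones(post, threshold=threshold, key_mode=mode)
    baseline_keys = set(baseline.keys(mode))
    shared = sorted(
        (key for key in result.expanded if key in baseline_keys), key=repr
    )
    return OverlapResult(
        patient_id=post.patient_id,
        chain=post.chain,
        key_mode=mode,
        threshold=threshold,
        n_expanded_post=result.n_expanded,
        n_shared=len(shared),
        shared_keys=tuple(shared),
    )
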