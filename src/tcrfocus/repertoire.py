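"""Core clonotype containers: :class:`Clone` and :class:`Repertoire`.

A clonotype is a unique rearranged T-cell receptor sequence observed in a
sample; its abundance is the number of (error-corrected) reads supporting it.
A :class:`Repertoire` is one sample's collection of clonotypes together with
identity metadata (patient, chain, timepoint). Clone frequencies
``p_i = count_i / total_reads`` are the quantity every downstream statistic
(Rényi entropy, expansion calls, persistence) is computed from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence, Tuple

import numpy as np

from .errors import KeyModeError, RepertoireError

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_LETTERS)

CHAINS = ("alpha", "beta")
TIMEPOINTS = ("BL", "postASCT", "other")

KeyMode = Literal["nt", "aa"]


@dataclass(frozen=True)
class Clone:
    """One clonotype: CDR3 amino-acid string plus optional nucleotide/gene labels.

    ``cdr3_aa`` may contain ``*`` for nonproductive junctions; such clones are
    kept at I/O time and filtered only by stages that need amino-acid sequence
    (e.g. kernel similarity).
    """

    cdr3_aa: str
    count: int
    cdr3_nt: Optional[str] = None
    v_call: Optional[str] = None
    j_call: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise RepertoireError("cdr3_aa must be a non-empty string")
        if int(self.count) < 1:
            raise RepertoireError(f"clone count must be >= 1, got {self.count}")

    @property
    def productive(self) -> bool:
        """True when the CDR3 contains no stop codon marker ('*')."""
        return "*" not in self.cdr3_aa


def clonotype_key(clone: Clone, mode: KeyMode = "aa"):
    """Identity key for a clonotype.

    ``aa`` mode keys on the CDR3 amino-acid string alone (coarse; merges
    convergent rearrangements). ``nt`` mode keys on
    ``(v_call, j_call, cdr3_nt)`` and is clonotype-faithful; it requires the
    nucleotide junction to be present.
    """
    if mode == "aa":
        return clone.cdr3_aa
    if mode == "nt":
        if clone.cdr3_nt is None:
            raise KeyModeError(
                f"nt key mode requires cdr3_nt; clone {clone.cdr3_aa!r} has none"
            )
        return (clone.v_call, clone.j_call, clone.cdr3_nt)
    raise KeyModeError(f"unknown key mode {mode!r}; expected 'nt' or 'aa'")


@dataclass
class Repertoire:
    """A sample's clonotype collection with identity metadata.

    Invariants enforced at construction: valid chain/timepoint labels and
    uniqueness of clonotype keys (under the repertoire's default key mode).
    """

    sample_id: str
    clones: Tuple[Clone, ...]
    patient_id: str = ""
    chain: str = "alpha"
    timepoint: str = "other"

    def __post_init__(self) -> None:
        self.clones = tuple(self.clones)
        if self.chain not in CHAINS:
            raise RepertoireError(f"chain must be one of {CHAINS}, got {self.chain!r}")
        if self.timepoint not in TIMEPOINTS:
            raise RepertoireError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        keys = self.keys()
        if len(set(keys)) != len(keys):
            raise RepertoireError(
                f"duplicate clonotype keys in repertoire {self.sample_id!r} "
                f"(key mode {self.default_key_mode!r}); merge counts upstream"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.clones], dtype=np.int64)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum()) if self.clones else 0

    @property
    def richness(self) -> int:
        """Number of unique clonotypes."""
        return len(self.clones)

    @property
    def frequencies(self) -> np.ndarray:
        if not self.clones:
            return np.array([], dtype=float)
        counts = self.counts
        return counts / counts.sum()

    @property
    def has_nt(self) -> bool:
        return bool(self.clones) and all(c.cdr3_nt is not None for c in self.clones)

    @property
    def default_key_mode(self) -> KeyMode:
        """'nt' when every clone carries a nucleotide junction, else 'aa'."""
        return "nt" if self.has_nt else "aa"

    def keys(self, mode: Optional[KeyMode] = None) -> list:
        mode = mode or self.default_key_mode
        return [clonotype_key(c, mode) for c in self.clones]

    # -- construction helpers ----------------------------------------------

    def with_clones(self, clones: Iterable[Clone]) -> "Repertoire":
        """Copy of this repertoire with a different clone collection."""
        return replace(self, clones=tuple(clones))

    def __len__(self) -> int:
        return len(self.clones)


def merge_clones(clones: Sequence[Clone], mode: KeyMode) -> Tuple[Clone, ...]:
    """Merge clones sharing a clonotype key, summing counts.

    First occurrence order and first occurrence's annotation fields are kept.
    """
    merged: dict = {}
    for clone in clones:
        key = clonotype_key(clone, mode)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(prev, count=prev.count + clone.count)
        else:
            merged[key] = clone
    return tuple(merged.values())
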