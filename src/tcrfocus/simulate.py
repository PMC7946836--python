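"""Synthetic single and paired bone-marrow TCR repertoires.

The generator emulates the statistical structure the analysis pipeline
assumes in real paired baseline / post-transplant data:

* heavy-tailed clone sizes — sampling weights follow a discrete power law
  (Zipf, weight of rank ``r`` proportional to ``r**-s``), the standard
  model for immune-repertoire clone-size distributions; a log-normal law
  is available behind a flag;
* a post-treatment richness bottleneck — only a fraction of baseline
  clonotypes survives the transplant;
* partial persistence of expanded clones — clonotypes above the expansion
  threshold at baseline survive with their own (typically higher)
  probability, and surviving expanded clones are preferentially boosted,
  producing the focused, lower-diversity post-transplant repertoire;
* optional planted CDR3 motif families whose members share an intact core,
  giving the kernel-similarity clustering a controlled positive signal.

CDR3 amino-acid composition is uniformly random over the 20-letter alphabet
(no positional bias), so any clustering signal is fully controlled by the
motif-family parameters.  Nucleotide junctions are produced by random
reverse translation with the standard codon table, so nt-mode clonotype
keys are well defined.  All randomness flows from a single seed.

Read counts are drawn multinomially from the clone weights conditioned on
every clone receiving at least one read via a +1 floor: each clone gets one
read and the remaining ``total_reads - n_clones`` are multinomial.  The
floor is declared in the ground-truth record (``count_floor``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data import CodonTable

from .errors import ConfigurationError
from .expansion import DEFAULT_EXPANSION_THRESHOLD
from .repertoire import AA_LETTERS, Clone, KeyMode, Repertoire, clonotype_key

_CODONS: Dict[str, List[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for codons in _CODONS.values():
    codons.sort()

SIZE_LAWS = ("zipf", "lognormal")


def _clone_weights(
    n_clones: int, zipf_exponent: float, size_law: str, rng: np.random.Generator
) -> np.ndarray:
    """Normalized clone sampling weights, sorted so rank order = clone order."""
    if size_law == "zipf":
        w = np.arange(1, n_clones + 1, dtype=float) ** (-zipf_exponent)
    elif size_law == "lognormal":
        # sigma chosen to give a comparably heavy tail; sorted descending so
        # clone index still equals abundance rank
        w = np.sort(rng.lognormal(mean=0.0, sigma=1.5, size=n_clones))[::-1]
    else:
        raise ConfigurationError(f"unknown size law {size_law!r}; expected {SIZE_LAWS}")
    return w / w.sum()


def _floored_counts(
    weights: np.ndarray, total_reads: int, rng: np.random.Generator
) -> np.ndarray:
    n = weights.size
    if total_reads < n:
        raise ConfigurationError(
            f"total_reads={total_reads} cannot cover {n} clones at one read each"
        )
    return 1 + rng.multinomial(total_reads - n, weights)


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_LETTERS[i] for i in rng.integers(0, 20, size=length))


def _reverse_translate(rng: np.random.Generator, cdr3_aa: str) -> str:
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in cdr3_aa
    )


def _gene_labels(rng: np.random.Generator, chain: str) -> Tuple[str, str]:
    prefix = "TRA" if chain == "alpha" else "TRB"
    return (
        f"{prefix}V{int(rng.integers(1, 41))}",
        f"{prefix}J{int(rng.integers(1, 51))}",
    )


def _generate_cdr3s(
    rng: np.random.Generator,
    n_clones: int,
    length_range: Tuple[int, int],
    n_motif_families: int,
    family_size: int,
    family_core_length: int,
    forbidden: FrozenSet[str] = frozenset(),
) -> Tuple[List[str], List[Optional[int]]]:
    """Unique CDR3s plus each clone's motif-family index (None = background).

    Family members are a full-length template (top of the length range, so
    single-residue variation preserves most of the triplet content) plus
    single-substitution variants outside an intact ``family_core_length``
    window; all members therefore share the implanted core, and each family
    is connected through its template at the default similarity threshold.
    Families are assigned round-robin to the top-ranked clones so that the
    planted signal lands among the expanded clones.
    """
    lo, hi = length_range
    if not (3 <= lo <= hi):
        raise ConfigurationError(f"invalid cdr3_length_range {length_range}")
    n_family_clones = n_motif_families * family_size
    if n_family_clones > n_clones:
        raise ConfigurationError(
            f"{n_motif_families} families of {family_size} exceed {n_clones} clones"
        )
    if n_motif_families and family_core_length + 2 > hi:
        raise ConfigurationError(
            "cdr3_length_range too short to implant the family core"
        )

    seen = set(forbidden)
    cdr3s: List[Optional[str]] = [None] * n_clones
    family_of: List[Optional[int]] = [None] * n_clones

    templates: List[str] = []
    core_starts: List[int] = []
    for _ in range(n_motif_families):
        while True:
            template = _random_cdr3(rng, hi)
            if template not in seen:
                break
        seen.add(template)
        templates.append(template)
        core_starts.append(int(rng.integers(0, hi - family_core_length + 1)))

    members_emitted = [0] * n_motif_families
    for idx in range(n_clones):
        if idx < n_family_clones:
            fam = idx % n_motif_families
            family_of[idx] = fam
            template = templates[fam]
            if members_emitted[fam] == 0:
                cdr3 = template
            else:
                core = range(
                    core_starts[fam], core_starts[fam] + family_core_length
                )
                positions = [p for p in range(len(template)) if p not in core]
                while True:
                    pos = positions[rng.integers(0, len(positions))]
                    letter = AA_LETTERS[rng.integers(0, 20)]
                    if letter == template[pos]:
                        continue
                    cdr3 = template[:pos] + letter + template[pos + 1 :]
                    if cdr3 not in seen:
                        break
            members_emitted[fam] += 1
        else:
            while True:
                cdr3 = _random_cdr3(rng, int(rng.integers(lo, hi + 1)))
                if cdr3 not in seen:
                    break
        seen.add(cdr3)
        cdr3s[idx] = cdr3
    return cdr3s, family_of  # type: ignore[return-value]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted alongside a single simulated repertoire."""

    weights: np.ndarray
    family_of: Dict[str, int]  # cdr3_aa -> motif family index (members only)
    count_floor: int = 1


def simulate_repertoire(
    n_clones: int,
    total_reads: int,
    zipf_exponent: float = 1.3,
    cdr3_length_range: Tuple[int, int] = (8, 20),
    n_motif_families: int = 0,
    family_size: int = 8,
    family_core_length: int = 6,
    size_law: str = "zipf",
    with_nt: bool = True,
    sample_id: str = "sim",
    patient_id: str = "SIM",
    chain: str = "alpha",
    timepoint: str = "other",
    seed=0,
    return_truth: bool = False,
):
    """Simulate one repertoire with power-law clone sizes.

    Clone ``i`` (0-based) has sampling weight proportional to
    ``(i + 1) ** -zipf_exponent``; counts are multinomial with a +1 floor so
    realized richness equals ``n_clones`` exactly.  Bit-identical output for
    a fixed seed.  With ``return_truth=True`` returns ``(Repertoire,
    SimTruth)``.
    """
    if n_clones < 1:
        raise ConfigurationError(f"n_clones must be >= 1, got {n_clones}")
    if size_law == "zipf" and not zipf_exponent > 1:
        raise ConfigurationError(
            f"zipf_exponent must exceed 1, got {zipf_exponent}"
        )
    rng = np.random.default_rng(seed)
    weights = _clone_weights(n_clones, zipf_exponent, size_law, rng)
    counts = _floored_counts(weights, total_reads, rng)
    cdr3s, family_of = _generate_cdr3s(
        rng, n_clones, cdr3_length_range, n_motif_families, family_size, family_core_length
    )
    clones = []
    for cdr3, count in zip(cdr3s, counts):
        v_call, j_call = _gene_labels(rng, chain)
        clones.append(
            Clone(
                cdr3_aa=cdr3,
                count=int(count),
                cdr3_nt=_reverse_translate(rng, cdr3) if with_nt else None,
                v_call=v_call,
                j_call=j_call,
            )
        )
    rep = Repertoire(
        sample_id=sample_id,
        clones=tuple(clones),
        patient_id=patient_id,
        chain=chain,
        timepoint=timepoint,
    )
    if not return_truth:
        return rep
    truth = SimTruth(
        weights=weights,
        family_of={c: f for c, f in zip(cdr3s, family_of) if f is not None},
    )
    return rep, truth


@dataclass(frozen=True)
class PairedSimConfig:
    """Generative parameters for one baseline / post-transplant pair.

    Defaults describe a realistic bottlenecked marrow repertoire: 5,000
    baseline clonotypes under a Zipf law with exponent 1.3 sampled at
    50,000 reads; 40% of clonotypes survive the transplant while expanded
    clones persist with probability 0.9 and are boosted 5-fold; 1,000 novel
    low-frequency clones appear post-transplant at 20,000 reads.
    """

    n_clones_bl: int = 5000
    zipf_exponent: float = 1.3
    total_reads_bl: int = 50000
    total_reads_post: int = 20000
    bottleneck: float = 0.4
    persistence_rho: float = 0.9
    expansion_boost: float = 5.0
    n_novel_post: int = 1000
    cdr3_length_range: Tuple[int, int] = (8, 20)
    n_motif_families: int = 0
    family_size: int = 8
    family_core_length: int = 6
    expansion_threshold: float = DEFAULT_EXPANSION_THRESHOLD
    size_law: str = "zipf"
    with_nt: bool = True
    patient_id: str = "SIM"
    chain: str = "alpha"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bottleneck", "persistence_rho"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.bottleneck == 0.0 and self.persistence_rho == 0.0 and self.n_novel_post == 0:
            raise ConfigurationError("post repertoire would be empty")
        if self.expansion_boost <= 0:
            raise ConfigurationError("expansion_boost must be positive")
        if self.n_novel_post < 0:
            raise ConfigurationError("n_novel_post must be >= 0")


@dataclass(frozen=True)
class PairedTruth:
    """Ground-truth record for a simulated baseline / post-transplant pair."""

    key_mode: KeyMode
    bl_expanded_keys: FrozenSet
    surviving_keys: FrozenSet
    novel_keys: FrozenSet
    post_expanded_keys: FrozenSet
    realized_persistent_expanded_fraction: float
    family_of: Dict[str, int] = field(default_factory=dict)
    count_floor: int = 1


def simulate_paired(config: PairedSimConfig) -> Tuple[Repertoire, Repertoire, PairedTruth]:
    """Simulate a paired baseline / post-transplant repertoire.

    Baseline is drawn as in :func:`simulate_repertoire`.  Each baseline
    clonotype survives the transplant with probability ``persistence_rho``
    if it was expanded at baseline (frequency > ``expansion_threshold``),
    ``bottleneck`` otherwise.  Survivors are re-ranked in their baseline
    order and reassigned weights from the same clone-size law over the
    compacted ranks — the niche left by lost clones is refilled by
    proliferation of the remainder — and surviving baseline-expanded clones
    have their weights multiplied by ``expansion_boost``.  ``n_novel_post``
    novel clonotypes (absent at baseline) take the trailing ranks, i.e.
    enter at low frequency.  Post counts use the same +1-floor multinomial.
    """
    master = np.random.SeedSequence(config.seed)
    ss_bl, ss_survival, ss_post = master.spawn(3)

    bl, bl_truth = simulate_repertoire(
        n_clones=config.n_clones_bl,
        total_reads=config.total_reads_bl,
        zipf_exponent=config.zipf_exponent,
        cdr3_length_range=config.cdr3_length_range,
        n_motif_families=config.n_motif_families,
        family_size=config.family_size,
        family_core_length=config.family_core_length,
        size_law=config.size_law,
        with_nt=config.with_nt,
        sample_id=f"{config.patient_id}_BL",
        patient_id=config.patient_id,
        chain=config.chain,
        timepoint="BL",
        seed=ss_bl,
        return_truth=True,
    )

    key_mode: KeyMode = bl.default_key_mode
    bl_freqs = bl.frequencies
    bl_expanded = bl_freqs > config.expansion_threshold

    rng_survival = np.random.default_rng(ss_survival)
    survive_p = np.where(bl_expanded, config.persistence_rho, config.bottleneck)
    survives = rng_survival.random(config.n_clones_bl) < survive_p
    survivor_idx = np.flatnonzero(survives)
    n_survivors = survivor_idx.size
    if n_survivors + config.n_novel_post < 1:
        raise ConfigurationError("no clones survive and no novel clones requested")

    rng_post = np.random.default_rng(ss_post)
    n_post = n_survivors + config.n_novel_post
    post_weights = _clone_weights(n_post, config.zipf_exponent, config.size_law, rng_post)
    # survivors occupy the leading compacted ranks in baseline order;
    # boost surviving baseline-expanded clones before renormalizing
    boost = np.ones(n_post)
    boost[:n_survivors] = np.where(bl_expanded[survivor_idx], config.expansion_boost, 1.0)
    post_weights = post_weights * boost
    post_weights /= post_weights.sum()
    post_counts = _floored_counts(post_weights, config.total_reads_post, rng_post)

    existing = frozenset(c.cdr3_aa for c in bl.clones)
    novel_cdr3s, _ = _generate_cdr3s(
        rng_post,
        config.n_novel_post,
        config.cdr3_length_range,
        0,
        config.family_size,
        config.family_core_length,
        forbidden=existing,
    )

    from dataclasses import replace as dc_replace

    post_clones: List[Clone] = []
    for new_rank, idx in enumerate(survivor_idx):
        post_clones.append(dc_replace(bl.clones[idx], count=int(post_counts[new_rank])))
    for j, cdr3 in enumerate(novel_cdr3s):
        v_call, j_call = _gene_labels(rng_post, config.chain)
        post_clones.append(
            Clone(
                cdr3_aa=cdr3,
                count=int(post_counts[n_survivors + j]),
                cdr3_nt=_reverse_translate(rng_post, cdr3) if config.with_nt else None,
                v_call=v_call,
                j_call=j_call,
            )
        )
    post = Repertoire(
        sample_id=f"{config.patient_id}_post",
        clones=tuple(post_clones),
        patient_id=config.patient_id,
        chain=config.chain,
        timepoint="postASCT",
    )

    surviving_keys = frozenset(
        clonotype_key(bl.clones[i], key_mode) for i in survivor_idx
    )
    novel_keys = frozenset(
        clonotype_key(c, key_mode) for c in post_clones[n_survivors:]
    )
    post_freqs = post.frequencies
    post_keys = post.keys(key_mode)
    post_expanded_keys = frozenset(
        key for key, f in zip(post_keys, post_freqs) if f > config.expansion_threshold
    )
    if post_expanded_keys:
        realized = sum(
            1 for key in post_expanded_keys if key in surviving_keys
        ) / len(post_expanded_keys)
    else:
        realized = float("nan")
    truth = PairedTruth(
        key_mode=key_mode,
        bl_expanded_keys=frozenset(
            key for key, e in zip(bl.keys(key_mode), bl_expanded) if e
        ),
        surviving_keys=surviving_keys,
        novel_keys=novel_keys,
        post_expanded_keys=post_expanded_keys,
        realized_persistent_expanded_fraction=realized,
        family_of=bl_truth.family_of,
    )
    return bl, post, truth
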