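"""Triplet string-kernel similarity over CDR3 amino-acid sequences.

Two CDR3s are compared through their contiguous 3-mer (triplet) content: the
spectrum kernel :math:`K(s,t) = \\sum_u c_s(u)\\,c_t(u)` is the inner product
of triplet count vectors, and similarity is the cosine normalization
:math:`K(s,t)/\\sqrt{K(s,s)K(t,t)} \\in [0,1]` — 1 for identical strings, 0
when no triplet is shared.  A similarity network connects CDR3s whose
similarity reaches a threshold (default 0.80, inclusive); *clusters* are the
connected components with at least two nodes (a singleton is not a cluster).

The threshold is calibrated so that motif-free control sequences — e.g.
unexpanded singleton clones or uniformly random CDR3s — show minimal
clustering; :func:`calibrate_control` measures exactly that clustered-node
fraction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import sqrt
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx

from .errors import SimilarityError
from .expansion import DEFAULT_EXPANSION_THRESHOLD
from .repertoire import _AA_SET, Repertoire

DEFAULT_SIMILARITY_THRESHOLD = 0.80
DEFAULT_TOP_N = 50


def triplet_counts(s: str) -> Dict[str, int]:
    """Counts of all contiguous amino-acid 3-mers of ``s`` (empty if len < 3)."""
    invalid = set(s) - _AA_SET
    if invalid:
        raise SimilarityError(
            f"invalid amino-acid characters {sorted(invalid)} in {s!r}"
        )
    return dict(Counter(s[i : i + 3] for i in range(len(s) - 2)))


def kernel_similarity(s: str, t: str) -> float:
    """Cosine-normalized triplet spectrum kernel similarity in [0, 1]."""
    if len(s) < 3 or len(t) < 3:
        raise SimilarityError(
            "kernel similarity is undefined for CDR3s shorter than 3 residues"
        )
    cs, ct = triplet_counts(s), triplet_counts(t)
    return _cosine(cs, ct)


def _cosine(cs: Dict[str, int], ct: Dict[str, int]) -> float:
    cross = sum(n * ct[u] for u, n in cs.items() if u in ct)
    if cross == 0:
        return 0.0
    ss = sum(n * n for n in cs.values())
    tt = sum(n * n for n in ct.values())
    return cross / sqrt(ss * tt)


def top_expanded_cdr3s(
    rep: Repertoire,
    n: int = DEFAULT_TOP_N,
    threshold: float = DEFAULT_EXPANSION_THRESHOLD,
) -> List[str]:
    """Top-``n`` expanded CDR3 amino-acid sequences, most frequent first.

    Nonproductive CDR3s and CDR3s shorter than 3 residues are excluded
    before ranking; counts of clones sharing an amino-acid CDR3 (convergent
    rearrangements) are pooled.  Ties in frequency break lexicographically.
    If fewer than ``n`` CDR3s are expanded, all of them are returned.
    """
    total = rep.total_reads
    if total == 0:
        return []
    pooled: Counter = Counter()
    for clone in rep.clones:
        if clone.productive and len(clone.cdr3_aa) >= 3:
            pooled[clone.cdr3_aa] += clone.count
    ranked = sorted(
        (cdr3 for cdr3, count in pooled.items() if count / total > threshold),
        key=lambda cdr3: (-pooled[cdr3] / total, cdr3),
    )
    return ranked[:n]


@dataclass(frozen=True)
class SimilarityNetwork:
    """Thresholded kernel-similarity graph over CDR3 strings."""

    graph: nx.Graph
    threshold: float
    clusters: Tuple[Tuple[str, ...], ...]  # components of size >= 2

    @property
    def nodes(self) -> Tuple[str, ...]:
        return tuple(self.graph.nodes)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def clustered_fraction(self) -> float:
        """Fraction of input CDR3s that belong to a cluster."""
        n = self.graph.number_of_nodes()
        if n == 0:
            return 0.0
        return sum(len(c) for c in self.clusters) / n


def build_network(
    cdr3s: Sequence[str],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> SimilarityNetwork:
    """All-pairs kernel similarity network with edges at similarity >= threshold.

    Input CDR3s must be deduplicated and at least 3 residues long.  Clusters
    are connected components with >= 2 nodes, ordered by size (largest
    first) then lexicographically by their smallest member.
    """
    cdr3s = list(cdr3s)
    if len(set(cdr3s)) != len(cdr3s):
        raise ValueError("input CDR3 list contains duplicates")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"similarity threshold must lie in (0, 1], got {threshold}")
    spectra = {s: triplet_counts(s) for s in cdr3s}
    for s, spec in spectra.items():
        if not spec:
            raise SimilarityError(f"CDR3 {s!r} shorter than 3 residues")
    graph = nx.Graph()
    graph.add_nodes_from(cdr3s)
    for i, s in enumerate(cdr3s):
        for t in cdr3s[i + 1 :]:
            sim = _cosine(spectra[s], spectra[t])
            if sim >= threshold:
                graph.add_edge(s, t, similarity=sim)
    components = [
        tuple(sorted(comp))
        for comp in nx.connected_components(graph)
        if len(comp) >= 2
    ]
    components.sort(key=lambda comp: (-len(comp), comp[0]))
    return SimilarityNetwork(graph=graph, threshold=threshold, clusters=tuple(components))


def calibrate_control(
    control_cdr3s: Sequence[str],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> float:
    """Clustered-node fraction of a control (motif-free / unexpanded) CDR3 set.

    Used to verify that the similarity threshold yields minimal clustering
    on sequences with no shared-motif structure.  Empty input returns 0.0.
    """
    if not list(control_cdr3s):
        return 0.0
    return build_network(control_cdr3s, threshold).clustered_fraction
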