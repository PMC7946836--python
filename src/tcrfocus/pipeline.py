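"""Cohort-level orchestration: depth matching, diversity, expansion,
clustering and persistence over a manifest of paired samples.

``run_cohort`` consumes a tab-separated manifest (sample_id, patient_id,
chain, timepoint, path), resolves baseline / post-treatment pairs per
patient and chain, and runs every analysis stage, writing tab-separated
tables and vector plots to an output directory.  Re-running with the same
manifest, configuration and seed reproduces every output byte for byte.

Default depths follow the chain-specific convention of subsampling to
3,000 reads for the α-chain and 9,000 for the β-chain, capped at the
shallower member of each pair (pairs below the default depth are profiled
at their own matched depth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .depth_matching import SubsampleSpec, match_pair, summarize_iterates
from .diversity import DEFAULT_ORDERS, renyi_profile
from .errors import DegenerateInputError, ManifestError
from .expansion import (
    DEFAULT_EXPANSION_THRESHOLD,
    expanded_clones,
    expanded_read_fraction,
    threshold_curve,
)
from .io import read_manifest, read_repertoire
from .persistence import shared_expanded_fraction
from .repertoire import Repertoire
from .similarity import (
    DEFAULT_SIMILARITY_THRESHOLD,
    DEFAULT_TOP_N,
    build_network,
    top_expanded_cdr3s,
)

DEFAULT_DEPTHS = {"alpha": 3000, "beta": 9000}
DEFAULT_THRESHOLD_GRID = tuple(float(t) for t in np.logspace(-5, -1, 13))

_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class CohortConfig:
    """Pipeline parameters; plain key=value config files map onto these fields."""

    iterations: int = 100
    depth_alpha: int = DEFAULT_DEPTHS["alpha"]
    depth_beta: int = DEFAULT_DEPTHS["beta"]
    expansion_threshold: float = DEFAULT_EXPANSION_THRESHOLD
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD
    top_n: int = DEFAULT_TOP_N
    orders: Tuple[float, ...] = tuple(DEFAULT_ORDERS)
    key_mode: Optional[str] = None  # None = auto (nt when available)
    dialect: str = "airr"
    seed: int = 0
    make_plots: bool = True

    def depth_for(self, chain: str) -> int:
        return self.depth_alpha if chain == "alpha" else self.depth_beta


def read_config(path) -> Dict[str, str]:
    """Parse a plain ``key = value`` config file (one pair per line, # comments)."""
    values: Dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ManifestError(f"{path}: config line {line!r} is not key = value")
            key, value = line.split("=", 1)
            values[key.strip()] = value.strip()
    return values


def config_from_file(path) -> CohortConfig:
    raw = read_config(path)
    kwargs: Dict[str, object] = {}
    for key, value in raw.items():
        if key in ("iterations", "depth_alpha", "depth_beta", "top_n", "seed"):
            kwargs[key] = int(value)
        elif key in ("expansion_threshold", "similarity_threshold"):
            kwargs[key] = float(value)
        elif key == "orders":
            kwargs[key] = tuple(
                float("inf") if tok in ("inf", "Inf") else float(tok)
                for tok in value.split(",")
            )
        elif key == "make_plots":
            kwargs[key] = value.lower() in ("1", "true", "yes")
        elif key in ("key_mode", "dialect"):
            kwargs[key] = value
        else:
            raise ManifestError(f"{path}: unknown config key {key!r}")
    return CohortConfig(**kwargs)


class PairedTestResult(NamedTuple):
    statistic: float
    pvalue: float
    n: int


def paired_richness_test(
    bl_values: Sequence[float], post_values: Sequence[float]
) -> PairedTestResult:
    """Two-sided paired t-test on baseline − post differences.

    The p-value is reported unadjusted; apply :func:`adjust_pvalues` when
    testing multiple chains or metrics.  All-zero differences (no variance)
    raise :class:`DegenerateInputError` rather than returning an undefined
    statistic.
    """
    bl = np.asarray(bl_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if bl.shape != post.shape:
        raise ValueError("paired collections must have equal length")
    if bl.size < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    diffs = bl - post
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise DegenerateInputError(
            "paired differences have zero variance; t statistic undefined"
        )
    result = stats.ttest_rel(bl, post)
    return PairedTestResult(float(result.statistic), float(result.pvalue), bl.size)


def adjust_pvalues(pvalues: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Bonferroni or Holm adjustment across a family of p-values."""
    from statsmodels.stats.multitest import multipletests

    if method not in ("bonferroni", "holm"):
        raise ValueError(f"unsupported adjustment {method!r}")
    return multipletests(list(pvalues), method=method)[1]


@dataclass
class CohortReport:
    """All per-sample and per-patient tables from one cohort run."""

    richness: pd.DataFrame
    renyi: pd.DataFrame
    threshold_curves: pd.DataFrame
    expansion: pd.DataFrame
    clusters: pd.DataFrame
    overlap: pd.DataFrame
    tests: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "richness": self.richness,
            "renyi": self.renyi,
            "threshold_curves": self.threshold_curves,
            "expansion": self.expansion,
            "clusters": self.clusters,
            "overlap": self.overlap,
            "tests": self.tests,
        }

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for name, table in self.tables().items():
            table.to_csv(
                os.path.join(outdir, f"{name}.tsv"),
                sep="\t",
                index=False,
                float_format=_FLOAT_FORMAT,
            )
        with open(os.path.join(outdir, "run_metadata.json"), "w") as handle:
            json.dump(self.metadata, handle, indent=2, sort_keys=True)
            handle.write("\n")


def _resolve_pairs(manifest: pd.DataFrame) -> List[Tuple[pd.Series, pd.Series]]:
    pairs = []
    grouped = manifest.groupby(["patient_id", "chain"], sort=True)
    for (patient, chain), group in grouped:
        bl = group[group["timepoint"] == "BL"]
        post = group[group["timepoint"] == "postASCT"]
        if len(bl) != 1 or len(post) != 1:
            raise ManifestError(
                f"patient {patient!r} chain {chain!r}: need exactly one BL and one "
                f"postASCT sample, found {len(bl)} BL / {len(post)} postASCT"
            )
        pairs.append((bl.iloc[0], post.iloc[0]))
    return pairs


def _load(row: pd.Series, dialect: str) -> Repertoire:
    return read_repertoire(
        row["path"],
        dialect=dialect,
        sample_id=row["sample_id"],
        patient_id=row["patient_id"],
        chain=row["chain"],
        timepoint=row["timepoint"],
    )


def run_cohort(
    manifest_path,
    outdir,
    config: Optional[CohortConfig] = None,
) -> CohortReport:
    """Run every analysis stage over a cohort manifest and write the report.

    Stages per resolved (patient, chain) pair: depth matching with
    ``config.iterations`` iterates; per-sample richness (full and
    depth-matched summary); Rényi profiles at the chain default depth
    (capped at the pair's matched depth); threshold–count curves on the
    matched iterates; expanded counts/proportions on full samples; triplet
    kernel clustering of the top expanded CDR3s; baseline overlap of
    post-treatment expanded clonotypes; and a paired t-test on richness
    across patients per chain.
    """
    config = config or CohortConfig()
    manifest = read_manifest(manifest_path)
    pairs = _resolve_pairs(manifest)

    richness_rows, renyi_rows, curve_rows = [], [], []
    expansion_rows, cluster_rows, overlap_rows = [], [], []
    chain_richness: Dict[str, List[Tuple[str, int, int]]] = {}

    for bl_row, post_row in pairs:
        bl = _load(bl_row, config.dialect)
        post = _load(post_row, config.dialect)
        patient, chain = bl.patient_id, bl.chain
        matched_depth = min(bl.total_reads, post.total_reads)
        iterates = match_pair(bl, post, n_iterations=config.iterations, seed=config.seed)

        for rep, matched in (
            (bl, [a for a, _ in iterates]),
            (post, [b for _, b in iterates]),
        ):
            summary = summarize_iterates([m.richness for m in matched])
            richness_rows.append(
                {
                    "sample_id": rep.sample_id,
                    "patient_id": patient,
                    "chain": chain,
                    "timepoint": rep.timepoint,
                    "total_reads": rep.total_reads,
                    "richness": rep.richness,
                    "matched_depth": matched_depth,
                    "matched_richness_median": summary.median,
                    "matched_richness_mean": summary.mean,
                    "matched_richness_min": summary.minimum,
                    "matched_richness_max": summary.maximum,
                }
            )

        profile_depth = min(config.depth_for(chain), matched_depth)
        spec = SubsampleSpec(
            depth=profile_depth, n_iterations=config.iterations, seed=config.seed
        )
        for rep in (bl, post):
            profile = renyi_profile(rep, spec, config.orders)
            for q, med, mean, lo, hi in zip(
                profile.orders, profile.median, profile.mean, profile.minimum, profile.maximum
            ):
                renyi_rows.append(
                    {
                        "sample_id": rep.sample_id,
                        "patient_id": patient,
                        "chain": chain,
                        "timepoint": rep.timepoint,
                        "depth": profile_depth,
                        "order": "inf" if np.isinf(q) else q,
                        "entropy_median": med,
                        "entropy_mean": mean,
                        "entropy_min": lo,
                        "entropy_max": hi,
                    }
                )

            curve_spec = SubsampleSpec(
                depth=matched_depth, n_iterations=config.iterations, seed=config.seed
            )
            grid = [t for t in DEFAULT_THRESHOLD_GRID if t > 1.0 / matched_depth]
            curve = threshold_curve(rep, grid, curve_spec)
            for t, summary in curve.items():
                curve_rows.append(
                    {
                        "sample_id": rep.sample_id,
                        "patient_id": patient,
                        "chain": chain,
                        "timepoint": rep.timepoint,
                        "threshold": t,
                        "count_median": summary.median,
                        "count_mean": summary.mean,
                        "count_min": summary.minimum,
                        "count_max": summary.maximum,
                    }
                )

            result = expanded_clones(rep, config.expansion_threshold)
            expansion_rows.append(
                {
                    "sample_id": rep.sample_id,
                    "patient_id": patient,
                    "chain": chain,
                    "timepoint": rep.timepoint,
                    "threshold": result.threshold,
                    "n_expanded": result.n_expanded,
                    "richness": result.richness,
                    "proportion_expanded": result.proportion_expanded,
                    "read_fraction_expanded": expanded_read_fraction(
                        rep, config.expansion_threshold
                    ),
                }
            )

            top = top_expanded_cdr3s(rep, config.top_n, config.expansion_threshold)
            network = build_network(top, config.similarity_threshold) if top else None
            cluster_rows.append(
                {
                    "sample_id": rep.sample_id,
                    "patient_id": patient,
                    "chain": chain,
                    "timepoint": rep.timepoint,
                    "n_input_cdr3s": len(top),
                    "n_clusters": network.n_clusters if network else 0,
                    "clustered_fraction": network.clustered_fraction if network else 0.0,
                    "largest_cluster": max(
                        (len(c) for c in network.clusters), default=0
                    )
                    if network
                    else 0,
                }
            )

        overlap = shared_expanded_fraction(
            post, bl, mode=config.key_mode, threshold=config.expansion_threshold
        )
        aa_overlap = shared_expanded_fraction(
            post, bl, mode="aa", threshold=config.expansion_threshold
        )
        overlap_rows.append(
            {
                "patient_id": patient,
                "chain": chain,
                "key_mode": overlap.key_mode,
                "n_expanded_post": overlap.n_expanded_post,
                "n_shared": overlap.n_shared,
                "shared_fraction": overlap.shared_fraction,
                "shared_fraction_aa": aa_overlap.shared_fraction,
            }
        )
        chain_richness.setdefault(chain, []).append(
            (patient, bl.richness, post.richness)
        )

    test_rows = []
    for chain in sorted(chain_richness):
        triples = chain_richness[chain]
        bl_vals = [r for _, r, _ in triples]
        post_vals = [r for _, _, r in triples]
        if len(triples) >= 2:
            try:
                result = paired_richness_test(bl_vals, post_vals)
                test_rows.append(
                    {
                        "chain": chain,
                        "metric": "richness",
                        "test": "paired_t",
                        "n_pairs": result.n,
                        "statistic": result.statistic,
                        "pvalue": result.pvalue,
                        "note": "unadjusted",
                    }
                )
            except DegenerateInputError:
                test_rows.append(
                    {
                        "chain": chain,
                        "metric": "richness",
                        "test": "paired_t",
                        "n_pairs": len(triples),
                        "statistic": float("nan"),
                        "pvalue": float("nan"),
                        "note": "degenerate: zero-variance differences",
                    }
                )

    report = CohortReport(
        richness=pd.DataFrame(richness_rows),
        renyi=pd.DataFrame(renyi_rows),
        threshold_curves=pd.DataFrame(curve_rows),
        expansion=pd.DataFrame(expansion_rows),
        clusters=pd.DataFrame(cluster_rows),
        overlap=pd.DataFrame(overlap_rows),
        tests=pd.DataFrame(
            test_rows,
            columns=["chain", "metric", "test", "n_pairs", "statistic", "pvalue", "note"],
        ),
        metadata={
            "package_version": __version__,
            "n_pairs": len(pairs),
            "config": {
                "iterations": config.iterations,
                "depth_alpha": config.depth_alpha,
                "depth_beta": config.depth_beta,
                "expansion_threshold": config.expansion_threshold,
                "similarity_threshold": config.similarity_threshold,
                "top_n": config.top_n,
                "orders": ["inf" if np.isinf(q) else q for q in config.orders],
                "key_mode": config.key_mode,
                "dialect": config.dialect,
                "seed": config.seed,
            },
        },
    )
    report.write(outdir)
    if config.make_plots:
        from .plots import plot_cohort

        plot_cohort(report, outdir)
    return report
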