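"""Overlap significance: hypergeometric tail tests, BH adjustment, result tables.

The over-representation p-value for a target list against a gene set is the
upper hypergeometric tail

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

where k is the observed overlap, K the gene-set size, n the number of targets
counted in the background, and N the background size. The sum is accumulated
in log space (log-gamma binomials + logsumexp) so that p-values far below
double-precision underflow of the individual terms (order 1e-26 and smaller)
remain accurate. Families of tests are corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .curation import TargetList
from .genesets import BackgroundRegistry, GeneSetCollection

logger = logging.getLogger(__name__)

# Underflow floor: p-values are clamped to the smallest positive normal
# double so BH multiplication and log reporting stay finite.
_P_FLOOR = float(np.finfo(float).tiny)

INTERSECT_BACKGROUND = "intersect_background"
RAW = "raw"
PER_TARGET_LIST = "per_target_list"
PER_RUN = "per_run"


class DomainError(ValueError):
    """Raised when test parameters violate 0 <= k <= min(n, K), K <= N, n <= N."""


def _log_choose(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters follow the ORA convention: ``k`` observed successes (overlap),
    ``K`` marked items (gene-set size), ``n`` draws (target-list size),
    ``N`` population (background size).

    Computed by log-gamma accumulation; the result is clamped to (0, 1].
    """
    if not (0 <= K <= N):
        raise DomainError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise DomainError(f"require 0 <= n <= N, got n={n}, N={N}")
    upper = min(n, K)
    if not (0 <= k <= upper):
        raise DomainError(f"require 0 <= k <= min(n, K)={upper}, got k={k}")
    if k == 0:
        return 1.0
    i = np.arange(k, upper + 1)
    log_terms = _log_choose(K, i) + _log_choose(N - K, n - i) - _log_choose(N, n)
    p = float(np.exp(logsumexp(log_terms)))
    return min(1.0, max(_P_FLOOR, p))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over the ascending
    order statistics; ties and the original ordering are preserved.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


def format_pvalue(p: float) -> str:
    """Scientific notation at 3 significant digits, e.g. ``1.90E-04``."""
    return f"{p:.2E}"


@dataclass
class AnalysisConfig:
    """Knobs of an overlap analysis run.

    alpha : significance threshold on adjusted p-values (default 0.05).
    target_universe_policy : ``"intersect_background"`` counts only target
        genes present in the resolved universe as ``n`` (the statistically
        coherent choice: genes outside the universe cannot be drawn);
        ``"raw"`` uses the full target-list size.
    correction_family : ``"per_target_list"`` applies BH across the tests of
        one target list (one report column); ``"per_run"`` pools all target
        lists of a run into a single family.
    """

    alpha: float = 0.05
    target_universe_policy: str = INTERSECT_BACKGROUND
    correction_family: str = PER_TARGET_LIST

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.target_universe_policy not in (INTERSECT_BACKGROUND, RAW):
            raise ValueError(f"unknown target universe policy {self.target_universe_policy!r}")
        if self.correction_family not in (PER_TARGET_LIST, PER_RUN):
            raise ValueError(f"unknown correction family {self.correction_family!r}")


@dataclass
class OverlapResult:
    """One tested (target list x gene set) pair."""

    target_label: str
    set_name: str
    set_source: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    overlap_genes: list[str]
    significant: bool

    def __post_init__(self) -> None:
        assert 0 <= self.k <= min(self.n, self.K)
        assert self.k == len(self.overlap_genes)
        assert 0 < self.p_raw <= self.p_adj <= 1
        assert self.K <= self.N and self.n <= self.N


def _raw_rows(
    target: TargetList,
    collections: Iterable[GeneSetCollection],
    registry: BackgroundRegistry,
    config: AnalysisConfig,
) -> list[dict]:
    rows = []
    for collection in collections:
        for gene_set in collection:
            universe, N = registry.background_for(gene_set)
            registry.missing_fraction(gene_set)
            if gene_set.size > N:
                raise DomainError(
                    f"gene set {gene_set.name!r} (K={gene_set.size}) larger than its "
                    f"background (N={N}): inconsistent background"
                )
            if config.target_universe_policy == INTERSECT_BACKGROUND:
                n = len(target.genes & universe)
            else:
                n = len(target.genes)
                if n > N:
                    raise DomainError(
                        f"target list {target.label!r} (n={n}) larger than background "
                        f"(N={N}) under the raw policy"
                    )
            overlap = sorted(target.genes & gene_set.genes)
            k = len(overlap)
            if k > min(n, gene_set.size):
                # Only reachable under intersect policy if overlap genes are
                # missing from the universe; count them into n to keep the
                # test well-posed.
                n = len((target.genes & universe) | set(overlap))
            rows.append(
                dict(
                    target_label=target.label,
                    set_name=gene_set.name,
                    set_source=gene_set.source,
                    k=k,
                    K=gene_set.size,
                    n=n,
                    N=N,
                    p_raw=hypergeom_tail(k, gene_set.size, n, N),
                    overlap_genes=overlap,
                )
            )
    return rows


def _finalize(rows: list[dict], alpha: float) -> list[OverlapResult]:
    adjusted = bh_adjust([r["p_raw"] for r in rows]) if rows else []
    return [
        OverlapResult(**row, p_adj=adj, significant=adj < alpha)
        for row, adj in zip(rows, adjusted)
    ]


def run_overlap_analysis(
    target: TargetList,
    collections: Iterable[GeneSetCollection],
    registry: BackgroundRegistry,
    config: AnalysisConfig | None = None,
) -> list[OverlapResult]:
    """Test one target list against every gene set of the given collections.

    For each gene set, the background universe is resolved from the
    registry, ``n`` is set per the target-universe policy, the overlap and
    its hypergeometric tail probability are computed, and BH adjustment is
    applied across all tests of the run. Results keep (collection, set)
    input order; overlap genes are sorted lexicographically.
    """
    config = config or AnalysisConfig()
    rows = _raw_rows(target, collections, registry, config)
    logger.info(
        "overlap analysis: target %s (%d genes), %d gene sets, policy=%s",
        target.label, len(target.genes), len(rows), config.target_universe_policy,
    )
    return _finalize(rows, config.alpha)


def run_overlap_analyses(
    targets: Sequence[TargetList],
    collections: Iterable[GeneSetCollection],
    registry: BackgroundRegistry,
    config: AnalysisConfig | None = None,
) -> dict[str, list[OverlapResult]]:
    """Run several target lists, honouring the correction-family policy.

    ``per_target_list`` adjusts each target's tests separately (one table
    column = one BH family); ``per_run`` pools every (target, set) test into
    a single family before adjusting.
    """
    config = config or AnalysisConfig()
    collections = list(collections)
    per_target_rows = {
        t.label: _raw_rows(t, collections, registry, config) for t in targets
    }
    if config.correction_family == PER_TARGET_LIST:
        return {
            label: _finalize(rows, config.alpha)
            for label, rows in per_target_rows.items()
        }
    labels = list(per_target_rows)
    flat = [row for label in labels for row in per_target_rows[label]]
    finalized = _finalize(flat, config.alpha)
    out: dict[str, list[OverlapResult]] = {}
    i = 0
    for label in labels:
        m = len(per_target_rows[label])
        out[label] = finalized[i : i + m]
        i += m
    return out


def results_to_frame(results: Iterable[OverlapResult]) -> pd.DataFrame:
    """Tabulate results: one row per tested gene set."""
    return pd.DataFrame(
        [
            {
                "target": r.target_label,
                "source": r.set_source,
                "term_name": r.set_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "p_adj_formatted": format_pvalue(r.p_adj),
                "significant": r.significant,
                "overlap_genes": "; ".join(r.overlap_genes),
            }
            for r in results
        ]
    )


def write_results_csv(results: Iterable[OverlapResult], path: str | Path) -> Path:
    """Write a per-target results CSV (gene lists ';'-joined and quoted)."""
    path = Path(path)
    results_to_frame(results).to_csv(path, index=False)
    return path


def read_results_csv(path: str | Path) -> list[OverlapResult]:
    """Read back a results CSV written by :func:`write_results_csv`."""
    frame = pd.read_csv(path, keep_default_na=False)
    results = []
    for _, row in frame.iterrows():
        genes = [g for g in str(row["overlap_genes"]).split("; ") if g]
        results.append(
            OverlapResult(
                target_label=str(row["target"]),
                set_name=str(row["term_name"]),
                set_source=str(row["source"]),
                k=int(row["k"]),
                K=int(row["K"]),
                n=int(row["n"]),
                N=int(row["N"]),
                p_raw=float(row["p_raw"]),
                p_adj=float(row["p_adj"]),
                overlap_genes=genes,
                significant=str(row["significant"]).lower() == "true",
            )
        )
    return results
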