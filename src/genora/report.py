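"""Publication-style merged result tables.

One analysis produces a results column per target-gene source (e.g. the
database-curated list and the literature-derived list of the same vitamin);
the merged report places those columns side by side, one row per tested gene
set, with a significance flag at the configured alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .enrichment import OverlapResult, format_pvalue


class RosterMismatchError(ValueError):
    """Raised when per-source result lists do not cover the same gene sets."""


@dataclass
class MergedReport:
    """One row per gene set; per-source adjusted p, flag, and overlap genes."""

    frame: pd.DataFrame
    labels: list[str]
    alpha: float

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path


def merge_reports(
    results_by_source: Mapping[str, Sequence[OverlapResult]],
    alpha: float = 0.05,
) -> MergedReport:
    """Merge per-source overlap results into one table.

    All sources must cover exactly the same gene sets; a mismatch raises
    :class:`RosterMismatchError` naming the differing sets. Row order
    follows the first source's result order. Gene-list cells are joined
    with ``"; "`` (and quoted by the CSV writer), p-values are kept at full
    precision alongside a 3-significant-digit formatted column.
    """
    if not results_by_source:
        raise ValueError("no results to merge")
    labels = list(results_by_source)
    rosters = {
        label: [(r.set_source, r.set_name) for r in results]
        for label, results in results_by_source.items()
    }
    reference = set(rosters[labels[0]])
    for label in labels[1:]:
        diff = reference ^ set(rosters[label])
        if diff:
            names = ", ".join(sorted(name for _, name in diff))
            raise RosterMismatchError(
                f"gene-set rosters differ between {labels[0]!r} and {label!r}: {names}"
            )

    indexed = {
        label: {(r.set_source, r.set_name): r for r in results}
        for label, results in results_by_source.items()
    }
    rows = []
    for key in rosters[labels[0]]:
        row: dict = {"source": key[0], "term_name": key[1]}
        for label in labels:
            r = indexed[label][key]
            row[f"{label}_k"] = r.k
            row[f"{label}_K"] = r.K
            row[f"{label}_n"] = r.n
            row[f"{label}_N"] = r.N
            row[f"{label}_p_adj"] = r.p_adj
            row[f"{label}_p_adj_formatted"] = format_pvalue(r.p_adj)
            row[f"{label}_significant"] = r.p_adj < alpha
            row[f"{label}_overlap_genes"] = "; ".join(r.overlap_genes)
        rows.append(row)
    return MergedReport(frame=pd.DataFrame(rows), labels=labels, alpha=alpha)
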