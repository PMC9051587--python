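"""Curation of vitamin target-gene lists from chemical-gene interaction tables.

The pipeline: parse a CTD-style interaction export, keep genes whose
interactions are supported by at least ``min_refs`` distinct references,
harmonize symbols against an old->current mapping table, then merge
per-source lists into a combined target list with per-gene provenance.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .genesets import normalize_symbol

logger = logging.getLogger(__name__)

# Accepted header spellings, normalized to lower-case alphanumerics.
_CHEMICAL_COLS = ("chemicalname", "chemical")
_CHEMICAL_ID_COLS = ("chemicalid",)
_GENE_COLS = ("genesymbol", "gene")
_ORGANISM_COLS = ("organism",)
_INTERACTION_COLS = ("interaction", "interactionactions")
_REFS_COLS = ("pubmedids", "referenceids", "references", "refs")


class InteractionParseError(ValueError):
    """Raised when an interaction table lacks a mandatory column."""


@dataclass(frozen=True)
class InteractionRecord:
    """One chemical-gene interaction row with its supporting references."""

    chemical_name: str
    chemical_id: str
    gene_symbol: str
    organism: str
    interaction_text: str
    reference_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.reference_ids:
            raise ValueError(
                f"interaction for {self.gene_symbol} has no supporting references"
            )


@dataclass
class TargetList:
    """A curated target-gene list with per-gene source provenance.

    ``vitamin`` identifies the chemical (``"A"``/``"D"`` in the motivating
    analysis, free-form for synthetic data); ``label`` names the evidence
    source (e.g. ``"CTD"``) or ``"combined"`` after merging.
    """

    vitamin: str
    label: str
    genes: frozenset[str]
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = {g: frozenset([self.label]) for g in self.genes}
        missing = self.genes - set(self.provenance)
        if missing:
            raise ValueError(
                f"genes without provenance in {self.label!r}: {sorted(missing)[:5]}..."
            )
        for g, srcs in self.provenance.items():
            if not srcs:
                raise ValueError(f"gene {g} has empty provenance")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class MappingTable:
    """Old-symbol -> current-symbol substitutions for harmonization."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {
            normalize_symbol(old): normalize_symbol(new)
            for old, new in self.entries.items()
        }

    @classmethod
    def read(cls, path: str | Path) -> "MappingTable":
        """Read a two-column TSV (old symbol, current symbol)."""
        entries: dict[str, str] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[1].strip():
                    raise ValueError(f"{Path(path).name}:{lineno}: expected 2 columns")
                entries[parts[0]] = parts[1]
        return cls(entries=entries)


def _norm_header(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


def _find_col(header: list[str], candidates: tuple[str, ...]) -> int | None:
    normed = [_norm_header(h) for h in header]
    for cand in candidates:
        if cand in normed:
            return normed.index(cand)
    return None


def parse_interactions(path: str | Path) -> list[InteractionRecord]:
    """Parse a chemical-gene interaction TSV into records.

    The header must name at least a chemical, a gene-symbol, and a reference
    column (CTD export spellings accepted; a leading ``#`` on the header row
    is tolerated). The reference column holds a pipe-separated identifier
    list, which is split and deduplicated. Other comment lines are skipped;
    rows with an empty gene symbol are skipped with a warning.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))

    header: list[str] | None = None
    data_rows: list[tuple[int, list[str]]] = []
    for lineno, row in enumerate(rows, start=1):
        if not row or not any(cell.strip() for cell in row):
            continue
        if header is None:
            # First meaningful line is the header; CTD exports prefix it with '#'.
            header = [row[0].lstrip("#"), *row[1:]]
            continue
        if row[0].startswith("#"):
            continue
        data_rows.append((lineno, row))

    if header is None:
        raise InteractionParseError(f"{path.name}: file has no header row")

    i_chem = _find_col(header, _CHEMICAL_COLS)
    i_gene = _find_col(header, _GENE_COLS)
    i_refs = _find_col(header, _REFS_COLS)
    if i_chem is None or i_gene is None or i_refs is None:
        missing = [
            label
            for label, idx in (("chemical", i_chem), ("gene symbol", i_gene), ("references", i_refs))
            if idx is None
        ]
        raise InteractionParseError(f"{path.name}: missing mandatory column(s): {', '.join(missing)}")
    i_chem_id = _find_col(header, _CHEMICAL_ID_COLS)
    i_org = _find_col(header, _ORGANISM_COLS)
    i_inter = _find_col(header, _INTERACTION_COLS)

    def cell(row: list[str], idx: int | None) -> str:
        return row[idx].strip() if idx is not None and idx < len(row) else ""

    records: list[InteractionRecord] = []
    for lineno, row in data_rows:
        gene_raw = cell(row, i_gene)
        if not gene_raw:
            logger.warning("%s:%d: empty gene symbol, row skipped", path.name, lineno)
            continue
        refs = frozenset(r.strip() for r in cell(row, i_refs).split("|") if r.strip())
        if not refs:
            logger.warning("%s:%d: no reference identifiers, row skipped", path.name, lineno)
            continue
        records.append(
            InteractionRecord(
                chemical_name=cell(row, i_chem),
                chemical_id=cell(row, i_chem_id),
                gene_symbol=normalize_symbol(gene_raw),
                organism=cell(row, i_org),
                interaction_text=cell(row, i_inter),
                reference_ids=refs,
            )
        )
    if not records:
        logger.warning("%s: no interaction records parsed", path.name)
    return records


def filter_by_evidence(
    records: Iterable[InteractionRecord],
    min_refs: int = 2,
    scope: str = "gene",
) -> frozenset[str]:
    """Keep genes whose interactions are supported by >= ``min_refs`` references.

    With ``scope="gene"`` (default) the reference identifiers of all records
    for a gene — including records from different descendant chemicals — are
    pooled before counting, so two single-reference records of the same gene
    count as two pieces of evidence. With ``scope="row"`` a gene qualifies
    only if some single record carries >= ``min_refs`` references.
    """
    if min_refs < 1:
        raise ValueError("min_refs must be >= 1")
    if scope not in ("gene", "row"):
        raise ValueError(f"unknown evidence scope {scope!r}")
    if scope == "row":
        return frozenset(
            r.gene_symbol for r in records if len(r.reference_ids) >= min_refs
        )
    pooled: dict[str, set[str]] = {}
    for r in records:
        pooled.setdefault(r.gene_symbol, set()).update(r.reference_ids)
    return frozenset(g for g, refs in pooled.items() if len(refs) >= min_refs)


def harmonize(
    genes: Iterable[str], mapping: MappingTable
) -> tuple[frozenset[str], dict[str, str]]:
    """Replace outdated symbols using the mapping table.

    Unmapped symbols are retained unchanged (recorded as identity in the
    report). Two inputs mapping to the same current symbol collapse to one;
    collapses are logged.

    Returns the harmonized set and a report mapping each input symbol to the
    symbol it became.
    """
    report: dict[str, str] = {}
    seen_targets: dict[str, str] = {}
    out: set[str] = set()
    for g in sorted(normalize_symbol(x) for x in genes):
        new = mapping.entries.get(g, g)
        report[g] = new
        if new in seen_targets and seen_targets[new] != g:
            logger.info("harmonize: %s collapses onto %s (already from %s)",
                        g, new, seen_targets[new])
        seen_targets.setdefault(new, g)
        out.add(new)
    return frozenset(out), report


def merge_sources(a: TargetList, b: TargetList) -> tuple[TargetList, dict[str, int]]:
    """Union two same-vitamin target lists, merging provenance.

    Returns the combined list and summary statistics; the identity
    ``|A| + |B| = |A ∪ B| + |A ∩ B|`` is asserted on every merge.
    """
    if a.vitamin != b.vitamin:
        raise ValueError(f"cannot merge target lists for vitamins {a.vitamin!r} and {b.vitamin!r}")
    union = a.genes | b.genes
    inter = a.genes & b.genes
    stats = {
        "size_a": len(a.genes),
        "size_b": len(b.genes),
        "intersection": len(inter),
        "union": len(union),
    }
    assert stats["union"] + stats["intersection"] == stats["size_a"] + stats["size_b"]
    provenance = {
        g: (a.provenance.get(g, frozenset()) | b.provenance.get(g, frozenset()))
        for g in union
    }
    combined = TargetList(
        vitamin=a.vitamin, label="combined", genes=frozenset(union), provenance=provenance
    )
    return combined, stats


def cross_overlap(a: TargetList, b: TargetList) -> int:
    """Number of genes shared by two target lists (any vitamins)."""
    return len(a.genes & b.genes)


def write_provenance_csv(target: TargetList, path: str | Path) -> Path:
    """Write a (gene, sources) CSV for a target list, sorted by gene."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["gene", "sources"])
        for g in sorted(target.genes):
            writer.writerow([g, ";".join(sorted(target.provenance[g]))])
    return path
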