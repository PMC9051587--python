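"""Gene sets, GMT input/output, and background universes.

Over-representation analysis needs three ingredients from this module: named
gene sets with a known size ``K``, collections of such sets read from GMT
files, and a *background* (universe) of size ``N`` for each source database.
The background policy follows the convention of setting ``N`` to the number
of genes annotated anywhere in the database a gene set came from; gene sets
taken from individual publications, which have no database of their own, fall
back to the largest registered universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

# Canonical source labels. Sources are plain strings so that synthetic
# benchmarks can introduce additional universes without modifying an Enum.
GO = "GO"
REACTOME = "Reactome"
WIKIPATHWAYS = "WikiPathways"
PUBLICATION = "publication"

DATABASE_SOURCES = (GO, REACTOME, WIKIPATHWAYS)


class GmtParseError(ValueError):
    """Raised when a GMT file violates the dialect (see :func:`read_gmt`)."""


class BackgroundConfigError(KeyError):
    """Raised when a gene set's source cannot be resolved to a universe."""


def normalize_symbol(token: str) -> str:
    """Normalize a gene symbol: strip whitespace, upper-case.

    Human gene symbols are conventionally upper case; ingesting everything
    upper-cased makes overlaps insensitive to source-file casing.

    Raises
    ------
    ValueError
        If the token is empty after stripping or contains a tab character.
    """
    if "\t" in token:
        raise ValueError(f"gene symbol contains a tab character: {token!r}")
    symbol = token.strip().upper()
    if not symbol:
        raise ValueError("empty gene symbol")
    return symbol


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of gene symbols from one source database.

    Parameters
    ----------
    name : str
        Set label, unique within its collection (e.g. ``"Renal system
        development"``).
    genes : frozenset of str
        Member gene symbols (set semantics; ``K = len(genes)``).
    source : str
        Originating database (``GO``, ``Reactome``, ``WikiPathways``) or
        ``publication`` for literature-derived sets.
    accession : str, optional
        Database accession such as ``"GO:0072001"`` or ``"WP5053"``.
    """

    name: str
    genes: frozenset[str]
    source: str = PUBLICATION
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty (K must be >= 1)")

    @property
    def size(self) -> int:
        """Set size K."""
        return len(self.genes)

    @classmethod
    def from_symbols(
        cls,
        name: str,
        symbols: Iterable[str],
        source: str = PUBLICATION,
        accession: str | None = None,
    ) -> "GeneSet":
        """Build a set from raw tokens, normalizing and deduplicating them."""
        return cls(name, frozenset(normalize_symbol(s) for s in symbols), source, accession)


@dataclass
class GeneSetCollection:
    """An ordered list of gene sets sharing one source.

    Order is preserved from the origin file and carried through to result
    tables. Set names must be unique within the collection.
    """

    source: str
    sets: list[GeneSet] = field(default_factory=list)
    origin_file: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GmtParseError(f"duplicate gene set name(s): {', '.join(dupes)}")
        for s in self.sets:
            if s.source != self.source:
                raise ValueError(
                    f"set {s.name!r} has source {s.source!r}, collection is {self.source!r}"
                )

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def all_genes(self) -> frozenset[str]:
        """Union of gene symbols across all member sets."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return frozenset(out)


def read_gmt(path: str | Path, source: str = PUBLICATION) -> GeneSetCollection:
    """Read a GMT file into a collection.

    Dialect: tab-separated; field 1 is the set name, field 2 a description
    (ignored), fields 3+ are gene symbols. Duplicate symbols within a line
    collapse; empty gene fields are dropped. Line order is preserved.

    Raises
    ------
    GmtParseError
        On a line with fewer than 3 fields (the line number is reported), a
        line whose gene fields are all empty, or a duplicate set name.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0].strip()
            tokens = [t for t in fields[2:] if t.strip()]
            if not tokens:
                raise GmtParseError(f"{path.name}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet.from_symbols(name, tokens, source=source))
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(source=source, sets=sets, origin_file=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    """Write a collection in GMT dialect (description emitted as ``NA``).

    Genes are written sorted so output is deterministic; a read/write
    round-trip preserves names and memberships exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, "NA", *sorted(s.genes)]) + "\n")
    return path


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a flat gene list: one symbol per line, blank lines ignored."""
    path = Path(path)
    out: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for raw in fh:
            token = raw.strip()
            if token and not token.startswith("#"):
                out.add(normalize_symbol(token))
    return frozenset(out)


def write_gene_list(genes: Iterable[str], path: str | Path) -> Path:
    """Write a flat gene list, one normalized symbol per line, sorted."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for g in sorted({normalize_symbol(g) for g in genes}):
            fh.write(g + "\n")
    return path


def read_background_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping gene-set name -> source label.

    Mirrors the deposited "background" indicator file that states which
    database universe each tested gene set should be scored against.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path.name}:{lineno}: expected 2 tab-separated columns")
            mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def apply_background_map(
    collection: GeneSetCollection, mapping: Mapping[str, str]
) -> list[GeneSetCollection]:
    """Split a mixed-provenance collection into per-source collections.

    A deposited "pathways of interest" GMT mixes sets from several databases;
    ``mapping`` assigns each set name its true source. Returns one collection
    per source, in order of first appearance, preserving within-source set
    order.

    Raises
    ------
    KeyError
        If a set name is missing from the mapping.
    """
    grouped: dict[str, list[GeneSet]] = {}
    for s in collection:
        try:
            src = mapping[s.name]
        except KeyError:
            raise KeyError(f"gene set {s.name!r} missing from background map") from None
        grouped.setdefault(src, []).append(
            GeneSet(s.name, s.genes, source=src, accession=s.accession)
        )
    return [
        GeneSetCollection(source=src, sets=sets, origin_file=collection.origin_file)
        for src, sets in grouped.items()
    ]


@dataclass
class BackgroundRegistry:
    """Per-source gene universes supplying the background size ``N``.

    The universe of a database is the union of gene symbols across all sets
    in that database's background GMT. Publication-derived sets, having no
    database, resolve to the largest registered universe.
    """

    universes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, uni in self.universes.items():
            if not uni:
                raise ValueError(f"universe for source {src!r} is empty")

    @classmethod
    def from_gmt_files(cls, paths_by_source: Mapping[str, str | Path]) -> "BackgroundRegistry":
        """Build a registry from background GMT files, one per source."""
        universes = {
            src: read_gmt(path, source=src).all_genes()
            for src, path in paths_by_source.items()
        }
        return cls(universes=universes)

    def register(self, source: str, genes: Iterable[str]) -> None:
        uni = frozenset(normalize_symbol(g) for g in genes)
        if not uni:
            raise ValueError(f"universe for source {source!r} is empty")
        self.universes[source] = uni

    @property
    def fallback_source(self) -> str:
        """The registered source with the largest universe."""
        if not self.universes:
            raise BackgroundConfigError("background registry is empty")
        return max(self.universes, key=lambda s: (len(self.universes[s]), s))

    def background_for(self, gene_set: GeneSet) -> tuple[frozenset[str], int]:
        """Resolve ``(universe, N)`` for a gene set.

        Database sets get their own universe; publication sets get the
        largest one. Unregistered database sources are configuration errors.
        """
        if gene_set.source == PUBLICATION:
            src = self.fallback_source
        elif gene_set.source in self.universes:
            src = gene_set.source
        else:
            raise BackgroundConfigError(
                f"no background universe registered for source {gene_set.source!r}"
            )
        universe = self.universes[src]
        return universe, len(universe)

    def missing_fraction(self, gene_set: GeneSet) -> float:
        """Fraction of a set's genes absent from its resolved universe.

        Set genes outside the universe are retained (K is the raw set size,
        matching how databases report their sets) but worth monitoring, so
        the fraction is computed and logged per set.
        """
        universe, _ = self.background_for(gene_set)
        frac = len(gene_set.genes - universe) / len(gene_set.genes)
        if frac > 0:
            logger.warning(
                "gene set %r: %.1f%% of genes absent from %s background",
                gene_set.name, 100 * frac, gene_set.source,
            )
        return frac
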