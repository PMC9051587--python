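"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators live here:

* :func:`make_instance` builds a universe + gene-set collections + target
  list in memory, with *planted enrichment*: genes belonging to designated
  sets receive elevated sampling odds (rho) when the target list is drawn,
  giving ground truth for recovery and calibration experiments. At rho = 1
  the target is a uniform simple random sample — exactly the null of the
  overlap test.

* :func:`vitamin_cakut_fixture` writes a complete, file-based replica of the
  vitamin A / vitamin D vs CAKUT study inputs whose cardinalities match the
  published ones exactly (target-list sizes, pairwise intersections, and all
  fourteen gene-set sizes), constructed by deterministic label allocation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curation import TargetList
from .genesets import (
    GO,
    PUBLICATION,
    REACTOME,
    WIKIPATHWAYS,
    BackgroundRegistry,
    GeneSet,
    GeneSetCollection,
    write_gene_list,
)

# --------------------------------------------------------------------------
# Planted-enrichment instances


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic instance.

    universe_sizes : per-source universe cardinalities (disjoint label pools).
    set_sizes : gene-set name -> K.
    set_sources : gene-set name -> source; defaults to the sole source when
        only one universe is configured.
    target_size : n, the number of target genes drawn.
    planted : gene-set name -> odds rho >= 1. Genes of a planted set are
        rho times as likely to enter the target list as unmarked genes;
        rho = 1 is the null.
    seed : RNG seed; the instance is a pure function of (config, seed).
    """

    universe_sizes: dict[str, int]
    set_sizes: dict[str, int]
    target_size: int
    set_sources: dict[str, str] | None = None
    planted: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.universe_sizes:
            raise ValueError("at least one universe is required")
        if self.set_sources is None:
            if len(self.universe_sizes) != 1:
                raise ValueError("set_sources required with multiple universes")
            only = next(iter(self.universe_sizes))
            self.set_sources = {name: only for name in self.set_sizes}
        for name in self.set_sizes:
            src = self.set_sources.get(name)
            if src not in self.universe_sizes:
                raise ValueError(f"set {name!r} assigned to unknown source {src!r}")
            if self.set_sizes[name] > self.universe_sizes[src]:
                raise ValueError(f"set {name!r} larger than its universe")
        for name, rho in self.planted.items():
            if name not in self.set_sizes:
                raise ValueError(f"planted set {name!r} not in set_sizes")
            if rho < 1:
                raise ValueError(f"planted odds must be >= 1, got rho={rho}")
        if self.target_size > min(self.universe_sizes.values()):
            raise ValueError("target_size exceeds the smallest universe")


@dataclass
class SyntheticInstance:
    """A generated universe + collections + target with known ground truth."""

    registry: BackgroundRegistry
    collections: list[GeneSetCollection]
    target: TargetList
    truth: dict[str, float]


def weighted_sample_without_replacement(
    items: np.ndarray, weights: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n items without replacement, successive draws proportional to
    the remaining weights (a Wallenius-type scheme).

    Implemented via the exponential-race equivalence: item i is assigned key
    E_i / w_i with E_i ~ Exp(1), and the n smallest keys win — identical in
    distribution to sequential weighted sampling, but vectorized. With all
    weights equal this is a uniform simple random sample.
    """
    if n > items.size:
        raise ValueError(f"cannot draw {n} from {items.size} items")
    keys = rng.exponential(size=items.size) / weights
    chosen = np.argpartition(keys, n - 1)[:n] if n < items.size else np.arange(items.size)
    return items[chosen]


def make_instance(config: SyntheticConfig) -> SyntheticInstance:
    """Generate one synthetic instance from its config (seed-deterministic).

    Universes are disjoint labelled pools; each gene set is a uniform draw
    of size K from its source universe; the target is drawn from the union
    of universes with per-gene weight max(rho over planted sets containing
    the gene), 1 otherwise.
    """
    rng = np.random.default_rng(config.seed)
    universes: dict[str, np.ndarray] = {}
    for src in sorted(config.universe_sizes):
        size = config.universe_sizes[src]
        universes[src] = np.array(
            [f"{src.upper()}_G{i:06d}" for i in range(size)], dtype=object
        )

    sets_by_source: dict[str, list[GeneSet]] = {}
    truth: dict[str, float] = {}
    planted_genes: dict[str, set[str]] = {}
    for name in config.set_sizes:  # insertion order
        src = config.set_sources[name]
        members = rng.choice(universes[src], size=config.set_sizes[name], replace=False)
        sets_by_source.setdefault(src, []).append(
            GeneSet(name, frozenset(members), source=src)
        )
        rho = float(config.planted.get(name, 1.0))
        truth[name] = rho
        if rho > 1:
            planted_genes[name] = set(members)

    pool = np.concatenate(list(universes.values()))
    weights = np.ones(pool.size)
    if planted_genes:
        weight_of: dict[str, float] = {}
        for name, genes in planted_genes.items():
            rho = truth[name]
            for g in genes:
                weight_of[g] = max(weight_of.get(g, 1.0), rho)
        for i, g in enumerate(pool):
            if g in weight_of:
                weights[i] = weight_of[g]
    drawn = weighted_sample_without_replacement(pool, weights, config.target_size, rng)

    registry = BackgroundRegistry(
        universes={src: frozenset(u) for src, u in universes.items()}
    )
    collections = [
        GeneSetCollection(source=src, sets=sets, origin_file="<synthetic>")
        for src, sets in sets_by_source.items()
    ]
    target = TargetList(vitamin="synthetic", label="synthetic", genes=frozenset(drawn))
    return SyntheticInstance(registry, collections, target, truth)


# --------------------------------------------------------------------------
# File-based study fixture with exact published cardinalities

# (name, source, K) for the fourteen tested gene sets, in report order.
STUDY_SET_SPECS: list[tuple[str, str, int]] = [
    ("CAKUT causal genes", PUBLICATION, 42),
    ("CAKUT DEGs", PUBLICATION, 74),
    ("Renal system development", GO, 315),
    ("Kidney development", GO, 306),
    ("Kidney morphogenesis", GO, 96),
    ("Metabolism of Angiotensinogen to Angiotensins", REACTOME, 18),
    ("RET signaling", REACTOME, 38),
    ("Signaling by WNT", REACTOME, 328),
    ("Signaling by NOTCH", REACTOME, 233),
    ("Signaling by Hedgehog", REACTOME, 149),
    ("Development of ureteric collection system", WIKIPATHWAYS, 47),
    ("Genes controlling nephrogenesis", WIKIPATHWAYS, 43),
    ("Nephrogenesis", WIKIPATHWAYS, 17),
    ("GDNF/RET signaling axis", WIKIPATHWAYS, 23),
]

# Annotation-universe sizes per database, nested WP < Reactome < GO so every
# target gene is present in all backgrounds.
STUDY_UNIVERSE_SIZES = {GO: 17_600, REACTOME: 10_800, WIKIPATHWAYS: 7_800}

# Published target-list cardinalities.
VITA_CTD, VITA_PUB, VITA_INTER = 1086, 521, 229   # union 1378
VITD_CTD, VITD_PUB, VITD_INTER = 263, 210, 15     # union 458
CROSS_AD = 134                                     # |A combined ∩ D combined|

_BG_FILES = {GO: "hsapiens.GO.name.gmt", REACTOME: "hsapiens.REAC.name.gmt",
             WIKIPATHWAYS: "hsapiens.WP.name.gmt"}


@dataclass
class StudyFixture:
    """In-memory handles plus file paths of a written study fixture."""

    out_dir: Path
    targets: dict[str, TargetList]          # "VitA-CTD", "VitA-Publication", ...
    combined: dict[str, TargetList]         # "VitA", "VitD"
    collection_path: Path
    background_map_path: Path
    background_paths: dict[str, Path]
    target_paths: dict[str, Path]
    registry: BackgroundRegistry
    collections: list[GeneSetCollection]


def _write_mixed_gmt(sets: list[GeneSet], path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "NA", *sorted(s.genes)]) + "\n")


def vitamin_cakut_fixture(seed: int, out_dir: str | Path) -> StudyFixture:
    """Write a file-based synthetic replica of the study inputs.

    The emitted files use the same formats the pipeline consumes (flat gene
    lists, GMT collections, a background-indicator TSV, per-database
    background GMTs) and satisfy, simultaneously and exactly:

    * vitamin A: |CTD| = 1086, |publication| = 521, intersection 229
      (combined 1378);
    * vitamin D: |CTD| = 263, |publication| = 210, intersection 15
      (combined 458);
    * |A combined ∩ D combined| = 134;
    * the fourteen gene-set sizes of the tested collection
      (42, 74, 315, 306, 96, 18, 38, 328, 233, 149, 47, 43, 17, 23).

    Overlaps between fixture targets and fixture pathway sets are incidental
    (whatever the seeded draws produce); only the cardinalities above are
    constrained. Output is byte-identical for a given seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_go = STUDY_UNIVERSE_SIZES[GO]
    symbols = np.array([f"G{i:05d}" for i in range(n_go)], dtype=object)
    universes = {
        GO: symbols,
        REACTOME: symbols[: STUDY_UNIVERSE_SIZES[REACTOME]],
        WIKIPATHWAYS: symbols[: STUDY_UNIVERSE_SIZES[WIKIPATHWAYS]],
    }

    # Target lists by deterministic slicing of one shuffled pool drawn from
    # the smallest universe, so every target gene is in every background.
    pool = rng.choice(universes[WIKIPATHWAYS], size=1702, replace=False)
    a_ctd = frozenset(pool[:VITA_CTD])
    a_pub = frozenset(pool[VITA_CTD - VITA_INTER : VITA_CTD - VITA_INTER + VITA_PUB])
    d_ctd = frozenset(pool[:CROSS_AD]) | frozenset(pool[1378 : 1378 + (VITD_CTD - CROSS_AD)])
    d_pub = frozenset(pool[1507 - VITD_INTER : 1507]) | frozenset(pool[1507:1702])

    targets = {
        "VitA-CTD": TargetList("A", "CTD", a_ctd),
        "VitA-Publication": TargetList("A", "Balmer2002", a_pub),
        "VitD-CTD": TargetList("D", "CTD", d_ctd),
        "VitD-Publication": TargetList("D", "Ramagopalan2010", d_pub),
    }

    # Tested gene sets: uniform draws from their source universe
    # (publication sets draw from the largest universe, their fallback).
    study_sets: list[GeneSet] = []
    for name, source, size in STUDY_SET_SPECS:
        pool_src = universes[GO] if source == PUBLICATION else universes[source]
        members = rng.choice(pool_src, size=size, replace=False)
        study_sets.append(GeneSet(name, frozenset(members), source=source))

    # Background GMTs: partition each universe into chunks of ~200 genes so
    # the union of each file's sets reproduces the universe exactly.
    background_paths: dict[str, Path] = {}
    for src, uni in universes.items():
        path = out_dir / _BG_FILES[src]
        with path.open("w", encoding="utf-8") as fh:
            for j, start in enumerate(range(0, uni.size, 200)):
                chunk = sorted(uni[start : start + 200])
                fh.write("\t".join([f"{src}_BG_{j:04d}", "NA", *chunk]) + "\n")
        background_paths[src] = path

    collection_path = out_dir / "PathwaysOfInterest.gmt"
    _write_mixed_gmt(study_sets, collection_path)

    background_map_path = out_dir / "PathwaysOfInterestBackground.txt"
    with background_map_path.open("w", encoding="utf-8") as fh:
        for s in study_sets:
            fh.write(f"{s.name}\t{s.source}\n")

    target_paths = {
        key: write_gene_list(t.genes, out_dir / f"{key.replace('Publication', t.label)}-Genes.txt")
        for key, t in targets.items()
    }

    registry = BackgroundRegistry(
        universes={src: frozenset(u) for src, u in universes.items()}
    )
    grouped: dict[str, list[GeneSet]] = {}
    for s in study_sets:
        grouped.setdefault(s.source, []).append(s)
    collections = [
        GeneSetCollection(source=src, sets=sets, origin_file=str(collection_path))
        for src, sets in grouped.items()
    ]

    from .curation import merge_sources

    combined = {
        "VitA": merge_sources(targets["VitA-CTD"], targets["VitA-Publication"])[0],
        "VitD": merge_sources(targets["VitD-CTD"], targets["VitD-Publication"])[0],
    }

    manifest = {
        "seed": seed,
        "universe_sizes": {k: int(v.size) for k, v in universes.items()},
        "set_sizes": {name: size for name, _, size in STUDY_SET_SPECS},
        "target_sizes": {k: len(t.genes) for k, t in targets.items()},
        "combined_sizes": {k: len(t.genes) for k, t in combined.items()},
    }
    (out_dir / "fixture-manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return StudyFixture(
        out_dir=out_dir,
        targets=targets,
        combined=combined,
        collection_path=collection_path,
        background_map_path=background_map_path,
        background_paths=background_paths,
        target_paths=target_paths,
        registry=registry,
        collections=collections,
    )


def write_truth_json(instance: SyntheticInstance, path: str | Path) -> Path:
    """Write the planted-odds ground truth of an instance as JSON."""
    path = Path(path)
    path.write_text(json.dumps(instance.truth, indent=2, sort_keys=True) + "\n")
    return path
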