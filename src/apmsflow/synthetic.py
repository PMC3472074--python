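"""Synthetic input bundles with planted ground truth.

Generates every file the pipeline consumes — count matrix, interactome
edge lists, annotations, gene sets, construct sequences and peptides —
with the statistical structure the analysis assumes: receptor-specific
proteins planted in each of the seven cell-line (Venn) regions at fold
``f`` over a ratio-1 background, control-dominated "background" and
equal-mean reagent proteins, dense interactome modules aligned with the
planted sets, planted annotation terms, and region-restricted peptides
per construct.

Spectral counts are negative-binomial by default (counts are
overdispersed across replicates); a Poisson model is available. One
integer seed drives independent derived streams per component, so any
single file can be regenerated without touching the others.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from . import io as apio
from .model import (
    BAIT,
    CELL_LINES,
    CONTROL,
    CountMatrix,
    GeneSet,
    ProteinRecord,
    Region,
    RegionMap,
    Sample,
    SampleDesign,
    ValidationError,
)

__all__ = [
    "VENN_REGIONS",
    "SimulationConfig",
    "GroundTruth",
    "ConstructBundle",
    "simulate_counts",
    "simulate_interactome",
    "simulate_annotations",
    "simulate_constructs",
    "simulate_bundle",
]

#: The seven non-empty cell-line subsets, canonically ordered.
VENN_REGIONS: tuple[frozenset[str], ...] = tuple(
    frozenset(c)
    for size in (1, 2, 3)
    for c in itertools.combinations(CELL_LINES, size)
)

_AA = "ACDEFGHIKLMNPQRSTVWY"

# fixed per-component seed-stream ids
_STREAM_COUNTS, _STREAM_NET, _STREAM_ANNOT, _STREAM_SEQ = 11, 13, 17, 19


def region_key(region: frozenset[str]) -> str:
    return "+".join(cl for cl in CELL_LINES if cl in region)


@dataclass
class SimulationConfig:
    seed: int = 0
    # count matrix composition
    #: restrict planting to these Venn region keys (None = all seven)
    planted_regions: tuple[str, ...] | None = None
    n_planted_per_region: int = 6
    n_background: int = 60
    n_reagent: int = 30
    n_other: int = 520
    fold: float = 8.0
    mu: float = 25.0
    mu_control: float = 25.0
    background_bait_mu: float = 2.0
    background_control_mu: float = 30.0
    dispersion: float = 5.0
    poisson: bool = False
    replicates: int = 2
    bait_replicates: dict[str, int] = field(
        default_factory=lambda: {"A4": 3}
    )
    # interactome
    n_extra_nodes: int = 100
    p_background_edge: float = 0.01
    p_module_edge: float = 0.6
    n_sources: int = 2
    # annotation
    n_random_terms: int = 20
    planted_term_coverage: float = 0.9
    random_term_prob: float = 0.05
    # constructs
    propeller_length: int = 240
    leg_length: int = 120
    cyto_length: int = 30
    n_peptides_per_region: int = 8
    min_peptide_length: int = 8
    max_peptide_length: int = 15

    def __post_init__(self) -> None:
        for name in ("p_background_edge", "p_module_edge",
                     "planted_term_coverage", "random_term_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.fold < 1.0:
            raise ValidationError("fold must be >= 1")
        for name in ("n_planted_per_region", "n_background", "n_reagent",
                     "n_other", "replicates", "n_sources",
                     "propeller_length", "leg_length", "cyto_length",
                     "n_peptides_per_region"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if not (2 <= self.min_peptide_length <= self.max_peptide_length):
            raise ValidationError("invalid peptide length range")
        valid = {region_key(r) for r in VENN_REGIONS}
        if self.planted_regions is not None:
            unknown = set(self.planted_regions) - valid
            if unknown:
                raise ValidationError(f"unknown planted region(s) {sorted(unknown)}")

    @property
    def regions(self) -> tuple[frozenset[str], ...]:
        if self.planted_regions is None:
            return VENN_REGIONS
        return tuple(
            r for r in VENN_REGIONS if region_key(r) in self.planted_regions
        )

    @property
    def n_proteins(self) -> int:
        return (
            len(self.regions) * self.n_planted_per_region
            + self.n_background
            + self.n_reagent
            + self.n_other
        )


@dataclass
class GroundTruth:
    """What was planted where, keyed consistently with the emitted files."""

    labels: dict[str, str]  # accession -> venn:<key> | background | reagent | other
    venn: dict[str, frozenset[str]]  # accession -> planted cell-line subset
    symbols: dict[str, str]  # accession -> gene symbol
    modules: dict[str, set[str]]  # venn key -> planted module symbols
    planted_terms: dict[str, str]  # term id -> venn key

    def planted_accessions(self) -> set[str]:
        return set(self.venn)

    def venn_by_symbol(self) -> dict[str, frozenset[str]]:
        return {self.symbols[a]: s for a, s in self.venn.items()}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _draw_count(
    rng: np.random.Generator, mean: float, config: SimulationConfig
) -> int:
    if mean <= 0:
        return 0
    if config.poisson:
        return int(rng.poisson(mean))
    phi = config.dispersion
    # NB with mean mu and variance mu + mu^2/phi
    return int(rng.negative_binomial(phi, phi / (phi + mean)))


def _build_design(config: SimulationConfig) -> SampleDesign:
    samples = []
    for cl in CELL_LINES:
        n_bait = config.bait_replicates.get(cl, config.replicates)
        for r in range(1, n_bait + 1):
            samples.append(Sample(f"{cl}_BAIT_{r}", cl, BAIT, r))
        for r in range(1, config.replicates + 1):
            samples.append(Sample(f"{cl}_CTRL_{r}", cl, CONTROL, r))
    return SampleDesign(samples)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, GroundTruth]:
    """Spectral-count matrix with planted receptor-specific enrichment."""
    rng = _rng(config.seed, _STREAM_COUNTS)
    design = _build_design(config)

    labels: dict[str, str] = {}
    venn: dict[str, frozenset[str]] = {}
    symbols: dict[str, str] = {}
    means: dict[str, dict[str, float]] = {}  # accession -> sample -> mean

    def bait_ctrl_means(
        bait_by_line: Mapping[str, float], control: float
    ) -> dict[str, float]:
        out = {}
        for s in design.samples:
            out[s.sample_id] = (
                bait_by_line[s.cell_line] if s.condition == BAIT else control
            )
        return out

    idx = 0

    def register(label: str, sample_means: dict[str, float]) -> str:
        nonlocal idx
        idx += 1
        acc = f"SYN{idx:04d}"
        labels[acc] = label
        symbols[acc] = f"G{idx:04d}"
        means[acc] = sample_means
        return acc

    for region in config.regions:
        key = region_key(region)
        for _ in range(config.n_planted_per_region):
            bait = {
                cl: config.fold * config.mu if cl in region else config.mu
                for cl in CELL_LINES
            }
            acc = register(f"venn:{key}", bait_ctrl_means(bait, config.mu_control))
            venn[acc] = region
    for _ in range(config.n_background):
        bait = {cl: config.background_bait_mu for cl in CELL_LINES}
        register("background", bait_ctrl_means(bait, config.background_control_mu))
    for _ in range(config.n_reagent):
        bait = {cl: config.mu_control for cl in CELL_LINES}
        register("reagent", bait_ctrl_means(bait, config.mu_control))
    for _ in range(config.n_other):
        # ratio-1 background: bait and control share the baseline mean
        bait = {cl: config.mu for cl in CELL_LINES}
        register("other", bait_ctrl_means(bait, config.mu))

    proteins = [
        ProteinRecord(
            accession=acc,
            gene_symbol=symbols[acc],
            counts={
                sid: _draw_count(rng, m, config)
                for sid, m in means[acc].items()
            },
            probability=1.0,
            n_unique_peptides=2,
        )
        for acc in labels
    ]
    truth = GroundTruth(
        labels=labels,
        venn=venn,
        symbols=symbols,
        modules={},
        planted_terms={},
    )
    return CountMatrix(proteins=proteins, design=design), truth


def simulate_interactome(
    config: SimulationConfig, truth: GroundTruth
) -> list[list[tuple[str, str, str]]]:
    """Erdos-Renyi background plus dense modules on the planted sets.

    Edges are split across ``n_sources`` source lists (a fraction lands
    in more than one) to exercise interactome merging. The planted
    module memberships are recorded on ``truth.modules``.
    """
    rng = _rng(config.seed, _STREAM_NET)
    proteins = sorted(truth.symbols.values())
    extra = [f"X{i:04d}" for i in range(1, config.n_extra_nodes + 1)]
    nodes = proteins + extra

    edges: set[tuple[str, str]] = set()
    n = len(nodes)
    # vectorized ER draw over the upper triangle
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < config.p_background_edge
    for i, j in zip(iu[mask], ju[mask]):
        edges.add(tuple(sorted((nodes[i], nodes[j]))))

    by_symbol = truth.venn_by_symbol()
    modules: dict[str, set[str]] = {}
    for region in config.regions:
        key = region_key(region)
        members = sorted(s for s, r in by_symbol.items() if r == region)
        modules[key] = set(members)
        for a, b in itertools.combinations(members, 2):
            if rng.random() < config.p_module_edge:
                edges.add(tuple(sorted((a, b))))
    truth.modules = modules

    sources: list[list[tuple[str, str, str]]] = [
        [] for _ in range(config.n_sources)
    ]
    for a, b in sorted(edges):
        k = int(rng.integers(config.n_sources))
        sources[k].append((a, b, f"db{k + 1}"))
        if rng.random() < 0.1:  # shared edges exercise provenance merging
            k2 = int(rng.integers(config.n_sources))
            if k2 != k:
                sources[k2].append((a, b, f"db{k2 + 1}"))
    return sources


def simulate_annotations(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], dict[str, GeneSet]]:
    """Gene/term annotations, a rooted relation DAG, and gene sets.

    One planted term per Venn region covers that region's planted
    proteins at the configured coverage; random terms annotate genes at
    low probability; every gene receives a subcellular-localization leaf
    term under one of the six standard category roots. An
    "adhesome-like" curated set overlaps the planted proteins.
    """
    from .network import DEFAULT_LOCALIZATION_ROOTS

    rng = _rng(config.seed, _STREAM_ANNOT)
    symbols = sorted(truth.symbols.values())
    by_symbol = truth.venn_by_symbol()

    loc_roots = [t for ts in DEFAULT_LOCALIZATION_ROOTS.values() for t in ts]
    relations: list[tuple[str, str]] = [(t, "T:ROOT") for t in loc_roots]
    # one annotatable leaf under each localization root
    leaf_of = {t: f"T:LOC{i:02d}" for i, t in enumerate(loc_roots)}
    relations += [(leaf, root) for root, leaf in leaf_of.items()]

    gene_terms: list[tuple[str, str]] = []
    planted_terms: dict[str, str] = {}
    for region in config.regions:
        key = region_key(region)
        term = f"T:SET_{key}"
        planted_terms[term] = key
        relations.append((term, "GO:0005622"))
        members = sorted(s for s, r in by_symbol.items() if r == region)
        for s in members:
            if rng.random() < config.planted_term_coverage:
                gene_terms.append((s, term))
    truth.planted_terms = planted_terms

    for i in range(config.n_random_terms):
        term = f"T:RND{i:03d}"
        relations.append((term, str(rng.choice(loc_roots))))
        for s in symbols:
            if rng.random() < config.random_term_prob:
                gene_terms.append((s, term))

    # every gene gets one localization leaf so the background covers all
    leaves = sorted(leaf_of.values())
    for s in symbols:
        gene_terms.append((s, leaves[int(rng.integers(len(leaves)))]))

    planted_symbols = sorted(by_symbol)
    n_core = max(1, len(planted_symbols) // 3)
    core = list(rng.choice(planted_symbols, size=n_core, replace=False))
    others = [s for s in symbols if s not in by_symbol]
    padding = list(rng.choice(others, size=min(20, len(others)), replace=False))
    gene_sets = {
        "adhesome_like": GeneSet("adhesome_like", core + padding)
    }
    return gene_terms, relations, gene_sets


@dataclass
class ConstructBundle:
    sequences: dict[str, str]
    region_maps: list[RegionMap]
    peptides: dict[str, list[tuple[str, str]]]  # cell line -> (pep, acc)
    expectations: list  # ConstructExpectation


#: Regions each construct retains / lacks on the wild-type receptor map.
_CONSTRUCT_RULES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    # cell line: (permitted regions, forbidden regions)
    "A4": (("propeller", "leg", "cyto"), ()),
    "X4C0": (("propeller", "leg"), ("cyto",)),
    "A4P_A5L": (("propeller",), ("leg", "cyto")),
}


def simulate_constructs(
    config: SimulationConfig, inject_violation: bool = False
) -> ConstructBundle:
    """Construct sequences, region map, and region-restricted peptides.

    All peptides map onto the wild-type receptor sequence; each cell
    line's peptides are sampled only from the regions its construct
    retains. ``inject_violation`` adds one forbidden-region peptide to
    the truncation mutant's list for negative testing.
    """
    from .coverage import ConstructExpectation

    rng = _rng(config.seed, _STREAM_SEQ)

    def random_seq(length: int) -> str:
        return "".join(rng.choice(list(_AA), size=length))

    wt_acc = "ITGA4SYN"
    propeller = random_seq(config.propeller_length)
    leg = random_seq(config.leg_length)
    cyto = random_seq(config.cyto_length)
    alt_leg = random_seq(config.leg_length + config.cyto_length)
    wt = propeller + leg + cyto

    p_end = config.propeller_length
    l_end = p_end + config.leg_length
    c_end = l_end + config.cyto_length
    region_map = RegionMap(
        accession=wt_acc,
        regions=[
            Region("propeller", 1, p_end),
            Region("leg", p_end + 1, l_end),
            Region("cyto", l_end + 1, c_end),
        ],
    )
    sequences = {
        wt_acc: wt,
        "X4C0SYN": propeller + leg,
        "A4PA5LSYN": propeller + alt_leg,
    }

    def sample_peptide(start: int, end: int) -> str:
        # peptide fully inside [start, end] (1-based) of the WT sequence
        length = int(
            rng.integers(config.min_peptide_length, config.max_peptide_length + 1)
        )
        length = min(length, end - start + 1)
        pos = int(rng.integers(start, end - length + 2))
        return wt[pos - 1 : pos - 1 + length]

    def occurs_only_within(pep: str, start: int, end: int) -> bool:
        i = wt.find(pep)
        while i != -1:
            if not (start <= i + 1 and i + len(pep) <= end):
                return False
            i = wt.find(pep, i + 1)
        return True

    peptides: dict[str, list[tuple[str, str]]] = {}
    for cl, (permitted, _forbidden) in _CONSTRUCT_RULES.items():
        peps: list[tuple[str, str]] = []
        for name in permitted:
            region = region_map.get(name)
            for _ in range(config.n_peptides_per_region):
                for _attempt in range(100):
                    pep = sample_peptide(region.start, region.end)
                    if occurs_only_within(pep, region.start, region.end):
                        break
                else:  # pragma: no cover - astronomically unlikely
                    raise RuntimeError("could not sample a region-unique peptide")
                peps.append((pep, wt_acc))
        peptides[cl] = peps

    if inject_violation:
        region = region_map.get("cyto")
        pep = sample_peptide(region.start, region.end)
        peptides["X4C0"].append((pep, wt_acc))

    expectations = [
        ConstructExpectation(
            cell_line=cl,
            accession=wt_acc,
            forbidden_regions=forbidden,
            required_regions=permitted,
        )
        for cl, (permitted, forbidden) in _CONSTRUCT_RULES.items()
    ]
    return ConstructBundle(
        sequences=sequences,
        region_maps=[region_map],
        peptides=peptides,
        expectations=expectations,
    )


def simulate_bundle(
    config: SimulationConfig,
    outdir: str | Path,
    inject_violation: bool = False,
) -> dict[str, Path]:
    """Write a complete, self-consistent input bundle to ``outdir``.

    Returns a name -> path manifest of everything written, including the
    ground-truth table and the resolved configuration.
    """
    from . import coverage as cov

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix, truth = simulate_counts(config)
    edge_sources = simulate_interactome(config, truth)
    gene_terms, relations, gene_sets = simulate_annotations(config, truth)
    constructs = simulate_constructs(config, inject_violation=inject_violation)

    paths: dict[str, Path] = {}

    def reg(name: str, filename: str) -> Path:
        paths[name] = outdir / filename
        return paths[name]

    apio.write_design(matrix.design, reg("design", "design.tsv"))
    apio.write_count_table(matrix, reg("counts", "counts.tsv"))

    # accession -> symbol mapping table (the cross-stage join key)
    import pandas as pd

    pd.DataFrame(
        sorted(truth.symbols.items()), columns=["accession", "gene_symbol"]
    ).to_csv(reg("mapping", "mapping.tsv"), sep="\t", index=False)

    for i, edges in enumerate(edge_sources, start=1):
        # first source as TSV with provenance, second as SIF
        if i == 1:
            apio.write_edge_list(edges, reg("edges_1", "edges_db1.tsv"))
        else:
            apio.write_edge_list(
                edges, reg(f"edges_{i}", f"edges_db{i}.sif"), sif=True
            )

    apio.write_annotations(gene_terms, reg("annotations", "annotations.tsv"))
    apio.write_relations(relations, reg("relations", "relations.tsv"))
    for name, gs in gene_sets.items():
        apio.write_gene_set(gs, reg(f"geneset_{name}", f"{name}.txt"))

    apio.write_fasta(constructs.sequences, reg("fasta", "constructs.fasta"))
    apio.write_region_map(constructs.region_maps, reg("regions", "regions.tsv"))
    for cl, peps in constructs.peptides.items():
        apio.write_peptides(peps, reg(f"peptides_{cl}", f"peptides_{cl}.tsv"))
    cov.write_expectations(
        constructs.expectations, reg("expectations", "expectations.tsv")
    )

    truth_rows = [
        {
            "accession": acc,
            "gene_symbol": truth.symbols[acc],
            "label": label,
            "venn_set": region_key(truth.venn[acc]) if acc in truth.venn else "",
        }
        for acc, label in truth.labels.items()
    ]
    pd.DataFrame(
        truth_rows, columns=["accession", "gene_symbol", "label", "venn_set"]
    ).to_csv(reg("truth", "truth.tsv"), sep="\t", index=False)

    with open(reg("config", "config.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    return paths
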