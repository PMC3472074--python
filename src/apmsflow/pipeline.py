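"""End-to-end pipeline orchestration.

Stages run in a fixed order (quantify -> cluster -> network -> enrich ->
peptide-validate); every output file is listed in a JSON manifest with a
content checksum and all resolved parameter values are written to a run
log, so a rerun with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import cluster as clu
from . import coverage as cov
from . import io as apio
from . import network as net
from . import quantify as qt
from . import terms as tm
from .model import CELL_LINES, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline", "ARTIFACTS"]

#: Artifact filenames produced by a full run, in stage order.
ARTIFACTS = (
    "enrichment.tsv",
    "threshold.tsv",
    "dendrogram.nwk",
    "clusters.tsv",
    "network.graphml",
    "network.sif",
    "venn_partition.tsv",
    "term_enrichment.tsv",
    "peptide_coverage.tsv",
)

_UNMAPPED = {"", "-", "NA", "NAN", "NONE"}


@dataclass
class RunConfig:
    counts: str
    design: str
    edges: list[str]
    annotations: str
    relations: str
    gene_set: str
    fasta: str
    regions: str
    peptides: dict[str, str]  # cell line -> peptide TSV
    expectations: str
    outdir: str
    mapping: str | None = None
    pseudocount: float = 1.0
    linkage: str = "average"
    min_corr: float = 0.6
    control_cap: float = 1.0
    min_fold: float = 5.0
    max_p_bonf: float = 0.1
    background: str = "annotation"  # or "detected"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    @classmethod
    def for_bundle(cls, bundle_dir: str | Path, outdir: str | Path, **kw) -> "RunConfig":
        """Config pointing at a directory written by ``simulate_bundle``."""
        b = Path(bundle_dir)
        edges = sorted(str(p) for p in b.glob("edges_*"))
        return cls(
            counts=str(b / "counts.tsv"),
            design=str(b / "design.tsv"),
            mapping=str(b / "mapping.tsv"),
            edges=edges,
            annotations=str(b / "annotations.tsv"),
            relations=str(b / "relations.tsv"),
            gene_set=str(b / "adhesome_like.txt"),
            fasta=str(b / "constructs.fasta"),
            regions=str(b / "regions.tsv"),
            peptides={
                cl: str(b / f"peptides_{cl}.tsv")
                for cl in CELL_LINES
                if (b / f"peptides_{cl}.tsv").exists()
            },
            expectations=str(b / "expectations.tsv"),
            outdir=str(outdir),
            **kw,
        )

    def validate(self) -> None:
        paths = [self.counts, self.design, self.annotations, self.relations,
                 self.gene_set, self.fasta, self.regions, self.expectations,
                 *self.edges, *self.peptides.values()]
        if self.mapping is not None:
            paths.append(self.mapping)
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise ValidationError(f"input path(s) do not exist: {missing}")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if not (-1.0 <= self.min_corr <= 1.0):
            raise ValidationError("min_corr must be in [-1, 1]")
        if self.control_cap < 0:
            raise ValidationError("control_cap must be >= 0")
        if not (0.0 < self.max_p_bonf <= 1.0):
            raise ValidationError("max_p_bonf must be in (0, 1]")
        if self.background not in ("annotation", "detected"):
            raise ValidationError("background must be 'annotation' or 'detected'")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute all stages; return the artifact -> checksum manifest.

    A stage failure raises :class:`StageError`; artifacts produced by
    completed stages are kept and flagged as partial in the manifest
    file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = ["resolved parameters:"]
    for k, v in asdict(config).items():
        log_lines.append(f"  {k} = {v!r}")

    stage = "quantify"
    try:
        design = apio.read_design(config.design)
        matrix = apio.read_count_table(config.counts, design)
        enrich = qt.build_enrichment_table(matrix, config.pseudocount)
        report = qt.specificity_threshold(enrich["ratio"].tolist())
        enrich = qt.call_specific(enrich, report.threshold)
        qt.write_enrichment_table(enrich, outdir / "enrichment.tsv")
        qt.write_threshold_report(report, outdir / "threshold.tsv")
        log_lines.append(
            f"quantify: {len(matrix)} proteins, threshold "
            f"{report.threshold:.4f} (mean {report.mean_ratio:.4f} + sd "
            f"{report.sd_ratio:.4f}, n={report.n_ratios})"
        )

        stage = "cluster"
        profiles = clu.build_profiles(enrich, config.pseudocount)
        dend = clu.hclust(profiles, linkage=config.linkage)
        selection = clu.select_clusters(
            dend, enrich, min_corr=config.min_corr, control_cap=config.control_cap
        )
        background_nodes = clu.flag_background_clusters(
            dend, enrich,
            ratio_threshold=report.threshold,
            control_cap=config.control_cap,
        )
        clu.write_newick(dend, outdir / "dendrogram.nwk")
        clu.write_cluster_table(selection, outdir / "clusters.tsv")
        log_lines.append(
            f"cluster: {len(selection.clusters)} selected clusters, "
            f"{len(background_nodes)} background nodes"
        )

        stage = "network"
        mapping = (
            apio.read_mapping(config.mapping) if config.mapping else {}
        )
        enrich_net = enrich.copy()
        if mapping:
            enrich_net["gene_symbol"] = [
                mapping.get(a, s)
                for a, s in zip(enrich_net["accession"], enrich_net["gene_symbol"])
            ]
        unmapped = enrich_net["gene_symbol"].str.upper().isin(_UNMAPPED)
        n_unmapped = int(unmapped.groupby(enrich_net["accession"]).any().sum())
        enrich_net = enrich_net[~unmapped]
        edge_lists = [apio.read_edge_list(p) for p in config.edges]
        interactome = net.merge_interactomes(edge_lists)
        partition = net.venn_partition(enrich_net)
        enriched_symbols = set(partition)
        mapped, frac = net.map_coverage(enriched_symbols, interactome)
        sub = net.induced_subnetwork(interactome, enriched_symbols)
        gene_set = apio.read_gene_set(config.gene_set)
        in_set = net.geneset_filter(enriched_symbols, gene_set)
        annotation = apio.read_annotations(config.annotations, config.relations)
        localization = net.annotate_localization(sub.nodes, annotation)
        ratios = {
            cl: dict(
                zip(
                    enrich_net[enrich_net["cell_line"] == cl]["gene_symbol"],
                    enrich_net[enrich_net["cell_line"] == cl]["ratio"],
                )
            )
            for cl in CELL_LINES
        }
        net.write_graphml(
            sub,
            outdir / "network.graphml",
            node_attrs={
                "venn_set": {
                    g: "+".join(cl for cl in CELL_LINES if cl in s)
                    for g, s in partition.items()
                },
                "localization": localization,
                "in_gene_set": {g: str(g in in_set) for g in sub.nodes},
                **{f"ratio_{cl}": ratios[cl] for cl in CELL_LINES},
            },
        )
        net.write_sif(sub, outdir / "network.sif")
        net.write_venn_table(partition, outdir / "venn_partition.tsv")
        log_lines.append(
            f"network: {len(enriched_symbols)} enriched proteins "
            f"({n_unmapped} unmapped dropped), {len(mapped)} mapped "
            f"({frac:.1%}), {sub.n_edges} induced edges, "
            f"{len(in_set)} in gene set {gene_set.name!r}"
        )

        stage = "enrich"
        background = (
            sorted(set(enrich_net["gene_symbol"]))
            if config.background == "detected"
            else None
        )
        rows = []
        for cl in CELL_LINES:
            genes = {g for g, s in partition.items() if cl in s}
            if not genes:
                continue
            for r in tm.enrich_set(
                genes,
                annotation,
                min_fold=config.min_fold,
                max_p_bonf=config.max_p_bonf,
                background=background,
            ):
                rows.append({"set": cl, **asdict(r)})
        pd.DataFrame(
            rows,
            columns=["set", "term", "k", "n", "K", "N", "fold", "p",
                     "p_bonferroni", "overrepresented"],
        ).to_csv(outdir / "term_enrichment.tsv", sep="\t", index=False)
        log_lines.append(f"enrich: {len(rows)} term tests")

        stage = "peptide-validate"
        sequences = apio.read_fasta(config.fasta)
        region_maps = {m.accession: m for m in apio.read_region_map(config.regions)}
        for acc, m in region_maps.items():
            if acc in sequences:
                m.validate_against(sequences[acc])
        expectations = cov.read_expectations(config.expectations)
        forbidden_by_key = {
            (e.cell_line, e.accession): e.forbidden_regions for e in expectations
        }
        reports: dict[tuple[str, str], cov.RegionCoverageReport] = {}
        for cl, path in config.peptides.items():
            peptides = apio.read_peptides(path)
            by_acc: dict[str, list[str]] = {}
            for pep, acc in peptides:
                by_acc.setdefault(acc, []).append(pep)
            for acc, peps in by_acc.items():
                if acc not in region_maps:
                    continue
                hits = cov.locate_peptides(peps, sequences[acc], accession=acc)
                reports[(cl, acc)] = cov.region_coverage(
                    hits,
                    region_maps[acc],
                    forbidden_regions=forbidden_by_key.get((cl, acc), ()),
                )
        summary = cov.validate_construct(reports, expectations, region_maps)
        cov.write_coverage_report(reports, summary, outdir / "peptide_coverage.tsv")
        log_lines.append(
            "peptide-validate: "
            + ("PASS" if summary.passed else f"FAIL ({len(summary.failures)})")
        )
    except Exception as exc:
        manifest = _write_manifest(outdir, partial=True)
        (outdir / "run.log").write_text(
            "\n".join(log_lines + [f"FAILED at stage {stage}: {exc}"]) + "\n",
            encoding="utf-8",
        )
        if isinstance(exc, StageError):  # pragma: no cover
            raise
        raise StageError(stage, exc) from exc

    manifest = _write_manifest(outdir, partial=False)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return manifest


def _write_manifest(outdir: Path, partial: bool) -> dict[str, str]:
    manifest = {
        name: _sha256(outdir / name)
        for name in ARTIFACTS
        if (outdir / name).is_file()
    }
    payload: dict[str, object] = dict(manifest)
    if partial:
        payload["_partial"] = True
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return manifest
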