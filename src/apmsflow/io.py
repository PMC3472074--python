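"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are tab-separated UTF-8 with a header row; lines
starting with ``#`` are ignored. Sequences travel as FASTA, interaction
edges as SIF (``A pp B``) or two/three-column TSV, annotations as a
GAF-like gene/term TSV plus a child/parent relations TSV, and gene sets
as one symbol per line.
"""

from __future__ import annotations

import csv
import io as _stdio
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CountMatrix,
    FormatError,
    GeneSet,
    ProteinRecord,
    Region,
    RegionMap,
    Sample,
    SampleDesign,
    ValidationError,
)
from .terms import TermAnnotation

__all__ = [
    "read_design",
    "write_design",
    "read_count_table",
    "write_count_table",
    "read_region_map",
    "write_region_map",
    "read_edge_list",
    "write_edge_list",
    "read_gene_set",
    "write_gene_set",
    "read_annotations",
    "write_annotations",
    "write_relations",
    "read_mapping",
    "read_fasta",
    "write_fasta",
    "read_peptides",
    "write_peptides",
]

_META_COLUMNS = ("accession", "gene_symbol", "probability", "n_unique_peptides")


def _read_tsv(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


# -- sample design ---------------------------------------------------------


def read_design(path: str | Path) -> SampleDesign:
    df = _read_tsv(path, required=("sample_id", "cell_line", "condition", "replicate"))
    samples = []
    for i, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: row {i + 2}: replicate {row['replicate']!r} is not an integer"
            ) from exc
        samples.append(
            Sample(
                sample_id=str(row["sample_id"]),
                cell_line=str(row["cell_line"]),
                condition=str(row["condition"]).upper(),
                replicate=rep,
            )
        )
    return SampleDesign(samples)


def write_design(design: SampleDesign, path: str | Path) -> None:
    rows = [
        (s.sample_id, s.cell_line, s.condition, s.replicate)
        for s in design.samples
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "cell_line", "condition", "replicate"]
    ).to_csv(path, sep="\t", index=False)


# -- count matrix ----------------------------------------------------------


def read_count_table(path: str | Path, design: SampleDesign) -> CountMatrix:
    """Parse a protein x sample spectral-count TSV against ``design``.

    Count columns are matched to design sample ids by name. Metadata
    columns ``probability`` and ``n_unique_peptides`` are optional.
    """
    df = _read_tsv(path, required=("accession", "gene_symbol"))
    for sid in design.sample_ids:
        if sid not in df.columns:
            raise FormatError(f"{path}: missing count column for sample {sid!r}")

    proteins: list[ProteinRecord] = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        counts: dict[str, int] = {}
        for sid in design.sample_ids:
            raw = row[sid]
            try:
                val = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: row {rownum}: count {raw!r} for {sid} is not numeric"
                ) from exc
            if val < 0 or val != int(val):
                raise ValidationError(
                    f"{path}: row {rownum}: count {raw!r} for {sid} must be a "
                    "non-negative integer"
                )
            counts[sid] = int(val)
        prob = None
        if "probability" in df.columns and not pd.isna(row["probability"]):
            prob = float(row["probability"])
        npep = None
        if "n_unique_peptides" in df.columns and not pd.isna(row["n_unique_peptides"]):
            npep = int(float(row["n_unique_peptides"]))
        proteins.append(
            ProteinRecord(
                accession=str(row["accession"]),
                gene_symbol=str(row["gene_symbol"]),
                counts=counts,
                probability=prob,
                n_unique_peptides=npep,
            )
        )
    return CountMatrix(proteins=proteins, design=design)


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    sids = list(matrix.design.sample_ids)
    rows = []
    for p in matrix.proteins:
        row: dict[str, object] = {
            "accession": p.accession,
            "gene_symbol": p.gene_symbol,
            "probability": "" if p.probability is None else p.probability,
            "n_unique_peptides": "" if p.n_unique_peptides is None else p.n_unique_peptides,
        }
        row.update({sid: p.counts[sid] for sid in sids})
        rows.append(row)
    pd.DataFrame(rows, columns=list(_META_COLUMNS) + sids).to_csv(
        path, sep="\t", index=False
    )


# -- region maps -----------------------------------------------------------


def read_region_map(path: str | Path) -> list[RegionMap]:
    df = _read_tsv(path, required=("accession", "region_name", "start", "end"))
    maps: dict[str, list[Region]] = {}
    for i, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: row {i + 2}: non-integer region bounds"
            ) from exc
        maps.setdefault(str(row["accession"]), []).append(
            Region(name=str(row["region_name"]), start=start, end=end)
        )
    return [RegionMap(accession=a, regions=rs) for a, rs in maps.items()]


def write_region_map(maps: Iterable[RegionMap], path: str | Path) -> None:
    rows = [
        (m.accession, r.name, r.start, r.end)
        for m in maps
        for r in m.regions
    ]
    pd.DataFrame(rows, columns=["accession", "region_name", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


# -- interaction edges -----------------------------------------------------


def read_edge_list(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse SIF (``A pp B``) or 2-3-column TSV edges.

    Self-loops are dropped and symbols upper-cased; endpoint order is
    preserved as read (canonicalization happens at interactome merge).
    The third TSV column, when present, is a provenance tag; for SIF and
    2-column TSV the file stem is used.
    """
    path = Path(path)
    default_tag = path.stem
    edges: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                fields = line.split("\t")
                if len(fields) == 2:
                    a, b, tag = fields[0], fields[1], default_tag
                elif len(fields) == 3:
                    a, b, tag = fields
                else:
                    raise FormatError(
                        f"{path}: line {lineno}: expected 2 or 3 tab-separated "
                        f"fields, got {len(fields)}"
                    )
            else:
                fields = line.split()
                if len(fields) != 3 or fields[1].lower() != "pp":
                    raise FormatError(
                        f"{path}: line {lineno}: expected SIF 'A pp B', got {line!r}"
                    )
                a, b, tag = fields[0], fields[2], default_tag
            if not a or not b:
                raise FormatError(f"{path}: line {lineno}: empty endpoint")
            a, b = a.upper(), b.upper()
            if a == b:
                continue
            edges.append((a, b, tag))
    return edges


def write_edge_list(
    edges: Iterable[tuple[str, str, str]], path: str | Path, sif: bool = False
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, tag in edges:
            if sif:
                fh.write(f"{a} pp {b}\n")
            else:
                fh.write(f"{a}\t{b}\t{tag}\n")


# -- gene sets -------------------------------------------------------------


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    path = Path(path)
    members = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.append(line)
    return GeneSet(name=name or path.stem, members=members)


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in sorted(gene_set.members):
            fh.write(m + "\n")


# -- annotations -----------------------------------------------------------


def read_annotations(
    gaf_path: str | Path, relations_path: str | Path | None = None
) -> TermAnnotation:
    """Build a :class:`TermAnnotation` from gene/term and relation TSVs.

    The relation file lists ``child<TAB>parent`` pairs and must be
    acyclic; with no relation file the rollup is the identity.
    """
    gaf = _read_tsv(gaf_path, required=("gene_symbol", "term"))
    gene_terms = [
        (str(r["gene_symbol"]), str(r["term"])) for _, r in gaf.iterrows()
    ]
    relations: list[tuple[str, str]] = []
    if relations_path is not None:
        rel = _read_tsv(relations_path, required=("child", "parent"))
        relations = [(str(r["child"]), str(r["parent"])) for _, r in rel.iterrows()]
    return TermAnnotation(gene_terms, relations)


def write_annotations(
    gene_terms: Iterable[tuple[str, str]], path: str | Path
) -> None:
    pd.DataFrame(list(gene_terms), columns=["gene_symbol", "term"]).to_csv(
        path, sep="\t", index=False
    )


def write_relations(
    relations: Iterable[tuple[str, str]], path: str | Path
) -> None:
    pd.DataFrame(list(relations), columns=["child", "parent"]).to_csv(
        path, sep="\t", index=False
    )


# -- accession -> symbol mapping ------------------------------------------


def read_mapping(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, required=("accession", "gene_symbol"))
    return {
        str(r["accession"]): str(r["gene_symbol"]).upper()
        for _, r in df.iterrows()
    }


# -- sequences -------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- peptides --------------------------------------------------------------


def read_peptides(path: str | Path) -> list[tuple[str, str]]:
    """Read (peptide sequence, parent accession) pairs."""
    df = _read_tsv(path, required=("peptide", "accession"))
    return [(str(r["peptide"]), str(r["accession"])) for _, r in df.iterrows()]


def write_peptides(
    peptides: Iterable[tuple[str, str]], path: str | Path
) -> None:
    pd.DataFrame(list(peptides), columns=["peptide", "accession"]).to_csv(
        path, sep="\t", index=False
    )
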