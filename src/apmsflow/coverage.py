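"""Peptide-to-sequence mapping and construct-specific coverage checks.

The receptor variants differ in which sequence regions they retain, so
the peptides identified from each cell line must map only into the
regions its construct actually contains. Matching is exact (I and L are
distinct); a peptide counts toward a region when its interval overlaps
the region by at least one residue, so a peptide may count toward two
adjacent regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import RegionMap, ValidationError

__all__ = [
    "AMINO_ACIDS",
    "PeptideHit",
    "RegionCoverageReport",
    "ConstructExpectation",
    "ValidationSummary",
    "locate_peptides",
    "region_coverage",
    "validate_construct",
    "read_expectations",
    "write_expectations",
    "write_coverage_report",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideHit:
    """All exact occurrences of one peptide in its parent sequence."""

    peptide: str
    accession: str
    matches: tuple[tuple[int, int], ...]  # 1-based inclusive


def locate_peptides(
    peptides: Iterable[str], sequence: str, accession: str = ""
) -> list[PeptideHit]:
    """Exact-match every peptide against ``sequence``.

    Reports all (possibly overlapping) occurrences; a peptide that does
    not occur yields an empty match list.
    """
    seq = sequence.upper()
    if not set(seq) <= AMINO_ACIDS:
        bad = sorted(set(seq) - AMINO_ACIDS)
        raise ValidationError(f"sequence contains non-amino-acid characters {bad}")
    hits = []
    for pep in peptides:
        pep = pep.upper()
        if not pep or not set(pep) <= AMINO_ACIDS:
            raise ValidationError(
                f"peptide {pep!r} contains non-amino-acid characters"
            )
        matches: list[tuple[int, int]] = []
        start = seq.find(pep)
        while start != -1:
            matches.append((start + 1, start + len(pep)))
            start = seq.find(pep, start + 1)
        hits.append(
            PeptideHit(peptide=pep, accession=accession, matches=tuple(matches))
        )
    return hits


@dataclass
class RegionCoverageReport:
    """Per-region peptide and residue coverage plus forbidden overlaps."""

    accession: str
    n_peptides: dict[str, int]
    n_residues_covered: dict[str, int]
    violations: list[tuple[str, str]]  # (peptide, forbidden region)

    def total_peptides(self) -> int:
        return sum(self.n_peptides.values())


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int] | None:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo <= hi else None


def region_coverage(
    hits: Sequence[PeptideHit],
    region_map: RegionMap,
    forbidden_regions: Iterable[str] = (),
) -> RegionCoverageReport:
    """Assign peptide matches to regions and count residue coverage.

    ``forbidden_regions`` names regions the construct lacks; any peptide
    overlapping one is recorded as a violation.
    """
    forbidden = set(forbidden_regions)
    unknown = forbidden - region_map.names()
    if unknown:
        raise ValidationError(
            f"{region_map.accession}: unknown forbidden region(s) {sorted(unknown)}"
        )
    n_peptides = {r.name: 0 for r in region_map.regions}
    covered: dict[str, set[int]] = {r.name: set() for r in region_map.regions}
    violations: list[tuple[str, str]] = []
    for hit in hits:
        touched: set[str] = set()
        for interval in hit.matches:
            for region in region_map.regions:
                ov = _overlap(interval, (region.start, region.end))
                if ov is None:
                    continue
                touched.add(region.name)
                covered[region.name].update(range(ov[0], ov[1] + 1))
        for name in touched:
            n_peptides[name] += 1
        for name in sorted(touched & forbidden):
            violations.append((hit.peptide, name))
    return RegionCoverageReport(
        accession=region_map.accession,
        n_peptides=n_peptides,
        n_residues_covered={k: len(v) for k, v in covered.items()},
        violations=violations,
    )


@dataclass(frozen=True)
class ConstructExpectation:
    cell_line: str
    accession: str
    forbidden_regions: tuple[str, ...]
    required_regions: tuple[str, ...]


@dataclass
class ValidationSummary:
    passed: bool
    failures: list[str] = field(default_factory=list)


def validate_construct(
    reports: Mapping[tuple[str, str], RegionCoverageReport],
    expectations: Sequence[ConstructExpectation],
    region_maps: Mapping[str, RegionMap] | None = None,
) -> ValidationSummary:
    """Check per-cell-line coverage reports against construct expectations.

    Passes iff every expectation sees zero forbidden-region violations
    and at least one peptide in each required region. With no
    expectations the result is a vacuous pass.
    """
    failures: list[str] = []
    for exp in expectations:
        if region_maps is not None:
            known = region_maps[exp.accession].names()
            for name in (*exp.forbidden_regions, *exp.required_regions):
                if name not in known:
                    raise ValidationError(
                        f"{exp.cell_line}/{exp.accession}: expectation references "
                        f"unknown region {name!r}"
                    )
        key = (exp.cell_line, exp.accession)
        report = reports.get(key)
        if report is None:
            failures.append(f"{exp.cell_line}/{exp.accession}: no coverage report")
            continue
        for name in exp.forbidden_regions:
            if name not in report.n_peptides:
                raise ValidationError(
                    f"{exp.cell_line}/{exp.accession}: expectation references "
                    f"unknown region {name!r}"
                )
        for pep, region in report.violations:
            if region in exp.forbidden_regions:
                failures.append(
                    f"{exp.cell_line}/{exp.accession}: peptide {pep} overlaps "
                    f"forbidden region {region}"
                )
        for name in exp.required_regions:
            if name not in report.n_peptides:
                raise ValidationError(
                    f"{exp.cell_line}/{exp.accession}: expectation references "
                    f"unknown region {name!r}"
                )
            if report.n_peptides[name] == 0:
                failures.append(
                    f"{exp.cell_line}/{exp.accession}: required region {name} "
                    "has no peptides"
                )
    return ValidationSummary(passed=not failures, failures=failures)


# -- persistence -----------------------------------------------------------


def read_expectations(path: str | Path) -> list[ConstructExpectation]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(
            ConstructExpectation(
                cell_line=str(row["cell_line"]),
                accession=str(row["accession"]),
                forbidden_regions=tuple(
                    s for s in str(row["forbidden_regions"]).split(",") if s
                ),
                required_regions=tuple(
                    s for s in str(row["required_regions"]).split(",") if s
                ),
            )
        )
    return out


def write_expectations(
    expectations: Iterable[ConstructExpectation], path: str | Path
) -> None:
    rows = [
        {
            "cell_line": e.cell_line,
            "accession": e.accession,
            "forbidden_regions": ",".join(e.forbidden_regions),
            "required_regions": ",".join(e.required_regions),
        }
        for e in expectations
    ]
    pd.DataFrame(
        rows,
        columns=["cell_line", "accession", "forbidden_regions", "required_regions"],
    ).to_csv(path, sep="\t", index=False)


def write_coverage_report(
    reports: Mapping[tuple[str, str], RegionCoverageReport],
    summary: ValidationSummary,
    path: str | Path,
) -> None:
    rows = []
    for (cell_line, acc), rep in sorted(reports.items()):
        for region in rep.n_peptides:
            rows.append(
                {
                    "cell_line": cell_line,
                    "accession": acc,
                    "region": region,
                    "n_peptides": rep.n_peptides[region],
                    "n_residues_covered": rep.n_residues_covered[region],
                    "n_violations": sum(
                        1 for _, r in rep.violations if r == region
                    ),
                }
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# construct validation: {'PASS' if summary.passed else 'FAIL'}\n")
        for f in summary.failures:
            fh.write(f"# failure: {f}\n")
        pd.DataFrame(
            rows,
            columns=[
                "cell_line",
                "accession",
                "region",
                "n_peptides",
                "n_residues_covered",
                "n_violations",
            ],
        ).to_csv(fh, sep="\t", index=False)
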