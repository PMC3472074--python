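"""Core domain types shared across the pipeline.

Conventions used throughout:

* residue coordinates are 1-based and inclusive;
* gene symbols are upper-cased on load and act as the join key between
  the quantification, network, annotation, and gene-set stages;
* spectral counts are non-negative integers keyed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CELL_LINES",
    "BAIT",
    "CONTROL",
    "FormatError",
    "ValidationError",
    "Sample",
    "SampleDesign",
    "ProteinRecord",
    "CountMatrix",
    "RegionMap",
    "GeneSet",
]

#: Canonical cell-line labels: wild-type receptor, cytoplasmic-tail
#: truncation, and the propeller/leg chimera.
CELL_LINES: tuple[str, ...] = ("A4", "X4C0", "A4P_A5L")

BAIT = "BAIT"
CONTROL = "CONTROL"
CONDITIONS = (BAIT, CONTROL)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    cell_line: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise ValidationError(
                f"unknown cell line {self.cell_line!r}; expected one of {CELL_LINES}"
            )
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not isinstance(self.replicate, int) or self.replicate < 1:
            raise ValidationError(
                f"replicate must be a positive integer, got {self.replicate!r}"
            )


@dataclass(frozen=True)
class SampleDesign:
    """The cell line x condition x replicate layout of one experiment."""

    samples: tuple[Sample, ...]

    def __init__(self, samples: Iterable[Sample]) -> None:
        object.__setattr__(self, "samples", tuple(samples))
        self._validate()

    def _validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        conditions = {s.condition for s in self.samples}
        if BAIT not in conditions or CONTROL not in conditions:
            raise ValidationError(
                "design must contain at least one BAIT and one CONTROL sample"
            )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)

    @property
    def cell_lines(self) -> tuple[str, ...]:
        """Cell lines present, in canonical order."""
        present = {s.cell_line for s in self.samples}
        return tuple(cl for cl in CELL_LINES if cl in present)

    def samples_for(
        self, cell_line: str | None = None, condition: str | None = None
    ) -> tuple[Sample, ...]:
        return tuple(
            s
            for s in self.samples
            if (cell_line is None or s.cell_line == cell_line)
            and (condition is None or s.condition == condition)
        )


@dataclass
class ProteinRecord:
    """One identified protein with its per-sample spectral counts.

    ``probability`` and ``n_unique_peptides`` are carried through from
    upstream protein inference so the identification filter can be
    re-applied, but both are optional.
    """

    accession: str
    gene_symbol: str
    counts: dict[str, int]
    probability: float | None = None
    n_unique_peptides: int | None = None

    def __post_init__(self) -> None:
        self.gene_symbol = self.gene_symbol.upper()
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise ValidationError(
                f"{self.accession}: probability {self.probability} outside [0, 1]"
            )
        if self.n_unique_peptides is not None and self.n_unique_peptides < 0:
            raise ValidationError(
                f"{self.accession}: negative unique-peptide count"
            )
        for sid, c in self.counts.items():
            if not isinstance(c, (int,)) or isinstance(c, bool) or c < 0:
                raise ValidationError(
                    f"{self.accession}: count for {sid} must be a non-negative "
                    f"integer, got {c!r}"
                )


@dataclass
class CountMatrix:
    """Rectangular proteins x samples spectral-count matrix with design."""

    proteins: list[ProteinRecord]
    design: SampleDesign

    def __post_init__(self) -> None:
        accs = [p.accession for p in self.proteins]
        if len(accs) != len(set(accs)):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValidationError(f"duplicate accessions: {dupes}")
        expected = set(self.design.sample_ids)
        for p in self.proteins:
            if set(p.counts) != expected:
                missing = sorted(expected - set(p.counts))
                extra = sorted(set(p.counts) - expected)
                raise ValidationError(
                    f"{p.accession}: counts not keyed by design sample ids "
                    f"(missing={missing}, extra={extra})"
                )

    def __len__(self) -> int:
        return len(self.proteins)

    @property
    def accessions(self) -> list[str]:
        return [p.accession for p in self.proteins]

    def get(self, accession: str) -> ProteinRecord:
        for p in self.proteins:
            if p.accession == accession:
                return p
        raise KeyError(accession)


@dataclass(frozen=True)
class Region:
    name: str
    start: int
    end: int


@dataclass
class RegionMap:
    """Named, non-overlapping residue intervals on one protein sequence."""

    accession: str
    regions: list[Region]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(names) != len(set(names)):
            raise ValidationError(
                f"{self.accession}: duplicate region names"
            )
        for r in self.regions:
            if not (1 <= r.start <= r.end):
                raise ValidationError(
                    f"{self.accession}/{r.name}: invalid interval "
                    f"[{r.start}, {r.end}] (need 1 <= start <= end)"
                )
        ordered = sorted(self.regions, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"{self.accession}: regions {a.name} and {b.name} overlap"
                )

    def names(self) -> set[str]:
        return {r.name for r in self.regions}

    def get(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"{self.accession}: no region named {name!r}")

    def validate_against(self, sequence: str) -> None:
        """Check all intervals fit within ``sequence``."""
        for r in self.regions:
            if r.end > len(sequence):
                raise ValidationError(
                    f"{self.accession}/{r.name}: end {r.end} exceeds sequence "
                    f"length {len(sequence)}"
                )


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __init__(self, name: str, members: Iterable[str]) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(
            self, "members", frozenset(m.upper() for m in members)
        )
        if not self.members:
            raise ValidationError(f"gene set {name!r} is empty")

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.members

    def __len__(self) -> int:
        return len(self.members)
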