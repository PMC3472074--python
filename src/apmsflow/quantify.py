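"""Spectral-count quantification and specificity thresholding.

Replicates are averaged (not summed) per condition so that cell lines
with unequal replicate numbers remain comparable; the bait/control
enrichment ratio uses a symmetric pseudocount to keep ratios finite
when control counts are zero. The specificity cut-off is the mean plus
one sample standard deviation of the pooled ratio distribution, applied
inclusively (ratio >= threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import BAIT, CONTROL, CountMatrix

__all__ = [
    "aggregate_replicates",
    "enrichment_ratio",
    "build_enrichment_table",
    "specificity_threshold",
    "call_specific",
    "dataset_overlap",
    "ThresholdReport",
    "write_enrichment_table",
    "read_enrichment_table",
    "write_threshold_report",
]

#: Default symmetric pseudocount for ratio computation.
DEFAULT_PSEUDOCOUNT = 1.0

ENRICHMENT_COLUMNS = [
    "accession",
    "gene_symbol",
    "cell_line",
    "bait_mean",
    "control_mean",
    "ratio",
    "specific",
]


def aggregate_replicates(
    matrix: CountMatrix, cell_line: str, condition: str
) -> dict[str, float]:
    """Arithmetic mean of replicate counts per protein accession."""
    samples = matrix.design.samples_for(cell_line=cell_line, condition=condition)
    if not samples:
        raise ValueError(f"no samples for ({cell_line}, {condition})")
    sids = [s.sample_id for s in samples]
    return {
        p.accession: float(np.mean([p.counts[sid] for sid in sids]))
        for p in matrix.proteins
    }


def enrichment_ratio(
    bait_mean: float, control_mean: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Bait over control mean count, with a symmetric pseudocount."""
    if bait_mean < 0 or control_mean < 0:
        raise ValueError("mean counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    denom = control_mean + pseudocount
    if denom == 0:
        raise ZeroDivisionError(
            "control mean is 0 with pseudocount 0; supply a positive "
            "pseudocount to obtain finite ratios"
        )
    return (bait_mean + pseudocount) / denom


def build_enrichment_table(
    matrix: CountMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-(protein, cell line) bait/control means and enrichment ratios.

    Returns a dataframe with :data:`ENRICHMENT_COLUMNS`; the ``specific``
    column is unset until :func:`call_specific` is applied.
    """
    frames = []
    symbols = {p.accession: p.gene_symbol for p in matrix.proteins}
    for cl in matrix.design.cell_lines:
        bait = aggregate_replicates(matrix, cl, BAIT)
        ctrl = aggregate_replicates(matrix, cl, CONTROL)
        for acc in matrix.accessions:
            frames.append(
                {
                    "accession": acc,
                    "gene_symbol": symbols[acc],
                    "cell_line": cl,
                    "bait_mean": bait[acc],
                    "control_mean": ctrl[acc],
                    "ratio": enrichment_ratio(bait[acc], ctrl[acc], pseudocount),
                    "specific": pd.NA,
                }
            )
    return pd.DataFrame(frames, columns=ENRICHMENT_COLUMNS)


@dataclass(frozen=True)
class ThresholdReport:
    """Mean + 1 sample SD specificity cut-off, with its ingredients."""

    mean_ratio: float
    sd_ratio: float
    threshold: float
    n_ratios: int


def specificity_threshold(ratios: Sequence[float]) -> ThresholdReport:
    """Cut-off = mean + one sample (n-1) standard deviation of ratios."""
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 ratios to estimate a threshold")
    if not np.all(np.isfinite(arr)):
        raise ValueError("ratios must be finite")
    mean = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1))
    return ThresholdReport(
        mean_ratio=mean, sd_ratio=sd, threshold=mean + sd, n_ratios=int(arr.size)
    )


def call_specific(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Set ``specific = ratio >= threshold`` (inclusive); idempotent."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = table.copy()
    out["specific"] = out["ratio"] >= threshold
    return out


def dataset_overlap(
    set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[int, float]:
    """Intersection size and the fraction of ``set_b`` shared with ``set_a``."""
    a = {s.upper() for s in set_a}
    b = {s.upper() for s in set_b}
    if not b:
        raise ValueError("reference set B is empty")
    inter = len(a & b)
    return inter, inter / len(b)


# -- persistence -----------------------------------------------------------


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "specific" in df.columns:
        df["specific"] = df["specific"].map(
            lambda v: pd.NA if pd.isna(v) else bool(v)
        )
    return df


def write_threshold_report(report: ThresholdReport, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "mean_ratio": report.mean_ratio,
                "sd_ratio": report.sd_ratio,
                "threshold": report.threshold,
                "n_ratios": report.n_ratios,
            }
        ]
    ).to_csv(path, sep="\t", index=False)
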