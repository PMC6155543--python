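"""Per-sample burden metrics, purity/ploidy solution selection, and
genomic-instability classes.

Samples are stratified by mutation burden and copy-number burden into four
classes: Low (few of both), M (>300 mutations, <80 altered segments,
mutational instability), C (>80 altered segments, <300 mutations,
chromosomal instability), and MC (high in both).  A copy-number segment
counts as altered when its mean log-ratio is strictly above 0.3 (gain) or
strictly below -0.3 (loss).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbsoluteSolution",
    "SampleMetrics",
    "count_mutations",
    "count_cna_segments",
    "mean_rms",
    "select_absolute_solution",
    "classify_instability",
    "sample_metrics_table",
    "clone_heatmap",
]

INSTABILITY_CLASSES = ("Low", "M", "C", "MC")


@dataclass(frozen=True)
class AbsoluteSolution:
    """One purity/ploidy solution for a sample."""

    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be > 0, got {self.ploidy}")


@dataclass(frozen=True)
class SampleMetrics:
    sample_id: str
    n_mutations: int
    n_cna_segments: int
    mean_rms: Optional[float]
    purity: Optional[float]
    ploidy: Optional[float]
    instability_class: str


def count_mutations(records: pd.DataFrame) -> int:
    """Number of variant rows for one sample; all variant classes count."""
    return int(len(records))


def count_cna_segments(
    segments: pd.DataFrame, gain_thr: float = 0.3, loss_thr: float = -0.3
) -> int:
    """Segments with mean log-ratio strictly above/below the gain/loss cuts."""
    if len(segments) == 0:
        return 0
    v = segments["Segment_Mean"].to_numpy(dtype=float)
    return int(((v > gain_thr) | (v < loss_thr)).sum())


def mean_rms(records: pd.DataFrame) -> Optional[float]:
    """Mean number of reads covering a mutated site (ref + alt reads).

    Undefined (None) for a sample without mutations.
    """
    if len(records) == 0:
        return None
    depth = records["t_ref_count"].to_numpy(float) + records["t_alt_count"].to_numpy(float)
    return float(depth.mean())


def select_absolute_solution(
    solutions: Sequence[AbsoluteSolution], reference: AbsoluteSolution
) -> AbsoluteSolution:
    """Pick the solution minimizing squared Euclidean distance to a reference
    (purity, ploidy) pair; ties resolve to the first listed."""
    if not solutions:
        raise ValueError("no candidate solutions")
    best = min(
        range(len(solutions)),
        key=lambda i: (
            (solutions[i].purity - reference.purity) ** 2
            + (solutions[i].ploidy - reference.ploidy) ** 2
        ),
    )
    return solutions[best]


def classify_instability(
    n_mutations: int, n_cna: int, mut_thr: int = 300, cna_thr: int = 80
) -> str:
    """Low / M / C / MC by strict inequalities; boundary equality is Low."""
    high_mut = n_mutations > mut_thr
    high_cna = n_cna > cna_thr
    if high_mut and high_cna:
        return "MC"
    if high_mut and n_cna < cna_thr:
        return "M"
    if high_cna and n_mutations < mut_thr:
        return "C"
    if high_mut or high_cna:  # exactly on one boundary while high on the other
        return "Low"
    return "Low"


def sample_metrics_table(
    maf: pd.DataFrame,
    seg: pd.DataFrame,
    purity: Optional[pd.DataFrame] = None,
    mut_thr: int = 300,
    cna_thr: int = 80,
    gain_thr: float = 0.3,
    loss_thr: float = -0.3,
) -> pd.DataFrame:
    """Per-sample metrics from MAF-like and SEG tables.

    ``purity``, when given, is a table with columns ``sample_id``, ``purity``
    and optionally ``ploidy``.  Samples present in either input appear in the
    output; mean RMS is missing for samples without mutations.
    """
    samples = sorted(
        set(maf["Tumor_Sample_Barcode"].unique()) | set(seg["Sample"].unique())
    )
    maf_g = dict(tuple(maf.groupby("Tumor_Sample_Barcode")))
    seg_g = dict(tuple(seg.groupby("Sample")))
    pur = {}
    plo = {}
    if purity is not None:
        for _, row in purity.iterrows():
            pur[row["sample_id"]] = float(row["purity"])
            if "ploidy" in purity.columns and pd.notna(row.get("ploidy")):
                plo[row["sample_id"]] = float(row["ploidy"])
    rows = []
    for s in samples:
        m = maf_g.get(s, maf.iloc[0:0])
        g = seg_g.get(s, seg.iloc[0:0])
        n_mut = count_mutations(m)
        n_cna = count_cna_segments(g, gain_thr, loss_thr)
        rows.append(
            {
                "sample_id": s,
                "n_mutations": n_mut,
                "n_cna_segments": n_cna,
                "mean_rms": mean_rms(m),
                "purity": pur.get(s, np.nan),
                "ploidy": plo.get(s, np.nan),
                "instability_class": classify_instability(n_mut, n_cna, mut_thr, cna_thr),
            }
        )
    return pd.DataFrame(rows)


def clone_heatmap(
    samples: pd.DataFrame, n_bins: int = 20
) -> np.ndarray:
    """Mean clone count binned on normalized log-burden axes.

    ``samples`` needs columns ``n_mutations``, ``n_cna_segments`` and
    ``mean_n_clones``.  Axes are ``log(1 + count)`` normalized by the cohort
    maximum, split into ``n_bins`` equal-width bins on [0, 1]; entry [i, j]
    is the mean clone count of samples in mutation-bin i (rows) and CNA-bin j
    (columns); empty cells are NaN.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x = np.log1p(samples["n_cna_segments"].to_numpy(float))
    y = np.log1p(samples["n_mutations"].to_numpy(float))
    x = x / x.max() if x.max() > 0 else np.zeros_like(x)
    y = y / y.max() if y.max() > 0 else np.zeros_like(y)
    xi = np.minimum((x * n_bins).astype(int), n_bins - 1)
    yi = np.minimum((y * n_bins).astype(int), n_bins - 1)
    grid = np.full((n_bins, n_bins), np.nan)
    counts = np.zeros((n_bins, n_bins))
    sums = np.zeros((n_bins, n_bins))
    clones = samples["mean_n_clones"].to_numpy(float)
    np.add.at(counts, (yi, xi), 1)
    np.add.at(sums, (yi, xi), clones)
    occupied = counts > 0
    grid[occupied] = sums[occupied] / counts[occupied]
    return grid
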