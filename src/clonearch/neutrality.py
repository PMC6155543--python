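"""Neutral-evolution classification from the 1/f cumulative VAF fit.

Under neutral (selection-free) tumor growth, the cumulative number of
subclonal mutations with variant allele frequency at least ``f`` grows
linearly in ``1/f``: M(f) = c * (1/f - 1/f_max).  A sample whose cumulative
VAF curve, restricted to a window of subclonal frequencies (default
[0.12, 0.24]), fits this line with R^2 above 0.98 is classified as
exhibiting features of neutral evolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NeutralityResult",
    "compute_vafs",
    "cumulative_vaf_curve",
    "neutral_fit_r2",
    "classify_neutral",
    "neutrality_table",
]

DEFAULT_F_MIN = 0.12
DEFAULT_F_MAX = 0.24
DEFAULT_R2_THRESHOLD = 0.98
DEFAULT_MIN_MUTATIONS = 10


@dataclass(frozen=True)
class NeutralityResult:
    sample_id: str
    r_squared: Optional[float]
    n_mutations_in_range: int
    neutral: Optional[bool]


def compute_vafs(records: pd.DataFrame) -> np.ndarray:
    """Variant allele frequencies alt/(alt+ref); zero-depth sites dropped."""
    alt = records["t_alt_count"].to_numpy(float)
    ref = records["t_ref_count"].to_numpy(float)
    depth = alt + ref
    ok = depth > 0
    return alt[ok] / depth[ok]


def cumulative_vaf_curve(
    vafs: Sequence[float],
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Pairs (1/f, M(f)) at each observed VAF in the window, or None.

    M(f) counts window mutations with VAF >= f, so the curve is monotone
    non-increasing in f (non-decreasing in 1/f).  Returns None (missing) when
    fewer than ``min_mutations`` VAFs fall in the window or the curve has a
    single support point, which cannot constrain a line.
    """
    if not (0.0 < f_min < f_max <= 1.0):
        raise ValueError(f"need 0 < f_min < f_max <= 1, got [{f_min}, {f_max}]")
    v = np.asarray(vafs, dtype=float)
    v = v[(v >= f_min) & (v <= f_max)]
    if v.size < min_mutations:
        return None
    f = np.unique(v)  # ascending
    m = v.size - np.searchsorted(np.sort(v), f, side="left")  # = #{v >= f}
    if f.size < 2:
        return None
    return 1.0 / f, m.astype(float)


def neutral_fit_r2(
    vafs: Sequence[float],
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
    fit_intercept: bool = True,
) -> Optional[float]:
    """R^2 of the least-squares line M(f) ~ 1/f over the window, or None."""
    curve = cumulative_vaf_curve(vafs, f_min, f_max, min_mutations)
    if curve is None:
        return None
    x, y = curve
    if fit_intercept:
        res = stats.linregress(x, y)
        return float(res.rvalue**2)
    slope = float((x * y).sum() / (x * x).sum())
    resid = y - slope * x
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0
    return 1.0 - float((resid**2).sum()) / ss_tot


def classify_neutral(
    r_squared: Optional[float], threshold: float = DEFAULT_R2_THRESHOLD
) -> Optional[bool]:
    """Strictly greater than the threshold; missing stays missing."""
    if r_squared is None:
        return None
    return bool(r_squared > threshold)


def neutrality_table(
    maf: pd.DataFrame,
    f_min: float = DEFAULT_F_MIN,
    f_max: float = DEFAULT_F_MAX,
    threshold: float = DEFAULT_R2_THRESHOLD,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
) -> pd.DataFrame:
    """Per-sample neutrality calls from a MAF-like table."""
    rows = []
    for sample, grp in maf.groupby("Tumor_Sample_Barcode"):
        vafs = compute_vafs(grp)
        in_range = int(((vafs >= f_min) & (vafs <= f_max)).sum())
        r2 = neutral_fit_r2(vafs, f_min, f_max, min_mutations)
        rows.append(
            {
                "sample_id": sample,
                "r_squared": np.nan if r2 is None else r2,
                "n_in_range": in_range,
                "neutral": classify_neutral(r2, threshold),
            }
        )
    return pd.DataFrame(rows)
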