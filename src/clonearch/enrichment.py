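"""Association of binary features with clonal / subclonal mutation burdens.

Features are binary sample annotations: presence of a mutational signature
(any positive deconvolution score counts as presence) or of a recurrent
cancer alteration.  For every feature and tumor type, carriers are compared
with non-carriers by a one-tailed two-sample Wilcoxon rank-sum
(Mann-Whitney) test, once against clonal and once against subclonal
mutation counts, asking whether carriers have *more* of each.  P-values are
summarized as scores = -log10(p); the false discovery rate is controlled
per tumor type (Benjamini-Hochberg); and each feature x type pair is
classed C (clonal only), S (subclonal only), CS (both) or none at a
kind-specific score cut: 2.5 for signatures, 3.0 for alterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "binarize_scores",
    "wilcoxon_one_tailed",
    "bh_fdr",
    "enrichment_scan",
    "SIGNATURE_SCORE_THRESHOLD",
    "ALTERATION_SCORE_THRESHOLD",
]

SIGNATURE_SCORE_THRESHOLD = 2.5
ALTERATION_SCORE_THRESHOLD = 3.0
EXACT_MAX_N = 8  # exact rank-sum enumeration up to this group size, tie-free


@dataclass(frozen=True)
class EnrichmentResult:
    feature_id: str
    tumor_type: str
    p_clonal: float
    p_subclonal: float
    score_clonal: float
    score_subclonal: float
    q_clonal: float
    q_subclonal: float
    enrichment_class: str  # C | S | CS | none


def binarize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Binary presence matrix: entry 1 iff the score is strictly positive.

    Scores must be nonnegative (they are fractions of explained mutations).
    Features with no carriers are kept but will be skipped downstream.
    """
    arr = scores.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("signature/alteration scores must be >= 0")
    binary = (scores > 0).astype(np.int8)
    empty = binary.columns[(binary.sum(axis=0) == 0)]
    if len(empty):
        logger.warning("features with no carriers (untestable): %s", list(empty))
    return binary


def wilcoxon_one_tailed(
    carriers: Sequence[float], noncarriers: Sequence[float]
) -> float:
    """One-sided rank-sum p-value for carriers stochastically greater.

    Exact null enumeration when the smaller group has at most 8 observations
    and the pooled values are tie-free; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(carriers, dtype=float)
    y = np.asarray(noncarriers, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted values (step-up, monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _classify(score_clonal: float, score_subclonal: float, cut: float) -> str:
    hi_c = score_clonal > cut
    hi_s = score_subclonal > cut
    if hi_c and hi_s:
        return "CS"
    if hi_c:
        return "C"
    if hi_s:
        return "S"
    return "none"


def enrichment_scan(
    counts: pd.DataFrame,
    features: pd.DataFrame,
    feature_kind: str = "signature",
    signature_score_threshold: float = SIGNATURE_SCORE_THRESHOLD,
    alteration_score_threshold: float = ALTERATION_SCORE_THRESHOLD,
    min_carriers: int = 3,
) -> pd.DataFrame:
    """Per (feature, tumor type) one-tailed enrichment scan.

    ``counts`` needs columns ``sample_id``, ``tumor_type``, ``clonal``,
    ``subclonal``; ``features`` is a binary samples x features frame indexed
    by sample id.  Each tumor type is tested separately and BH-FDR is
    applied within type, separately for the clonal and subclonal test
    families.  Feature x type pairs with fewer than ``min_carriers``
    carriers, or without any non-carrier, are skipped with a logged reason.
    """
    if feature_kind not in ("signature", "alteration"):
        raise ValueError("feature_kind must be 'signature' or 'alteration'")
    cut = (
        signature_score_threshold
        if feature_kind == "signature"
        else alteration_score_threshold
    )
    if not set(counts["sample_id"]).issuperset(features.index):
        missing = set(features.index) - set(counts["sample_id"])
        raise ValueError(f"feature matrix has samples without counts: {sorted(missing)[:5]}")

    rows: list[dict] = []
    for ttype, grp in counts.groupby("tumor_type"):
        grp = grp.set_index("sample_id")
        feat = features.loc[features.index.intersection(grp.index)]
        tested: list[tuple[str, float, float]] = []
        for fid in feat.columns:
            mask = feat[fid].astype(bool)
            carriers = grp.loc[feat.index[mask]]
            noncar = grp.loc[feat.index[~mask]]
            if len(carriers) < min_carriers or len(noncar) == 0:
                logger.info(
                    "skipping %s in %s: %d carriers / %d non-carriers",
                    fid, ttype, len(carriers), len(noncar),
                )
                continue
            p_c = wilcoxon_one_tailed(carriers["clonal"], noncar["clonal"])
            p_s = wilcoxon_one_tailed(carriers["subclonal"], noncar["subclonal"])
            tested.append((fid, p_c, p_s))
        if not tested:
            continue
        q_c = bh_fdr([t[1] for t in tested])
        q_s = bh_fdr([t[2] for t in tested])
        for (fid, p_c, p_s), qc, qs in zip(tested, q_c, q_s):
            sc = float(-np.log10(p_c)) if p_c > 0 else np.inf
            ss = float(-np.log10(p_s)) if p_s > 0 else np.inf
            rows.append(
                {
                    "feature_id": fid,
                    "tumor_type": ttype,
                    "p_clonal": p_c,
                    "p_subclonal": p_s,
                    "score_clonal": sc,
                    "score_subclonal": ss,
                    "q_clonal": float(qc),
                    "q_subclonal": float(qs),
                    "enrichment_class": _classify(sc, ss, cut),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "tumor_type", "p_clonal", "p_subclonal",
            "score_clonal", "score_subclonal", "q_clonal", "q_subclonal",
            "enrichment_class",
        ],
    )
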