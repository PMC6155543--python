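"""End-to-end pipeline driver: consensus -> metrics -> neutrality -> enrichment.

``run_pipeline`` chains the stages over the interchange files, writes the
cohort-level output tables (a per-sample summary table, an enrichment
table, a neutrality table) plus a run manifest recording the seed, package
version and every effective threshold.  Fully deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as cio
from .enrichment import enrichment_scan
from .metrics import sample_metrics_table
from .neutrality import neutrality_table
from .trees import consensus_summary

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "accuracy_flag"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Thresholds default to the analysis constants: top candidate fraction
    0.1, clone prevalence floor 0.01, instability cuts 300 mutations / 80
    segments, CNA log-ratio cut 0.3, neutrality R-squared 0.98 over the VAF
    window [0.12, 0.24], and enrichment score cuts 2.5 (signatures) / 3.0
    (alterations).
    """

    trees: str
    maf: str
    seg: str
    outdir: str
    features: Optional[str] = None
    feature_kind: str = "signature"
    tumor_types: Optional[str] = None  # TSV sample_id, tumor_type
    purity: Optional[str] = None  # TSV sample_id, purity[, ploidy]
    top_fraction: float = 0.1
    prevalence_threshold: float = 0.01
    mut_class_threshold: int = 300
    cna_class_threshold: int = 80
    cna_value_cut: float = 0.3
    neutrality_r2: float = 0.98
    vaf_window: tuple[float, float] = (0.12, 0.24)
    signature_score_threshold: float = 2.5
    alteration_score_threshold: float = 3.0
    min_carriers: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = cio.read_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "vaf_window" in data:
            data["vaf_window"] = tuple(data["vaf_window"])
        return cls(**data)

    def validate(self) -> None:
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if not (0.0 < self.prevalence_threshold < 1.0):
            raise ValueError("prevalence_threshold must be in (0, 1)")
        lo, hi = self.vaf_window
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError("vaf_window must satisfy 0 < lo < hi <= 1")
        if not (0.0 < self.neutrality_r2 < 1.0):
            raise ValueError("neutrality_r2 must be in (0, 1)")


def _check_exists(path: Optional[str], label: str) -> None:
    if path is not None and not Path(path).exists():
        raise FileNotFoundError(f"{label} input not found: {path}")


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the cohort report under ``config.outdir``."""
    config.validate()
    for label in ("trees", "maf", "seg", "features", "tumor_types", "purity"):
        _check_exists(getattr(config, label), label)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tree_sets = cio.read_tree_json(config.trees)
    summaries = [consensus_summary(ts, config.top_fraction) for ts in tree_sets]
    consensus = cio.write_consensus(summaries, outdir / "consensus.tsv")

    maf = cio.read_maf(config.maf)
    seg = cio.read_seg(config.seg)
    purity = pd.read_csv(config.purity, sep="\t") if config.purity else None
    metrics = sample_metrics_table(
        maf,
        seg,
        purity=purity,
        mut_thr=config.mut_class_threshold,
        cna_thr=config.cna_class_threshold,
        gain_thr=config.cna_value_cut,
        loss_thr=-config.cna_value_cut,
    )
    sample_table = metrics.merge(consensus, on="sample_id", how="left")
    sample_table.to_csv(outdir / "sample_table.tsv", sep="\t", index=False)

    neutral = neutrality_table(
        maf,
        f_min=config.vaf_window[0],
        f_max=config.vaf_window[1],
        threshold=config.neutrality_r2,
    )
    neutral.to_csv(outdir / "neutrality.tsv", sep="\t", index=False)

    outputs = {
        "consensus": consensus,
        "sample_table": sample_table,
        "neutrality": neutral,
    }

    if config.features is not None:
        features = cio.read_feature_matrix(config.features)
        if config.tumor_types is not None:
            tt = pd.read_csv(config.tumor_types, sep="\t")
        else:
            logger.warning("no tumor-type table given; testing as one cohort")
            tt = pd.DataFrame(
                {"sample_id": consensus["sample_id"], "tumor_type": "ALL"}
            )
        counts = consensus.rename(
            columns={"mean_clonal": "clonal", "mean_subclonal": "subclonal"}
        )[["sample_id", "clonal", "subclonal"]].merge(tt, on="sample_id")
        enrich = enrichment_scan(
            counts,
            features,
            feature_kind=config.feature_kind,
            signature_score_threshold=config.signature_score_threshold,
            alteration_score_threshold=config.alteration_score_threshold,
            min_carriers=config.min_carriers,
        )
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        outputs["enrichment"] = enrich

    from . import __version__

    manifest = {
        "package": "clonearch",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "top_fraction": config.top_fraction,
            "prevalence_threshold": config.prevalence_threshold,
            "mut_class_threshold": config.mut_class_threshold,
            "cna_class_threshold": config.cna_class_threshold,
            "cna_value_cut": config.cna_value_cut,
            "neutrality_r2": config.neutrality_r2,
            "vaf_window": list(config.vaf_window),
            "signature_score_threshold": config.signature_score_threshold,
            "alteration_score_threshold": config.alteration_score_threshold,
            "min_carriers": config.min_carriers,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    logger.info("pipeline complete; thresholds: %s", manifest["thresholds"])
    return outputs


def accuracy_flag(
    mean_rms: float,
    mutations_per_clone: float,
    n_clones: int,
    curves: Optional[dict[int, list[tuple[float, float]]]] = None,
) -> str:
    """Reconstruction-accuracy flag from a user-supplied threshold curve.

    ``curves`` maps a clone number to a piecewise-linear threshold — a list
    of (mutations_per_clone, minimum mean RMS) breakpoints.  Samples above
    the interpolated curve are "ok"; below it the clone number is likely
    overestimated.  Without a configured curve the flag is always "ok" (the
    published threshold lines are figure-derived and not distributed here);
    a notice is logged.
    """
    if not curves:
        logger.info("no accuracy threshold curves configured; returning 'ok'")
        return "ok"
    key = min(curves, key=lambda k: abs(k - n_clones))
    pts = sorted(curves[key])
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    if mutations_per_clone <= xs[0]:
        need = ys[0]
    elif mutations_per_clone >= xs[-1]:
        need = ys[-1]
    else:
        import bisect

        j = bisect.bisect_right(xs, mutations_per_clone)
        t = (mutations_per_clone - xs[j - 1]) / (xs[j] - xs[j - 1])
        need = ys[j - 1] + t * (ys[j] - ys[j - 1])
    return "ok" if mean_rms >= need else "possibly_overestimated"
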