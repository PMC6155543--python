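"""Strict readers and writers for the interchange formats.

Formats handled here:

* tree JSON — one document per sample:
  ``{"sample_id": ..., "candidates": [{"cdll": ..., "nodes": [{"clone_id",
  "parent_id" | null, "n_mutations", "cell_fraction" | null}]}]}``;
  a file may hold a single document or a list of them;
* MAF-like mutation tables — tab-delimited, 1-based coordinates, with at
  least Tumor_Sample_Barcode, Chromosome, Start_Position, Reference_Allele,
  Tumor_Seq_Allele2, t_ref_count, t_alt_count;
* SEG copy-number segmentations — Sample, Chromosome, Start, End,
  Num_Probes (optional), Segment_Mean; 1-based inclusive coordinates;
* feature matrices — TSV, samples as rows, features as columns, entries
  binary or nonnegative scores.

Readers validate the type invariants and report the offending row; writers
round-trip integer fields bit-exactly and reals to 6 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .trees import CandidateTree, CandidateTreeSet, ClonalPhylogeny, CloneNode

__all__ = [
    "read_tree_json",
    "write_tree_json",
    "read_maf",
    "write_maf",
    "read_seg",
    "write_seg",
    "read_feature_matrix",
    "write_feature_matrix",
    "write_consensus",
    "read_config",
    "write_config",
]

MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "t_ref_count",
    "t_alt_count",
]
SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Segment_Mean"]


class FormatError(ValueError):
    """Malformed interchange file; the message names file and position."""


# ---------------------------------------------------------------------------
# Tree JSON
# ---------------------------------------------------------------------------

def _phylogeny_from_doc(nodes: list[dict], where: str) -> ClonalPhylogeny:
    try:
        return ClonalPhylogeny(
            CloneNode(
                clone_id=int(n["clone_id"]),
                parent_id=None if n.get("parent_id") is None else int(n["parent_id"]),
                n_mutations=int(n["n_mutations"]),
                cell_fraction=(
                    None if n.get("cell_fraction") is None else float(n["cell_fraction"])
                ),
            )
            for n in nodes
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{where}: invalid tree nodes: {exc}") from exc


def read_tree_json(path: str | Path) -> list[CandidateTreeSet]:
    """Read one or many per-sample candidate-tree documents."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    docs = data if isinstance(data, list) else [data]
    out = []
    for d, doc in enumerate(docs):
        where = f"{path.name}[{d}]"
        if "sample_id" not in doc or "candidates" not in doc:
            raise FormatError(f"{where}: needs 'sample_id' and 'candidates'")
        cands = []
        for c, cand in enumerate(doc["candidates"]):
            if "cdll" not in cand or "nodes" not in cand:
                raise FormatError(
                    f"{where}.candidates[{c}]: needs 'cdll' and 'nodes'"
                )
            phylo = _phylogeny_from_doc(cand["nodes"], f"{where}.candidates[{c}]")
            try:
                cands.append(CandidateTree(phylo, float(cand["cdll"])))
            except ValueError as exc:
                raise FormatError(f"{where}.candidates[{c}]: {exc}") from exc
        if not cands:
            raise FormatError(f"{where}: empty candidate list")
        out.append(CandidateTreeSet(str(doc["sample_id"]), cands))
    return out


def write_tree_json(tree_sets: Iterable[CandidateTreeSet], path: str | Path) -> None:
    docs = []
    for ts in tree_sets:
        docs.append(
            {
                "sample_id": ts.sample_id,
                "candidates": [
                    {
                        "cdll": round(float(c.cdll), 6),
                        "nodes": [
                            {
                                "clone_id": n.clone_id,
                                "parent_id": n.parent_id,
                                "n_mutations": n.n_mutations,
                                "cell_fraction": (
                                    None
                                    if n.cell_fraction is None
                                    else float(f"{n.cell_fraction:.6g}")
                                ),
                            }
                            for _, n in sorted(c.phylogeny.nodes.items())
                        ],
                    }
                    for c in ts.candidates
                ],
            }
        )
    payload = docs if len(docs) != 1 else docs[0]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# MAF / SEG / feature tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")


def read_maf(path: str | Path) -> pd.DataFrame:
    """Tab-delimited MAF-like mutation table with per-row validation."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str}, comment="#")
    _require_columns(df, MAF_COLUMNS, path)
    for col in ("Start_Position", "t_ref_count", "t_alt_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < (1 if col == "Start_Position" else 0))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path.name} row {row + 2}: invalid {col} value {df[col].iloc[row]!r}"
            )
        df[col] = vals.astype(np.int64)
    return df


def write_maf(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> pd.DataFrame:
    """Standard SEG segmentation table, 1-based inclusive coordinates."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str}, comment="#")
    _require_columns(df, SEG_COLUMNS, path)
    for col in ("Start", "End"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise FormatError(f"{path.name} row {row + 2}: non-numeric {col}")
        df[col] = vals.astype(np.int64)
    bad = df["Start"] > df["End"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path.name} row {row + 2}: Start > End "
            f"({df['Start'].iloc[row]} > {df['End'].iloc[row]})"
        )
    df["Segment_Mean"] = pd.to_numeric(df["Segment_Mean"], errors="raise")
    return df


def write_seg(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["Segment_Mean"] = out["Segment_Mean"].map(lambda v: float(f"{v:.6g}"))
    out.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path, binary: bool = True) -> pd.DataFrame:
    """Samples x features TSV; entries validated binary (or nonnegative)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path.name}: duplicate sample or feature labels")
    arr = df.to_numpy(dtype=float)
    if binary:
        if not np.isin(arr, (0.0, 1.0)).all():
            raise FormatError(f"{path.name}: entries must be 0/1")
        return df.astype(np.int8)
    if (arr < 0).any():
        raise FormatError(f"{path.name}: scores must be >= 0")
    return df


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_consensus(summaries: Iterable, path: str | Path) -> pd.DataFrame:
    """Write consensus summaries as a per-sample TSV and return the frame."""
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "mean_n_clones": round(s.mean_n_clones, 6),
                "mean_tree_score": round(s.mean_tree_score, 6),
                "mean_clonal": round(s.mean_clonal, 6),
                "mean_subclonal": round(s.mean_subclonal, 6),
                "n_candidates_used": s.n_candidates_used,
            }
            for s in summaries
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{Path(path).name}: config must be a mapping")
    return data


def write_config(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
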