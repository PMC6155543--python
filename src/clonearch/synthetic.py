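"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the interchange data a subclonal-reconstruction
workflow produces, with the statistical structure the downstream analysis
assumes, so the whole pipeline can run and be validated without external
data:

* true clone trees with cell fractions (stick-broken, every clone above the
  detection floor), built by sequential attachment — each new clone joins
  the root with probability ``branching_tendency`` and otherwise extends the
  most recently added clone, so 0 gives a chain and 1 a star;
* read-level mutation tables: each mutation's expected VAF is
  purity x CCF / 2 (diploid convention), read counts are binomial at a
  Poisson depth, and observed VAFs under the 1% floor are dropped,
  emulating the detection limit of exome sequencing;
* candidate-tree sets: the true tree plus perturbed copies (subtree
  regrafts, clone merges and splits), each with a pseudo log-likelihood
  that penalizes perturbation distance plus Gumbel noise, so the true
  topology is top-ranked in expectation;
* per-sample mutation/CNA burdens drawn to realize a configured mix of the
  Low/M/C/MC instability classes (with margin to the 300/80 boundaries so
  detection-floor losses cannot flip a class);
* binary feature matrices with planted multiplicative shifts of carriers'
  clonal or subclonal burdens, and null features without effect.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trees import (
    CandidateTree,
    CandidateTreeSet,
    ClonalPhylogeny,
    CloneNode,
    clonal_subclonal_counts,
    tree_score,
)

__all__ = [
    "PlantedFeature",
    "CohortConfig",
    "CohortBundle",
    "generate_true_tree",
    "generate_mutation_table",
    "generate_candidates",
    "generate_burdens",
    "generate_segments",
    "plant_feature_effects",
    "generate_cohort",
]

_BASES = np.array(["A", "C", "G", "T"])

# burden sampling regions per instability class: (mut_lo, mut_hi, cna_lo, cna_hi)
# kept well clear of the 300 / 80 classification boundaries so that mutations
# lost to the VAF detection floor cannot move a sample across a class line
_CLASS_REGIONS = {
    "Low": (30, 250, 0, 60),
    "M": (450, 2000, 0, 60),
    "C": (30, 250, 110, 400),
    "MC": (450, 2000, 110, 400),
}


@dataclass(frozen=True)
class PlantedFeature:
    """A feature whose carriers get a multiplicative burden shift."""

    feature_id: str
    target: str  # "clonal" | "subclonal"
    effect_size: float  # 1.0 = no shift

    def __post_init__(self) -> None:
        if self.target not in ("clonal", "subclonal"):
            raise ValueError("target must be 'clonal' or 'subclonal'")
        if not np.isfinite(self.effect_size) or self.effect_size < 0:
            raise ValueError("effect_size must be finite and >= 0")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 200
    tumor_type_labels: tuple[str, ...] = ("TT1", "TT2", "TT3", "TT4")
    clones_min: int = 1
    clones_max: int = 8
    branching_tendency: float = 0.5
    clonal_fraction_range: tuple[float, float] = (0.3, 0.6)
    mean_depth: float = 100.0  # reads per mutated site
    purity_alpha: float = 10.0  # purity ~ Beta(alpha, beta)
    purity_beta: float = 3.0
    vaf_floor: float = 0.01
    min_clone_fraction: float = 0.08  # keeps every clone above the floor
    n_candidates_per_sample: int = 50
    candidate_noise: float = 1.0  # mean perturbation moves per candidate
    cdll_gap: float = 5.0  # log-likelihood penalty per move
    planted_features: tuple[PlantedFeature, ...] = ()
    n_null_features: int = 5
    feature_prevalence: float = 0.3
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"Low": 0.4, "M": 0.2, "C": 0.2, "MC": 0.2}
    )
    # optional additive clone-count shift per instability class, e.g.
    # {"MC": 3, "M": 1, "C": 1} plants more clones in doubly unstable samples
    class_clone_gradient: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clones_min < 1 or self.clones_max < self.clones_min:
            raise ValueError("need 1 <= clones_min <= clones_max")
        if not (0.0 <= self.branching_tendency <= 1.0):
            raise ValueError("branching_tendency must be in [0, 1]")
        if not (0.0 < self.vaf_floor < 1.0):
            raise ValueError("vaf_floor must be in (0, 1)")
        bad = set(self.class_mix) - set(_CLASS_REGIONS)
        if bad:
            raise ValueError(f"unknown instability classes in class_mix: {bad}")
        tot = sum(self.class_mix.values())
        if not np.isclose(tot, 1.0):
            raise ValueError(f"class_mix proportions must sum to 1, got {tot}")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def generate_true_tree(
    n_clones: int,
    branching_tendency: float,
    rng: np.random.Generator,
    mutations: Optional[Sequence[int]] = None,
    min_clone_fraction: float = 0.08,
) -> ClonalPhylogeny:
    """Sequential-attachment clone tree with consistent cell fractions.

    Clone ``i`` (i >= 1) attaches to the root with probability
    ``branching_tendency`` and otherwise to clone ``i - 1``; 0 therefore
    yields a chain and 1 a star.  Per-clone cell fractions are Dirichlet
    stick-breaks floored at ``min_clone_fraction`` and renormalized, so they
    sum to 1 and every subtree fraction is consistent.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if mutations is None:
        mutations = [1] * n_clones
    parents: list[Optional[int]] = [None]
    for i in range(1, n_clones):
        if rng.random() < branching_tendency:
            parents.append(0)
        else:
            parents.append(i - 1)
    w = rng.dirichlet(np.full(n_clones, 1.5))
    floor = min(min_clone_fraction, 1.0 / n_clones)
    w = w * (1.0 - n_clones * floor) + floor  # min weight >= floor, sum == 1
    return ClonalPhylogeny(
        CloneNode(i, parents[i], int(mutations[i]), float(w[i]))
        for i in range(n_clones)
    )


def _subtree_fractions(tree: ClonalPhylogeny) -> dict[int, float]:
    """Cancer cell fraction of each clone = its subtree's cell-fraction sum."""
    ccf: dict[int, float] = {}

    def rec(u: int) -> float:
        total = tree.node(u).cell_fraction or 0.0
        for c in tree.children(u):
            total += rec(c)
        ccf[u] = min(1.0, total)
        return total

    rec(tree.root_id)
    return ccf


# ---------------------------------------------------------------------------
# Mutation tables
# ---------------------------------------------------------------------------

def generate_mutation_table(
    tree: ClonalPhylogeny,
    sample_id: str,
    purity: float,
    rng: np.random.Generator,
    mean_depth: float = 100.0,
    vaf_floor: float = 0.01,
) -> pd.DataFrame:
    """MAF-like records for every mutation on the tree, with read counts.

    Expected VAF of a clone's mutations is purity x CCF / 2 (diploid, no
    copy-number awareness); alt counts are binomial at Poisson depths and
    records whose observed VAF falls below ``vaf_floor`` are dropped.
    """
    ccf = _subtree_fractions(tree)
    frames = []
    for cid, node in sorted(tree.nodes.items()):
        n = node.n_mutations
        if n == 0:
            continue
        depth = np.maximum(rng.poisson(mean_depth, size=n), 1)
        p = min(1.0, max(0.0, purity * ccf[cid] / 2.0))
        alt = rng.binomial(depth, p)
        keep = alt / depth >= vaf_floor
        n_keep = int(keep.sum())
        if n_keep == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "Tumor_Sample_Barcode": sample_id,
                    "Chromosome": rng.integers(1, 23, size=n_keep).astype(str),
                    "Start_Position": rng.integers(1, 250_000_000, size=n_keep),
                    "Reference_Allele": rng.choice(_BASES, size=n_keep),
                    "Tumor_Seq_Allele2": rng.choice(_BASES, size=n_keep),
                    "t_ref_count": (depth - alt)[keep],
                    "t_alt_count": alt[keep],
                    "clone_id": cid,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "Tumor_Sample_Barcode", "Chromosome", "Start_Position",
                "Reference_Allele", "Tumor_Seq_Allele2",
                "t_ref_count", "t_alt_count", "clone_id",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Candidate trees
# ---------------------------------------------------------------------------

def _perturb(tree: ClonalPhylogeny, n_moves: int, rng: np.random.Generator) -> ClonalPhylogeny:
    """Apply ``n_moves`` random edits: subtree regraft, merge, or split."""
    parents = {i: n.parent_id for i, n in tree.nodes.items()}
    muts = {i: n.n_mutations for i, n in tree.nodes.items()}
    next_id = max(parents) + 1

    def descendants(u: int) -> set[int]:
        out = {u}
        frontier = [u]
        while frontier:
            v = frontier.pop()
            for w, p in parents.items():
                if p == v and w not in out:
                    out.add(w)
                    frontier.append(w)
        return out

    root = next(i for i, p in parents.items() if p is None)
    for _ in range(n_moves):
        moves = []
        non_root = [i for i in parents if i != root]
        if non_root:
            moves.extend(["regraft", "merge"])
        if any(m >= 2 for m in muts.values()):
            moves.append("split")
        if not moves:
            break
        move = moves[rng.integers(len(moves))]
        if move == "regraft":
            u = non_root[rng.integers(len(non_root))]
            forbidden = descendants(u)
            targets = [i for i in parents if i not in forbidden]
            parents[u] = targets[rng.integers(len(targets))]
        elif move == "merge":
            u = non_root[rng.integers(len(non_root))]
            p = parents[u]
            muts[p] += muts.pop(u)
            for w in list(parents):
                if parents.get(w) == u:
                    parents[w] = p
            del parents[u]
            non_root = [i for i in parents if i != root]
        else:  # split
            candidates = [i for i, m in muts.items() if m >= 2]
            u = candidates[rng.integers(len(candidates))]
            half = muts[u] // 2
            muts[u] -= half
            parents[next_id] = u
            muts[next_id] = half
            next_id += 1
    return ClonalPhylogeny(
        CloneNode(i, parents[i], muts[i], None) for i in parents
    )


def generate_candidates(
    true_tree: ClonalPhylogeny,
    n_candidates: int,
    candidate_noise: float,
    cdll_gap: float,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> CandidateTreeSet:
    """The candidate-tree harvest: perturbed copies of the truth, scored.

    Each candidate applies Poisson(``candidate_noise``) random edits; its
    pseudo complete-data log-likelihood is ``-(edits) * cdll_gap`` plus
    standard Gumbel noise, so unperturbed copies rank highest in
    expectation while occasional rank inversions exercise the weighting.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    cands = []
    for _ in range(n_candidates):
        n_moves = int(rng.poisson(candidate_noise)) if candidate_noise > 0 else 0
        phylo = _perturb(true_tree, n_moves, rng) if n_moves else true_tree
        cdll = -n_moves * cdll_gap + rng.gumbel(0.0, 1.0)
        cands.append(CandidateTree(phylo, float(cdll)))
    return CandidateTreeSet(sample_id, cands)


# ---------------------------------------------------------------------------
# Burdens, segments, features
# ---------------------------------------------------------------------------

def generate_burdens(
    class_mix: dict[str, float], n_samples: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-sample instability class with mutation / CNA-segment targets.

    Classes are assigned multinomially at the configured proportions and the
    burden targets are drawn uniformly inside each class region, away from
    the 300 / 80 boundaries.
    """
    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    labels = rng.choice(len(classes), size=n_samples, p=probs / probs.sum())
    rows = []
    for lab in labels:
        cls = classes[int(lab)]
        mut_lo, mut_hi, cna_lo, cna_hi = _CLASS_REGIONS[cls]
        rows.append(
            {
                "instability_class": cls,
                "n_mutations_target": int(rng.integers(mut_lo, mut_hi + 1)),
                "n_cna_target": int(rng.integers(cna_lo, cna_hi + 1)),
            }
        )
    return pd.DataFrame(rows)


def generate_segments(
    sample_id: str,
    n_altered: int,
    rng: np.random.Generator,
    n_neutral_mean: float = 30.0,
) -> pd.DataFrame:
    """SEG records: ``n_altered`` segments with |log-ratio| > 0.3 plus a
    Poisson number of copy-neutral segments inside (-0.3, 0.3)."""
    n_neutral = int(rng.poisson(n_neutral_mean))
    n = n_altered + n_neutral
    values = np.concatenate(
        [
            rng.uniform(0.35, 1.5, size=n_altered)
            * rng.choice([-1.0, 1.0], size=n_altered),
            rng.uniform(-0.25, 0.25, size=n_neutral),
        ]
    )
    start = rng.integers(1, 200_000_000, size=n)
    length = rng.integers(10_000, 10_000_000, size=n)
    return pd.DataFrame(
        {
            "Sample": sample_id,
            "Chromosome": rng.integers(1, 23, size=n).astype(str),
            "Start": start,
            "End": start + length,
            "Num_Probes": rng.integers(10, 5000, size=n),
            "Segment_Mean": np.round(values, 6),
        }
    )


def plant_feature_effects(
    counts: pd.DataFrame,
    planted: Sequence[PlantedFeature],
    rng: np.random.Generator,
    n_null_features: int = 5,
    prevalence: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binary feature matrix plus burden table with planted shifts applied.

    Carriers are Bernoulli(``prevalence``) per feature.  For each planted
    feature, carriers' target counts are re-drawn as
    Poisson(effect_size x original count); null features leave counts
    untouched.  Returns ``(features, shifted_counts)``; the input frame is
    not modified.
    """
    counts = counts.copy()
    samples = counts["sample_id"].to_numpy()
    feat_ids = [p.feature_id for p in planted] + [
        f"null_{i + 1}" for i in range(n_null_features)
    ]
    mat = rng.random((len(samples), len(feat_ids))) < prevalence
    features = pd.DataFrame(
        mat.astype(np.int8), index=pd.Index(samples, name="sample_id"),
        columns=feat_ids,
    )
    for p in planted:
        carriers = features[p.feature_id].to_numpy(bool)
        base = counts.loc[carriers, p.target].to_numpy(float)
        counts.loc[carriers, p.target] = rng.poisson(
            np.maximum(base, 1.0) * p.effect_size
        )
    return features, counts


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """All interchange tables of one synthetic cohort plus ground truth."""

    config: CohortConfig
    truth: pd.DataFrame
    true_trees: dict[str, ClonalPhylogeny]
    candidates: list[CandidateTreeSet]
    maf: pd.DataFrame
    seg: pd.DataFrame
    features: pd.DataFrame
    purity: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        from . import io as cio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_tree_json(self.candidates, outdir / "candidates.json")
        cio.write_maf(self.maf.drop(columns=["clone_id"]), outdir / "mutations.maf.tsv")
        cio.write_seg(self.seg, outdir / "segments.seg.tsv")
        cio.write_feature_matrix(self.features, outdir / "features.tsv")
        self.purity.to_csv(outdir / "purity.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        cio.write_config(dataclasses.asdict(self.config), outdir / "config.yaml")


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full cohort bundle, deterministic per ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    ttypes = [config.tumor_type_labels[i % len(config.tumor_type_labels)] for i in range(n)]

    burdens = generate_burdens(config.class_mix, n, rng)

    # feature carriers are drawn first so planted effects can shape the
    # per-sample burden targets before trees and reads are generated
    feat_ids = [p.feature_id for p in config.planted_features] + [
        f"null_{i + 1}" for i in range(config.n_null_features)
    ]
    carrier_mat = rng.random((n, len(feat_ids))) < config.feature_prevalence
    features = pd.DataFrame(
        carrier_mat.astype(np.int8),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=feat_ids,
    )

    truth_rows = []
    true_trees: dict[str, ClonalPhylogeny] = {}
    cand_sets: list[CandidateTreeSet] = []
    maf_frames: list[pd.DataFrame] = []
    seg_frames: list[pd.DataFrame] = []
    purities = []

    lo, hi = config.clonal_fraction_range
    for i, sid in enumerate(sample_ids):
        total_mut = int(burdens.loc[i, "n_mutations_target"])
        clonal = int(round(rng.uniform(lo, hi) * total_mut))
        subclonal = total_mut - clonal
        for p in config.planted_features:
            if not carrier_mat[i, feat_ids.index(p.feature_id)]:
                continue
            if p.target == "clonal":
                clonal = int(rng.poisson(max(clonal, 1) * p.effect_size))
            else:
                subclonal = int(rng.poisson(max(subclonal, 1) * p.effect_size))

        n_clones = int(rng.integers(config.clones_min, config.clones_max + 1))
        if config.class_clone_gradient:
            n_clones += int(
                config.class_clone_gradient.get(
                    str(burdens.loc[i, "instability_class"]), 0
                )
            )
            n_clones = max(1, n_clones)
        if n_clones == 1:
            clone_muts = [clonal + subclonal]
        else:
            shares = rng.dirichlet(np.full(n_clones - 1, 1.0))
            sub_alloc = rng.multinomial(subclonal, shares)
            clone_muts = [clonal] + list(sub_alloc)
        tree = generate_true_tree(
            n_clones,
            config.branching_tendency,
            rng,
            mutations=clone_muts,
            min_clone_fraction=config.min_clone_fraction,
        )
        true_trees[sid] = tree

        purity = float(rng.beta(config.purity_alpha, config.purity_beta))
        purities.append({"sample_id": sid, "purity": purity, "ploidy": 2.0})

        maf_frames.append(
            generate_mutation_table(
                tree, sid, purity, rng,
                mean_depth=config.mean_depth, vaf_floor=config.vaf_floor,
            )
        )
        seg_frames.append(
            generate_segments(sid, int(burdens.loc[i, "n_cna_target"]), rng)
        )
        cand_sets.append(
            generate_candidates(
                tree,
                config.n_candidates_per_sample,
                config.candidate_noise,
                config.cdll_gap,
                rng,
                sample_id=sid,
            )
        )

        true_clonal, true_subclonal = clonal_subclonal_counts(tree)
        truth_rows.append(
            {
                "sample_id": sid,
                "tumor_type": ttypes[i],
                "instability_class": burdens.loc[i, "instability_class"],
                "n_clones": n_clones,
                "tree_score": tree_score(tree),
                "clonal": true_clonal,
                "subclonal": true_subclonal,
                "n_mutations_target": total_mut,
                "n_cna_target": int(burdens.loc[i, "n_cna_target"]),
                "purity": purity,
            }
        )

    return CohortBundle(
        config=config,
        truth=pd.DataFrame(truth_rows),
        true_trees=true_trees,
        candidates=cand_sets,
        maf=pd.concat(maf_frames, ignore_index=True),
        seg=pd.concat(seg_frames, ignore_index=True),
        features=features,
        purity=pd.DataFrame(purities),
    )
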