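"""Two-stage screen for radiation-responsive m6A biomarker transcripts.

Stage I: transcripts differentially methylated at one or more timepoints
after a high-dose exposure are categorized as Hyper (only hyper calls),
Hypo (only hypo calls) or Inconsistent (both, removed from further
analysis); within a category, soft clustering of the standardized temporal
log2-fold-change profiles separates a consistently responding sub-category
from a transient one.  Stage II: single-timepoint hyper sets from an
independent lower-dose exposure.  The candidate biomarkers are the
intersection of the stage-I consistent sub-category with every stage-II set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import FuzzyCMeans

__all__ = [
    "ClusterResult",
    "CandidateSet",
    "assign_category",
    "categorize_genes",
    "build_temporal_table",
    "cluster_time_profiles",
    "select_consistent",
    "intersect_candidates",
    "two_stage_screen",
]

CATEGORIES = ("Hyper", "Hypo", "Inconsistent", "None")


@dataclass
class ClusterResult:
    """Soft clustering of temporal profiles.

    membership: gene x cluster weights (rows sum to 1); labels: argmax hard
    assignment (ties to the lowest cluster index); centroids: cluster centers
    in the standardized profile space.
    """

    membership: pd.DataFrame
    labels: pd.Series
    centroids: np.ndarray
    n_clusters: int
    seed: int

    def __post_init__(self) -> None:
        sums = self.membership.to_numpy().sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        if self.centroids.shape[0] != self.n_clusters:
            raise ValueError("centroid count must equal n_clusters")


@dataclass
class CandidateSet:
    """A gene set with the names of the sets it was intersected from."""

    genes: frozenset[str]
    provenance: tuple[str, ...] = field(default_factory=tuple)


def assign_category(statuses: Sequence[str]) -> str:
    """Temporal category from per-timepoint differential statuses.

    Hyper iff at least one hyper call and no hypo call; Hypo symmetric;
    Inconsistent iff both kinds appear; None iff neither.
    """
    statuses = list(statuses)
    if not statuses:
        raise ValueError("empty status vector")
    bad = set(statuses) - {"hyper", "hypo", "ns"}
    if bad:
        raise ValueError(f"unknown statuses: {sorted(bad)}")
    has_hyper = "hyper" in statuses
    has_hypo = "hypo" in statuses
    if has_hyper and has_hypo:
        return "Inconsistent"
    if has_hyper:
        return "Hyper"
    if has_hypo:
        return "Hypo"
    return "None"


def build_temporal_table(diff_by_tpi: Mapping[float, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-timepoint differential calls into temporal matrices.

    Returns ``(log2fc, status)``: gene x timepoint DataFrames with columns in
    strictly increasing timepoint order.
    """
    if not diff_by_tpi:
        raise ValueError("no differential tables supplied")
    tps = sorted(diff_by_tpi)
    fc = pd.DataFrame(
        {t: diff_by_tpi[t].set_index("gene_id")["log2_fc"] for t in tps}
    )
    status = pd.DataFrame(
        {t: diff_by_tpi[t].set_index("gene_id")["status"] for t in tps}
    )
    if fc.isna().any().any():
        raise ValueError("gene sets differ across timepoints")
    return fc, status


def categorize_genes(status: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`assign_category` over a gene x timepoint status table."""
    arr = status.to_numpy()
    has_hyper = (arr == "hyper").any(axis=1)
    has_hypo = (arr == "hypo").any(axis=1)
    cat = np.where(
        has_hyper & has_hypo,
        "Inconsistent",
        np.where(has_hyper, "Hyper", np.where(has_hypo, "Hypo", "None")),
    )
    return pd.Series(cat, index=status.index, name="category")


def _standardize_rows(profiles: pd.DataFrame) -> np.ndarray:
    X = profiles.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant profile(s) standardized to the zero vector",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mu) / sd
    Z[flat, :] = 0.0
    return Z


def cluster_time_profiles(
    profiles: pd.DataFrame,
    n_clusters: int = 2,
    fuzzifier: float = 2.0,
    seed: int = 0,
) -> ClusterResult:
    """Fuzzy c-means on per-gene z-standardized temporal log2FC profiles.

    ``profiles`` is a gene x timepoint DataFrame.  Standardization removes
    per-gene amplitude so clusters separate profile *shapes*; constant
    profiles become the zero vector (with a warning).  Deterministic for a
    fixed ``seed``.
    """
    if profiles.shape[1] < 2:
        raise ValueError("clustering needs at least 2 timepoints")
    if profiles.shape[0] < n_clusters:
        raise ValueError("fewer genes than clusters")
    Z = _standardize_rows(profiles)
    fcm = FuzzyCMeans(n_clusters=n_clusters, m=fuzzifier, random_state=seed).fit(Z)
    membership = pd.DataFrame(
        fcm.membership_, index=profiles.index, columns=[f"cluster_{j}" for j in range(n_clusters)]
    )
    labels = pd.Series(fcm.labels_, index=profiles.index, name="cluster")
    return ClusterResult(
        membership=membership,
        labels=labels,
        centroids=fcm.cluster_centers_,
        n_clusters=n_clusters,
        seed=seed,
    )


def select_consistent(
    profiles: pd.DataFrame, cluster_result: ClusterResult, category: str
) -> frozenset[str]:
    """Genes of the sub-cluster whose mean raw profile keeps the category sign.

    ``profiles`` are the *unstandardized* log2 fold changes (standardization
    destroys sign, so consistency is judged on the raw cluster-mean profile):
    for Hyper the qualifying cluster's mean log2FC must be > 0 at every
    timepoint, for Hypo < 0.  Genes hard-assigned to qualifying clusters are
    returned; if no cluster qualifies the set is empty.
    """
    if category not in ("Hyper", "Hypo"):
        raise ValueError("category must be 'Hyper' or 'Hypo'")
    if not profiles.index.equals(cluster_result.labels.index):
        raise ValueError("cluster result does not match the profile table")
    selected: set[str] = set()
    for j in range(cluster_result.n_clusters):
        members = cluster_result.labels.index[cluster_result.labels.to_numpy() == j]
        if len(members) == 0:
            continue
        mean_profile = profiles.loc[members].mean(axis=0).to_numpy()
        ok = np.all(mean_profile > 0) if category == "Hyper" else np.all(mean_profile < 0)
        if ok:
            selected.update(members)
    return frozenset(selected)


def intersect_candidates(
    sets: Mapping[str, frozenset[str] | set[str]], require_all: bool = True
) -> CandidateSet:
    """Exact intersection of named gene sets, provenance recorded.

    With ``require_all=False`` genes present in at least two sets are kept
    instead of the full intersection.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    names = tuple(sets)
    if require_all:
        genes = frozenset.intersection(*(frozenset(s) for s in sets.values()))
    else:
        counts: dict[str, int] = {}
        for s in sets.values():
            for g in s:
                counts[g] = counts.get(g, 0) + 1
        genes = frozenset(g for g, c in counts.items() if c >= 2)
    return CandidateSet(genes=genes, provenance=names)


def two_stage_screen(
    stage1_diff: Mapping[float, pd.DataFrame],
    stage2_diff: Mapping[float, pd.DataFrame],
    n_clusters: int = 2,
    fuzzifier: float = 2.0,
    seed: int = 0,
) -> dict:
    """Run the full two-stage biomarker screen.

    Stage I: temporal categorization of the multi-timepoint differential
    calls, fuzzy sub-clustering of the Hyper category, selection of the
    consistently hyper-methylated sub-cluster.  Stage II: the hyper set at
    each supplied timepoint.  Candidates: intersection of all stages.

    Returns a dict with keys ``category`` (per-gene Series), ``cluster``
    (ClusterResult or None), ``consistent_hyper`` (frozenset), ``stage2_sets``
    (name -> frozenset), and ``candidates`` (CandidateSet).
    """
    fc, status = build_temporal_table(stage1_diff)
    category = categorize_genes(status)
    hyper_genes = category.index[category == "Hyper"]

    cluster = None
    if len(hyper_genes) >= n_clusters:
        hyper_fc = fc.loc[hyper_genes]
        cluster = cluster_time_profiles(hyper_fc, n_clusters=n_clusters, fuzzifier=fuzzifier, seed=seed)
        consistent = select_consistent(hyper_fc, cluster, "Hyper")
    else:
        # too few genes to sub-cluster: every Hyper gene whose profile stays
        # positive at all timepoints counts as consistent
        consistent = frozenset(
            g for g in hyper_genes if (fc.loc[g].to_numpy() > 0).all()
        )

    stage2_sets = {
        f"hyper_stageII_t{t:g}": frozenset(
            df.loc[df["status"] == "hyper", "gene_id"]
        )
        for t, df in sorted(stage2_diff.items())
    }
    all_sets = {"consistent_hyper_stageI": consistent, **stage2_sets}
    candidates = intersect_candidates(all_sets) if len(all_sets) >= 2 else CandidateSet(
        genes=consistent, provenance=("consistent_hyper_stageI",)
    )
    return {
        "category": category,
        "cluster": cluster,
        "consistent_hyper": consistent,
        "stage2_sets": stage2_sets,
        "candidates": candidates,
    }
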