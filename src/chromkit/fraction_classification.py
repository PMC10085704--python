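"""Fraction-profile classification: z-scoring, clustering, high confidence.

The six-fraction workflow: proteins with significant quantity differences
across fractions (permutation-FDR ANOVA) are z-scored on their
fraction-group means and partitioned by k-means; clusters whose centroid
peaks only in the chromatin wash fractions are labelled
"chromatome-enriched" and their union forms the profile-based
high-confidence chromatome. A direct per-condition chromatome-vs-proteome
t-test provides the alternative high-confidence definition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import AgglomerativeClustering, KMeans

from .differential_stats import DifferentialResult, TestConfig, multi_sample_anova
from .preprocessing import ImputationConfig, filter_min_valid, impute_gaussian_downshift
from .io_tables import (
    CHROMATOME_FRACTIONS,
    SIX_FRACTIONS,
    IntensityMatrix,
    SampleDesign,
    TableError,
)

logger = logging.getLogger(__name__)

CHROMATOME_ENRICHED = "chromatome-enriched"


@dataclass
class ClusterAssignment:
    """Cluster membership, z-scored profiles and per-cluster metadata."""

    assignments: pd.Series  # protein -> cluster id (1-based)
    z_profiles: pd.DataFrame  # protein x profile columns
    centroids: pd.DataFrame  # cluster id x profile columns
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def members(self, cluster: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster])

    def proteins_with_label(self, label: str) -> frozenset[str]:
        ids: set[str] = set()
        for cluster, lab in self.labels.items():
            if lab == label:
                ids |= set(self.members(cluster))
        return frozenset(ids)

    @property
    def chromatome_enriched_proteins(self) -> frozenset[str]:
        return self.proteins_with_label(CHROMATOME_ENRICHED)

    @classmethod
    def empty(cls, columns) -> "ClusterAssignment":
        return cls(
            assignments=pd.Series(dtype=int),
            z_profiles=pd.DataFrame(columns=list(columns)),
            centroids=pd.DataFrame(columns=list(columns)),
            labels={},
        )


@dataclass
class HighConfidenceSet:
    """Proteins passing the chromatome-over-proteome enrichment test."""

    proteins: frozenset[str]
    table: pd.DataFrame
    p_threshold: float
    min_fc: float

    def __contains__(self, protein: str) -> bool:
        return protein in self.proteins

    def __len__(self) -> int:
        return len(self.proteins)


def zscore_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0 / sd 1 (sample sd).

    Constant rows cannot be scaled and are mapped to all-zero vectors
    (logged as a warning).
    """
    if frame.shape[1] < 2:
        raise TableError("zscore_rows needs >= 2 columns")
    mean = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=1)
    constant = (sd == 0) | sd.isna()
    if constant.any():
        logger.warning("%d constant rows mapped to all-zero z-scores",
                       int(constant.sum()))
    safe_sd = sd.mask(constant, 1.0)
    z = frame.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return z


def cluster_profiles(
    z_matrix: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_restarts: int = 100,
    method: str = "kmeans",
) -> ClusterAssignment:
    """Partition z-scored profiles into ``k`` clusters.

    ``method="kmeans"`` (default) runs k-means with k-means++ starts and
    ``n_restarts`` restarts, keeping the lowest within-cluster sum of
    squares; ``"agglomerative"`` offers plain average-linkage clustering.
    Cluster ids are renumbered by hierarchically ordering the centroids
    (average linkage) so equivalent partitions present identically.
    """
    n = len(z_matrix)
    if k < 1:
        raise TableError("k must be >= 1")
    if k > n:
        raise TableError(f"k={k} exceeds number of proteins ({n})")
    X = z_matrix.to_numpy()
    if method == "kmeans":
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                    random_state=seed)
        raw = km.fit_predict(X)
        centroids = km.cluster_centers_
    elif method == "agglomerative":
        if k == 1:
            raw = np.zeros(n, dtype=int)
        else:
            agg = AgglomerativeClustering(n_clusters=k, linkage="average")
            raw = agg.fit_predict(X)
        centroids = np.stack([X[raw == c].mean(axis=0) for c in range(k)])
    else:
        raise TableError(f"unknown clustering method {method!r}")

    if k > 1:
        order = leaves_list(linkage(centroids, method="average"))
    else:
        order = np.array([0])
    renumber = {int(old): new + 1 for new, old in enumerate(order)}
    assignments = pd.Series(
        [renumber[int(c)] for c in raw], index=z_matrix.index, name="cluster"
    )
    centroid_frame = pd.DataFrame(
        centroids[order], index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=z_matrix.columns,
    )
    return ClusterAssignment(assignments, z_matrix.copy(), centroid_frame)


def _label_centroid(centroid: pd.Series) -> str:
    """Heuristic localization label from a fraction-profile centroid.

    "chromatome-enriched" requires the centroid maxima to lie only in the
    chromatin wash fractions with both nuclei and cytoplasm coordinates
    below the centroid mean.
    """
    peak = centroid.max()
    maxima = set(centroid.index[centroid >= peak - 1e-9])
    center = centroid.mean()
    chrom = set(CHROMATOME_FRACTIONS) & set(centroid.index)
    if (
        maxima
        and maxima <= chrom
        and centroid.get("nuclei", np.inf) < center
        and centroid.get("cytoplasm", np.inf) < center
    ):
        return CHROMATOME_ENRICHED
    top = centroid.idxmax()
    if top == "nuclei":
        return "nucleoplasmic"
    if top in ("cytoplasm", "whole_cell"):
        return "cytoplasmic"
    return "other"


def label_fraction_clusters(assignment: ClusterAssignment) -> ClusterAssignment:
    """Attach localization labels; invariant to cluster index permutation."""
    assignment.labels = {
        int(cluster): _label_centroid(assignment.centroids.loc[cluster])
        for cluster in assignment.centroids.index
    }
    return assignment


def classify_fractions(
    matrix: IntensityMatrix,
    design: SampleDesign,
    anova_config: TestConfig | None = None,
    k: int = 9,
    min_fc: float = 1.5,
    seed: int = 0,
    n_restarts: int = 100,
    cluster_method: str = "kmeans",
    min_valid: int = 2,
    imputation: ImputationConfig | None = None,
) -> tuple[DifferentialResult, ClusterAssignment]:
    """Full six-fraction pipeline: filtering, imputation, ANOVA, z-scoring,
    clustering and labelling.

    Missing values are handled the way the testing convention expects:
    proteins with fewer than ``min_valid`` observed values in every group
    are dropped, the rest is imputed by Gaussian downshift before the
    ANOVA (pass ``min_valid=0`` to skip both steps). Returns the ANOVA
    result and the labelled clustering of significant proteins;
    ``assignment.chromatome_enriched_proteins`` is the profile-based
    high-confidence chromatome. With no significant proteins the
    clustering is empty (not an error).
    """
    anova_config = anova_config or TestConfig(seed=seed)
    present = set(design.subset(
        [s for s in matrix.sample_ids if s in design.table.index]
    ).table["fraction"])
    missing = [f for f in SIX_FRACTIONS if f not in present]
    if missing:
        raise TableError(f"design lacks fractions: {missing}")

    if min_valid > 0:
        matrix = filter_min_valid(matrix, design, min_valid=min_valid,
                                  scope="any_group")
        if matrix.values.isna().any().any():
            matrix = impute_gaussian_downshift(
                matrix, imputation or ImputationConfig(seed=seed)
            )
    anova = multi_sample_anova(matrix, design, groups=list(SIX_FRACTIONS),
                               config=anova_config, min_fc=min_fc)
    significant = anova.significant_proteins
    if not significant:
        return anova, ClusterAssignment.empty(SIX_FRACTIONS)

    mean_cols = {f: anova.table.loc[significant, f"mean_{f}"] for f in SIX_FRACTIONS}
    profile = pd.DataFrame(mean_cols)
    z = zscore_rows(profile)
    k_eff = min(k, len(z))
    if k_eff < k:
        logger.warning("reducing k from %d to %d (only %d significant proteins)",
                       k, k_eff, len(z))
    assignment = cluster_profiles(z, k_eff, seed=seed, n_restarts=n_restarts,
                                  method=cluster_method)
    return anova, label_fraction_clusters(assignment)


def define_high_confidence(
    chromatome: IntensityMatrix,
    proteome: IntensityMatrix,
    design: SampleDesign,
    condition: str | None = None,
    p_threshold: float = 0.05,
    min_fc: float = 1.5,
) -> HighConfidenceSet:
    """Chromatome-over-proteome enrichment test (one condition, one layer).

    A plain two-sample Student t-test per protein; membership requires raw
    ``p < p_threshold`` and a chromatome-minus-proteome mean difference of
    at least ``log2(min_fc)`` (direction: enriched at chromatin).
    """
    shared = chromatome.values.index.intersection(proteome.values.index)
    if shared.empty:
        raise TableError("no shared proteins between layers")
    chrom_cols = [s for s in design.samples(condition=condition)
                  if s in chromatome.values.columns]
    prot_cols = [s for s in design.samples(condition=condition)
                 if s in proteome.values.columns]
    if not chrom_cols or not prot_cols:
        raise TableError(
            f"condition {condition!r} not present in both layers"
        )
    A = chromatome.values.loc[shared, chrom_cols].to_numpy()
    B = proteome.values.loc[shared, prot_cols].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sp_stats.ttest_ind(A, B, axis=1, nan_policy="omit")
    diff = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    n_a = (~np.isnan(A)).sum(axis=1)
    n_b = (~np.isnan(B)).sum(axis=1)
    p[(n_a < 2) | (n_b < 2)] = np.nan
    member = (p < p_threshold) & (diff >= np.log2(min_fc)) & np.isfinite(p)
    table = pd.DataFrame(
        {"difference": diff, "p": p, "member": member}, index=shared
    )
    return HighConfidenceSet(
        proteins=frozenset(table.index[table["member"]]),
        table=table,
        p_threshold=p_threshold,
        min_fc=min_fc,
    )
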