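"""Relative chromatin binding, fold-change ranking, row normalization
and cross-layer Pearson correlation.

Relative chromatin binding (RCB) is the chromatome log2 intensity of a
protein minus its mean proteome log2 intensity over the replicates of the
same condition; positive values mean enriched at chromatin relative to
expression. RCB is kept per chromatome replicate so that downstream ANOVA
retains within-group variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .differential_stats import DifferentialResult, TestConfig, multi_sample_anova
from .fraction_classification import ClusterAssignment, HighConfidenceSet, \
    cluster_profiles, zscore_rows
from .io_tables import IntensityMatrix, SampleDesign, TableError

logger = logging.getLogger(__name__)


@dataclass
class RelativeBindingProfile:
    """Per-protein, per-chromatome-replicate RCB values.

    ``values`` keeps the chromatome sample columns; ``design`` is the
    matching sub-design. ``filled`` lists proteins whose proteome side was
    absent in at least one condition and was replaced by the configured
    fixed value.
    """

    values: pd.DataFrame
    design: SampleDesign
    filled: frozenset[str] = frozenset()

    @property
    def conditions(self) -> list[str]:
        return self.design.conditions

    def condition_means(self) -> pd.DataFrame:
        """Mean RCB per protein and condition."""
        cols = {}
        for cond in self.conditions:
            samples = [s for s in self.design.samples(condition=cond)
                       if s in self.values.columns]
            cols[cond] = self.values[samples].mean(axis=1)
        return pd.DataFrame(cols)


def relative_chromatin_binding(
    chromatome: IntensityMatrix,
    proteome: IntensityMatrix,
    design: SampleDesign,
    proteome_fill: float | None = 0.0,
) -> RelativeBindingProfile:
    """RCB(p, c, r) = chromatome(p, c, r) - mean_r' proteome(p, c, r').

    Proteins the proteome layer does not quantify in a condition get the
    fixed fallback ``proteome_fill`` as their RCB (``None`` leaves them
    missing); either way they are flagged in ``filled``.
    """
    chromatome.require_scale("log2")
    proteome.require_scale("log2")
    shared = chromatome.values.index.intersection(proteome.values.index)
    if shared.empty:
        raise TableError("no shared proteins between layers")

    chrom_cols_all, rows, out_cols = [], [], {}
    filled: set[str] = set()
    prot_aligned = proteome.values.reindex(chromatome.values.index)
    for cond in design.conditions:
        chrom_cols = [s for s in design.samples(condition=cond)
                      if s in chromatome.values.columns]
        prot_cols = [s for s in design.samples(condition=cond)
                     if s in proteome.values.columns]
        if not chrom_cols:
            continue
        if not prot_cols:
            raise TableError(f"condition {cond!r} has no proteome samples")
        prot_mean = prot_aligned[prot_cols].mean(axis=1)
        missing_prot = prot_mean.isna()
        filled |= set(prot_mean.index[missing_prot])
        for col in chrom_cols:
            rcb = chromatome.values[col] - prot_mean
            if proteome_fill is not None:
                rcb = rcb.mask(missing_prot, proteome_fill)
            out_cols[col] = rcb
            chrom_cols_all.append(col)
            row = design.table.loc[col]
            rows.append({"fraction": row["fraction"], "condition": cond,
                         "replicate": int(row["replicate"])})
    values = pd.DataFrame(out_cols, index=chromatome.values.index)
    sub_design = SampleDesign(
        pd.DataFrame(rows, index=pd.Index(chrom_cols_all, name="sample_id"))
    )
    return RelativeBindingProfile(values, sub_design, frozenset(filled))


def rcb_anova_cluster(
    profiles: RelativeBindingProfile,
    high_confidence: HighConfidenceSet | frozenset | set,
    config: TestConfig | None = None,
    min_fc: float = 2.0,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 100,
) -> tuple[DifferentialResult, ClusterAssignment]:
    """ANOVA of RCB across conditions on high-confidence binders, then
    z-scoring and clustering of the significant RCB profiles.

    Clusters are labelled by the condition where their centroid peaks
    (e.g. ``"formative-peak"``).
    """
    config = config or TestConfig(seed=seed)
    members = getattr(high_confidence, "proteins", high_confidence)
    keep = [p for p in profiles.values.index if p in members]
    if not keep:
        raise TableError("high-confidence set does not intersect the profiles")
    conditions = profiles.conditions
    if len(conditions) < 3:
        raise TableError(f"RCB ANOVA requires >= 3 conditions, got {len(conditions)}")

    matrix = IntensityMatrix(profiles.values.loc[keep].copy(), "log2")
    anova = multi_sample_anova(matrix, profiles.design, groups=conditions,
                               config=config, min_fc=min_fc)
    significant = anova.significant_proteins
    if not significant:
        return anova, ClusterAssignment.empty(conditions)

    means = pd.DataFrame(
        {c: anova.table.loc[significant, f"mean_{c}"] for c in conditions}
    )
    z = zscore_rows(means)
    k_eff = min(k, len(z))
    assignment = cluster_profiles(z, k_eff, seed=seed, n_restarts=n_restarts)
    assignment.labels = {
        int(c): f"{assignment.centroids.loc[c].idxmax()}-peak"
        for c in assignment.centroids.index
    }
    return anova, assignment


def rank_by_fold_change(diff: DifferentialResult) -> pd.DataFrame:
    """Rank proteins by log2 fold change, 1 = most enriched, ties averaged."""
    if "difference" not in diff.table.columns:
        raise TableError("result has no 'difference' column to rank")
    table = pd.DataFrame(index=diff.table.index)
    table["fold_change_log2"] = diff.table["difference"]
    table["rank"] = table["fold_change_log2"].rank(
        ascending=False, method="average"
    )
    table["significant"] = diff.table["significant"]
    return table.sort_values("rank")


def row_normalize(values: pd.DataFrame, mode: str = "subtract_row_mean") -> pd.DataFrame:
    """Center each row so it sums to zero."""
    if mode != "subtract_row_mean":
        raise TableError(f"unknown row normalization mode {mode!r}")
    if values.shape[1] < 2:
        raise TableError("row_normalize needs >= 2 columns")
    return values.sub(values.mean(axis=1), axis=0)


def pearson_correlate(
    layer_a: pd.Series,
    layer_b: pd.Series,
    subset: "pd.Index | list[str] | None" = None,
) -> tuple[float, int]:
    """Pearson r over pairwise-complete shared proteins.

    Only proteins quantified in both vectors (and, optionally, in the
    ``subset`` panel) contribute. Returns ``(r, n_pairs)``.
    """
    joined = pd.concat([layer_a, layer_b], axis=1, join="inner", keys=["a", "b"])
    if subset is not None:
        joined = joined.loc[joined.index.intersection(pd.Index(subset))]
    joined = joined.dropna()
    n = len(joined)
    if n < 3:
        raise TableError(f"need >= 3 pairwise-complete proteins, got {n}")
    r = float(sp_stats.pearsonr(joined["a"], joined["b"]).statistic)
    return r, n
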