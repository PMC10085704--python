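"""Affinity-purification MS: pulldown-vs-IgG enrichment and bait-normalized
complex stoichiometry.

"Identified" means a non-missing quantification in a replicate; the
filtering, imputation and moderated testing reuse the preprocessing and
differential modules so the pulldown analysis follows the same statistical
machinery as the fractionation experiments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential_stats import DifferentialResult, TestConfig, sam_ttest
from .io_tables import IntensityMatrix, SampleDesign, TableError
from .preprocessing import ImputationConfig, filter_min_valid, impute_gaussian_downshift

logger = logging.getLogger(__name__)


@dataclass
class StoichiometryTable:
    """Bait-normalized subunit stoichiometries per condition.

    ``table`` is long-format: one row per (subunit, condition) with the
    mean log2 ratio to the bait, its SD across replicates, the linear
    stoichiometry (``2**mean``) and the replicate count used. The bait's
    ratio is identically 0 (stoichiometry 1) in every condition.
    """

    table: pd.DataFrame
    bait: str

    def stoichiometry(self, subunit: str, condition: str) -> float:
        sub = self.table[(self.table["subunit"] == subunit)
                         & (self.table["condition"] == condition)]
        if sub.empty:
            raise KeyError((subunit, condition))
        return float(sub["stoichiometry"].iloc[0])


def chipms_differential(
    matrix: IntensityMatrix,
    design: SampleDesign,
    config: TestConfig | None = None,
    condition: str | None = None,
    min_identified: int = 2,
    filter_scope: str = "any_group",
    imputation: ImputationConfig | None = None,
) -> DifferentialResult:
    """Pulldown-vs-IgG differential enrichment.

    Proteins identified fewer than ``min_identified`` times in a triplicate
    set are removed, the remainder is imputed (Gaussian downshift) and
    tested with :func:`sam_ttest` (permutation FDR, default 5%). The
    ``enriched`` call requires significance *and* a log2 fold change of at
    least ``fc_threshold_log2`` toward the pulldown. Proteins never
    observed in the IgG control are flagged ``control_absent``.
    """
    config = config or TestConfig()
    pd_cols = [s for s in design.samples(fraction="pulldown", condition=condition)
               if s in matrix.values.columns]
    igg_cols = [s for s in design.samples(fraction="igg", condition=condition)
                if s in matrix.values.columns]
    if not igg_cols:
        raise TableError("design has no IgG control samples")
    if not pd_cols:
        raise TableError("design has no pulldown samples")

    sub = matrix.subset_samples(pd_cols + igg_cols)
    sub_design = design.subset(pd_cols + igg_cols)
    control_absent = sub.values[igg_cols].isna().all(axis=1)

    filtered = filter_min_valid(sub, sub_design, min_valid=min_identified,
                                scope=filter_scope)
    imputation = imputation or ImputationConfig(seed=config.seed)
    imputed = impute_gaussian_downshift(filtered, imputation)

    result = sam_ttest(imputed, sub_design, pd_cols, igg_cols, config)
    result.kind = "chipms"
    table = result.table
    table["enriched"] = (
        (table["q"] <= config.fdr)
        & (table["difference"] >= config.fc_threshold_log2)
        & table["q"].notna()
    )
    table["control_absent"] = control_absent.reindex(table.index).fillna(False)
    return result


def stoichiometry(
    ibaq_matrix: IntensityMatrix,
    design: SampleDesign,
    bait: str,
    members: "set[str] | list[str]",
    fraction: str = "pulldown",
) -> StoichiometryTable:
    """Bait-normalized stoichiometry from log2 iBAQ values.

    Per replicate, each member's log2 iBAQ minus the bait's; per condition,
    the mean and SD of these ratios over replicates (a geometric mean in
    linear space) and the linear stoichiometry ``2**mean``. Replicates
    where the bait is missing are dropped with a warning; a bait absent
    from every replicate is an error.
    """
    ibaq_matrix.require_scale("log2")
    if bait not in ibaq_matrix.values.index:
        raise TableError(f"bait {bait!r} not in matrix")
    members = list(dict.fromkeys([bait] + [m for m in members if m != bait]))
    absent = [m for m in members if m not in ibaq_matrix.values.index]
    if absent:
        raise TableError(f"members not in matrix: {absent}")

    records = []
    any_replicates = False
    for cond in design.conditions:
        cols = [s for s in design.samples(fraction=fraction, condition=cond)
                if s in ibaq_matrix.values.columns]
        if not cols:
            continue
        bait_vals = ibaq_matrix.values.loc[bait, cols]
        usable = [c for c in cols if np.isfinite(bait_vals[c])]
        dropped = sorted(set(cols) - set(usable))
        if dropped:
            logger.warning("bait %r missing in replicates %s; dropped", bait, dropped)
        if not usable:
            continue
        any_replicates = True
        for member in members:
            ratios = (
                ibaq_matrix.values.loc[member, usable] - bait_vals[usable]
            ).dropna()
            if ratios.empty:
                mean = sd = np.nan
                n = 0
            else:
                mean = float(ratios.mean())
                sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
                n = int(len(ratios))
            records.append(
                {
                    "subunit": member,
                    "condition": cond,
                    "mean_log2_ratio": mean,
                    "sd_log2": sd,
                    "stoichiometry": float(2.0 ** mean) if np.isfinite(mean)
                    else np.nan,
                    "n_replicates": n,
                }
            )
    if not any_replicates:
        raise TableError(f"bait {bait!r} quantified in no replicate")
    return StoichiometryTable(pd.DataFrame.from_records(records), bait=bait)
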