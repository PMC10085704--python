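"""Valid-value filtering, CV-based QC and Gaussian-downshift imputation."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import IntensityMatrix, SampleDesign, TableError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    """Gaussian-downshift imputation parameters.

    Missing cells of sample column *j* are drawn from
    ``Normal(mean_j - downshift * sd_j, (width * sd_j)^2)`` where
    ``mean_j``/``sd_j`` are computed over the observed values of that
    column. Defaults follow the common Perseus setting.
    """

    width: float = 0.2
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


@dataclass
class QCReport:
    """Per-protein group CVs, per-sample missingness and summary stats.

    CVs are percent (sd/mean * 100) on the linear intensity scale and are
    only reported for groups with at least ``min_valid`` observed values.
    """

    cv_percent: pd.DataFrame  # protein x group (columns "fraction|condition")
    n_valid: pd.DataFrame  # protein x group
    sample_missing_fraction: pd.Series
    median_cv: float
    n_below_20: int
    n_below_10: int
    min_valid: int

    @property
    def table(self) -> pd.DataFrame:
        out = self.cv_percent.add_prefix("cv_")
        return out.join(self.n_valid.add_prefix("n_valid_"))


def _group_columns(
    matrix: IntensityMatrix, design: SampleDesign
) -> dict[tuple[str, str], list[str]]:
    design.validate_matrix(matrix)
    in_matrix = set(matrix.sample_ids)
    groups = {
        key: [s for s in samples if s in in_matrix]
        for key, samples in design.groups().items()
    }
    return {key: cols for key, cols in groups.items() if cols}


def filter_min_valid(
    matrix: IntensityMatrix,
    design: SampleDesign,
    min_valid: int = 2,
    scope: str = "any_group",
) -> IntensityMatrix:
    """Drop proteins lacking ``min_valid`` observed values per group.

    ``scope="any_group"`` keeps a protein if at least one
    (fraction, condition) group passes the rule (the usual convention for
    two-group tests); ``"all_groups"`` requires every group to pass.
    """
    if scope not in ("any_group", "all_groups"):
        raise ValueError(f"scope must be 'any_group' or 'all_groups', got {scope!r}")
    groups = _group_columns(matrix, design)
    too_small = [key for key, cols in groups.items() if len(cols) < min_valid]
    if too_small:
        raise TableError(
            f"groups smaller than min_valid={min_valid}: {sorted(too_small)}"
        )
    passing = pd.DataFrame(
        {
            str(key): matrix.values[cols].notna().sum(axis=1) >= min_valid
            for key, cols in groups.items()
        }
    )
    keep = passing.any(axis=1) if scope == "any_group" else passing.all(axis=1)
    return matrix.subset_proteins(list(matrix.values.index[keep]))


def compute_cv(
    matrix: IntensityMatrix,
    design: SampleDesign,
    min_valid: int = 2,
) -> QCReport:
    """Coefficient of variation per protein and replicate group.

    The matrix is log2; CV% is computed on the back-transformed linear
    intensities (``2**x``), the conventional scale for this statistic.
    Groups with fewer than ``min_valid`` observed values get a missing CV.
    """
    matrix.require_scale("log2")
    groups = _group_columns(matrix, design)
    cv_cols, n_cols = {}, {}
    for (fraction, condition), cols in groups.items():
        label = f"{fraction}|{condition}"
        linear = np.power(2.0, matrix.values[cols])
        n = linear.notna().sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = linear.mean(axis=1)
            sd = linear.std(axis=1, ddof=1)
        cv = sd / mean * 100.0
        cv[n < min_valid] = np.nan
        cv_cols[label] = cv
        n_cols[label] = n
    cv_percent = pd.DataFrame(cv_cols)
    n_valid = pd.DataFrame(n_cols)
    missing = matrix.values.isna().mean(axis=0)
    all_cvs = cv_percent.values[np.isfinite(cv_percent.values)]
    median_cv = float(np.median(all_cvs)) if all_cvs.size else float("nan")
    return QCReport(
        cv_percent=cv_percent,
        n_valid=n_valid,
        sample_missing_fraction=missing,
        median_cv=median_cv,
        n_below_20=int((all_cvs < 20.0).sum()),
        n_below_10=int((all_cvs < 10.0).sum()),
        min_valid=min_valid,
    )


def impute_gaussian_downshift(
    matrix: IntensityMatrix,
    config: ImputationConfig | None = None,
) -> IntensityMatrix:
    """Replace missing cells with down-shifted Gaussian draws, column-wise.

    Observed cells are never altered; every column needs at least two
    observed values to estimate its mean and sd. Seeded and reproducible.
    """
    config = config or ImputationConfig()
    matrix.require_scale("log2")
    rng = np.random.default_rng(config.seed)
    values = matrix.values.copy()
    for col in values.columns:
        observed = values[col].dropna()
        if len(observed) < 2:
            raise TableError(
                f"column {col!r} has {len(observed)} observed values; "
                "imputation needs at least 2"
            )
        n_missing = int(values[col].isna().sum())
        if n_missing == 0:
            continue
        mu = float(observed.mean())
        sd = float(observed.std(ddof=1))
        draws = rng.normal(mu - config.downshift * sd, config.width * sd, n_missing)
        values.loc[values[col].isna(), col] = draws
    return IntensityMatrix(values, matrix.scale_tag, matrix.gene_names)
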