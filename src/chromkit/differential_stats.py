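"""Moderated two-sample tests with permutation FDR, ANOVA and BH adjustment.

The two-sample statistic is ``d = (mean_a - mean_b) / (se + s0)`` with the
pooled-variance standard error and a non-negative moderation constant
``s0`` that penalizes small-variance proteins. The false-discovery rate is
estimated from group-label permutations: for each candidate cutoff on the
statistic, the estimated FDR is the median over permutations of the number
of permuted statistics exceeding the cutoff, divided by the number of
observed statistics exceeding it (capped at 1). A protein's q-value is the
smallest estimated FDR over cutoffs it attains, which is non-increasing in
the statistic by construction. Significance additionally requires a
minimal absolute log2 fold change.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import ClassVar, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import IntensityMatrix, SampleDesign, TableError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestConfig:
    """Configuration shared by the permutation-FDR tests."""

    __test__: "ClassVar[bool]" = False  # not a pytest class

    s0: float = 1.0
    n_permutations: int = 250
    fdr: float = 0.05
    sides: str = "two"
    fc_threshold_log2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.sides not in ("one", "two"):
            raise ValueError("sides must be 'one' or 'two'")
        if self.fc_threshold_log2 < 0:
            raise ValueError("fc_threshold_log2 must be >= 0")


@dataclass
class DifferentialResult:
    """Per-protein test output plus the configuration that produced it."""

    table: pd.DataFrame
    config: TestConfig
    kind: str = "two_sample"
    groups: tuple = ()

    @property
    def significant_proteins(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def volcano_frame(self) -> pd.DataFrame:
        """Volcano-ready export: difference, -log10 p, q, significance."""
        out = pd.DataFrame(index=self.table.index)
        out["difference"] = self.table["difference"]
        with np.errstate(divide="ignore"):
            out["minus_log10_p"] = -np.log10(self.table["p"])
        out["q"] = self.table["q"]
        out["significant"] = self.table["significant"]
        return out


# ---------------------------------------------------------------------------
# group resolution
# ---------------------------------------------------------------------------

def resolve_group(
    matrix: IntensityMatrix, design: SampleDesign, spec
) -> list[str]:
    """Resolve a group specifier to matrix columns.

    ``spec`` may be a list of sample ids, a ``(fraction, condition)``
    tuple, a fraction label, or a condition label.
    """
    in_matrix = set(matrix.sample_ids)
    fractions = set(design.table["fraction"])
    if isinstance(spec, str):
        if spec in fractions:
            cols = [s for s in design.samples(fraction=spec) if s in in_matrix]
        else:
            cols = [s for s in design.samples(condition=spec) if s in in_matrix]
    elif (
        isinstance(spec, tuple)
        and len(spec) == 2
        and all(isinstance(x, str) for x in spec)
        and spec[0] in fractions
    ):
        fraction, condition = spec
        cols = [s for s in design.samples(fraction=fraction, condition=condition)
                if s in in_matrix]
    else:
        cols = [s for s in spec if s in in_matrix]
        missing = sorted(set(spec) - in_matrix)
        if missing:
            raise TableError(f"group samples not in matrix: {missing}")
        return cols
    if not cols:
        raise TableError(f"group specifier {spec!r} matches no matrix samples")
    return cols


# ---------------------------------------------------------------------------
# statistic kernels (nan-aware, broadcast over an optional permutation axis)
# ---------------------------------------------------------------------------

def _mean_var(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = (~np.isnan(block)).sum(axis=-1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(block, axis=-1)
        var = np.nanvar(block, axis=-1, ddof=1)
    return n.astype(float), mean, var


def _moderated_stats(
    X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (difference, d, se, df); NaN where a side has < 2 valid values.

    ``idx_a``/``idx_b`` are column index arrays; 2-D index arrays of shape
    (n_perm, k) broadcast the computation over permutations.
    """
    na, ma, va = _mean_var(X[:, idx_a])
    nb, mb, vb = _mean_var(X[:, idx_b])
    with np.errstate(divide="ignore", invalid="ignore"):
        df = na + nb - 2.0
        sp2 = ((na - 1.0) * va + (nb - 1.0) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        diff = ma - mb
        d = diff / (se + s0)
    invalid = (na < 2) | (nb < 2)
    diff = np.where((na < 1) | (nb < 1), np.nan, diff)
    d = np.where(invalid, np.nan, d)
    se = np.where(invalid, np.nan, se)
    return diff, d, se, df


def _student_p(
    diff: np.ndarray, se: np.ndarray, df: np.ndarray, sides: str
) -> np.ndarray:
    """Plain (unmoderated) Student t-test p-value."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = np.full(diff.shape, np.nan)
    valid = np.isfinite(se) & np.isfinite(diff) & (df > 0)
    zero_zero = valid & (se == 0) & (diff == 0)
    inf_t = valid & (se == 0) & (diff != 0)
    ok = valid & (se > 0)
    if sides == "two":
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
        p[inf_t] = 0.0
    else:
        p[ok] = stats.t.sf(t[ok], df[ok])
        p[inf_t] = np.where(diff[inf_t] > 0, 0.0, 1.0)
    p[zero_zero] = 1.0
    return np.minimum(p, 1.0)


def _two_group_assignments(
    n_total: int, n_a: int, n_permutations: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Index sets assigned to group A: exhaustive if feasible, else random."""
    total = math.comb(n_total, n_a)
    if total < 2:
        raise TableError("fewer than 2 distinct label permutations")
    if total <= n_permutations:
        combos = np.array(list(itertools.combinations(range(n_total), n_a)))
        return combos, True
    keys = rng.random((n_permutations, n_total))
    combos = np.sort(np.argsort(keys, axis=1)[:, :n_a], axis=1)
    return combos, False


def _complement(idx: np.ndarray, n_total: int) -> np.ndarray:
    mask = np.ones((idx.shape[0], n_total), dtype=bool)
    rows = np.arange(idx.shape[0])[:, None]
    mask[rows, idx] = False
    return np.nonzero(mask)[1].reshape(idx.shape[0], n_total - idx.shape[1])


def _permutation_q(
    score_obs: np.ndarray, score_perm: np.ndarray
) -> np.ndarray:
    """Permutation-FDR q-values for a "larger is more significant" score.

    Cutoffs are the observed score values; ties share the q of the common
    cutoff. ``score_perm`` has shape (n_proteins, n_permutations).
    """
    n = score_obs.shape[0]
    q = np.full(n, np.nan)
    valid = np.isfinite(score_obs)
    if not valid.any():
        return q
    s = score_obs[valid]
    cutoffs = np.unique(s)  # ascending
    sorted_s = np.sort(s)
    obs_exceed = sorted_s.size - np.searchsorted(sorted_s, cutoffs, side="left")
    n_perm = score_perm.shape[1]
    counts = np.empty((n_perm, cutoffs.size))
    for j in range(n_perm):
        col = score_perm[:, j]
        col = np.sort(col[np.isfinite(col)])
        counts[j] = col.size - np.searchsorted(col, cutoffs, side="left")
    perm_exceed = np.median(counts, axis=0)
    fdr = np.minimum(perm_exceed / obs_exceed, 1.0)
    # q at cutoff c_j = min FDR over cutoffs <= c_j (rejection regions
    # containing the protein); running min keeps q non-increasing in score.
    q_at_cutoff = np.minimum.accumulate(fdr)
    q[valid] = q_at_cutoff[np.searchsorted(cutoffs, s)]
    return q


# ---------------------------------------------------------------------------
# public tests
# ---------------------------------------------------------------------------

def sam_ttest(
    matrix: IntensityMatrix,
    design: SampleDesign,
    group_a,
    group_b,
    config: TestConfig | None = None,
) -> DifferentialResult:
    """s0-moderated two-sample test with permutation-based FDR.

    The permutation null resamples group labels over the pooled columns
    (all distinct assignments when their number does not exceed
    ``n_permutations``, otherwise that many random ones, seeded).
    ``significant`` requires both ``q <= fdr`` and the fold-change
    threshold (``|difference| >= fc_threshold_log2``; for one-sided tests
    the difference must be positive in the tested direction).
    """
    config = config or TestConfig()
    matrix.require_scale("log2")
    cols_a = resolve_group(matrix, design, group_a)
    cols_b = resolve_group(matrix, design, group_b)
    overlap = set(cols_a) & set(cols_b)
    if overlap:
        raise TableError(f"groups overlap: {sorted(overlap)}")
    X = matrix.values[cols_a + cols_b].to_numpy()
    n_a, n_b = len(cols_a), len(cols_b)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)

    diff, d, se, df = _moderated_stats(X, idx_a, idx_b, config.s0)
    p = _student_p(diff, se, df, config.sides)

    rng = np.random.default_rng(config.seed)
    perm_a, _ = _two_group_assignments(n_a + n_b, n_a, config.n_permutations, rng)
    perm_b = _complement(perm_a, n_a + n_b)
    _, d_perm, _, _ = _moderated_stats(X, perm_a, perm_b, config.s0)

    if config.sides == "two":
        score_obs, score_perm = np.abs(d), np.abs(d_perm)
    else:
        score_obs, score_perm = d, d_perm
    q = _permutation_q(score_obs, score_perm)

    if config.sides == "two":
        fc_ok = np.abs(diff) >= config.fc_threshold_log2
    else:
        fc_ok = diff >= config.fc_threshold_log2
    significant = (q <= config.fdr) & fc_ok & np.isfinite(q)

    valid_a = matrix.values[cols_a].notna().sum(axis=1)
    valid_b = matrix.values[cols_b].notna().sum(axis=1)
    table = pd.DataFrame(
        {
            "mean_a": matrix.values[cols_a].mean(axis=1),
            "mean_b": matrix.values[cols_b].mean(axis=1),
            "n_a": valid_a,
            "n_b": valid_b,
            "difference": diff,
            "d": d,
            "p": p,
            "q": q,
            "significant": significant,
        },
        index=matrix.values.index,
    )
    return DifferentialResult(table, config, kind="two_sample",
                              groups=(tuple(cols_a), tuple(cols_b)))


def paired_normalized_ttest(
    chromatome: IntensityMatrix,
    proteome: IntensityMatrix,
    design: SampleDesign,
    condition_a: str,
    condition_b: str,
    config: TestConfig | None = None,
) -> DifferentialResult:
    """Test condition contrasts on chromatome-minus-proteome differences.

    For every condition, replicate *i* of the chromatome layer is matched
    to replicate *i* of the proteome layer and their per-protein log2
    difference forms a derived matrix; :func:`sam_ttest` then contrasts the
    two conditions on these normalized values.
    """
    config = config or TestConfig()
    shared = chromatome.values.index.intersection(proteome.values.index)
    if shared.empty:
        raise TableError("no shared proteins between layers")
    diff_cols: dict[str, pd.Series] = {}
    rows = []
    sample_ids = []
    for cond in (condition_a, condition_b):
        chrom_cols = [s for s in design.samples(condition=cond)
                      if s in chromatome.values.columns]
        prot_cols = [s for s in design.samples(condition=cond)
                     if s in proteome.values.columns]
        if len(chrom_cols) != len(prot_cols):
            raise TableError(
                f"condition {cond!r}: unequal replicate counts between layers "
                f"({len(chrom_cols)} chromatome vs {len(prot_cols)} proteome)"
            )
        if not chrom_cols:
            raise TableError(f"condition {cond!r} has no samples")
        chrom_by_rep = sorted(chrom_cols, key=lambda s: design.table.loc[s, "replicate"])
        prot_by_rep = sorted(prot_cols, key=lambda s: design.table.loc[s, "replicate"])
        for r, (c_col, p_col) in enumerate(zip(chrom_by_rep, prot_by_rep), start=1):
            sid = f"normdiff_{cond}_{r}"
            diff_cols[sid] = (
                chromatome.values.loc[shared, c_col]
                - proteome.values.loc[shared, p_col]
            )
            sample_ids.append(sid)
            rows.append({"fraction": "chromatome_w3", "condition": cond, "replicate": r})
    diff_matrix = IntensityMatrix(pd.DataFrame(diff_cols, index=shared), "log2")
    diff_design = SampleDesign(
        pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    )
    result = sam_ttest(diff_matrix, diff_design, condition_a, condition_b, config)
    result.kind = "paired_normalized"
    return result


def _anova_f(
    X: np.ndarray, idx_groups: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One-way ANOVA F over column groups; returns (F, dfb, dfw, group means)."""
    stats_per_group = [_mean_var(X[:, idx]) for idx in idx_groups]
    ns = np.stack([s[0] for s in stats_per_group])
    means = np.stack([s[1] for s in stats_per_group])
    vars_ = np.stack([s[2] for s in stats_per_group])
    G = len(idx_groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        N = ns.sum(axis=0)
        grand = np.nansum(ns * means, axis=0) / N
        ssb = np.nansum(ns * (means - grand) ** 2, axis=0)
        ssw = np.nansum((ns - 1.0) * vars_, axis=0)
        dfb = float(G - 1)
        dfw = N - G
        F = (ssb / dfb) / (ssw / dfw)
    invalid = (ns < 2).any(axis=0) | (dfw < 1)
    F = np.where(invalid, np.nan, F)
    # zero within-group variance: infinite F if between-group signal exists
    with np.errstate(invalid="ignore"):
        zero_w = ~invalid & (ssw == 0)
    F = np.where(zero_w & (ssb > 0), np.inf, F)
    F = np.where(zero_w & (ssb == 0), 0.0, F)
    return F, np.full_like(F, dfb), dfw, means


def _multiset_permutations(
    labels: np.ndarray, limit: int
) -> list[np.ndarray] | None:
    """All distinct permutations of a label multiset, or None if > limit."""
    counts: dict[int, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    total = math.factorial(len(labels))
    for c in counts.values():
        total //= math.factorial(c)
    if total > limit:
        return None
    out: list[np.ndarray] = []
    labels_sorted = sorted(counts)

    def recurse(prefix: list[int], remaining: dict[int, int]) -> None:
        if len(prefix) == len(labels):
            out.append(np.array(prefix))
            return
        for lab in labels_sorted:
            if remaining[lab] > 0:
                remaining[lab] -= 1
                prefix.append(lab)
                recurse(prefix, remaining)
                prefix.pop()
                remaining[lab] += 1

    recurse([], dict(counts))
    return out


def multi_sample_anova(
    matrix: IntensityMatrix,
    design: SampleDesign,
    groups: Sequence | None = None,
    config: TestConfig | None = None,
    min_fc: float = 1.5,
) -> DifferentialResult:
    """One-way ANOVA across >= 3 groups with permutation-based FDR.

    Group labels are shuffled across all pooled columns (all distinct
    labelings when feasible, otherwise ``n_permutations`` random shuffles)
    and the FDR estimator of :func:`sam_ttest` is applied with cutoffs on
    F. ``significant`` additionally requires the maximal absolute pairwise
    difference of group means to reach ``log2(min_fc)``.
    """
    config = config or TestConfig()
    matrix.require_scale("log2")
    if groups is None:
        design.validate_matrix(matrix)
        in_matrix = set(matrix.sample_ids)
        pairs = [
            (key, [s for s in samples if s in in_matrix])
            for key, samples in design.groups().items()
        ]
        pairs = [(key, cols) for key, cols in pairs if cols]
        labels = ["|".join(map(str, key)) for key, _ in pairs]
        group_cols = [cols for _, cols in pairs]
    else:
        group_cols = [resolve_group(matrix, design, g) for g in groups]
        labels = [str(g) for g in groups]
    if len(group_cols) < 3:
        raise TableError(f"ANOVA requires >= 3 groups, got {len(group_cols)}")
    seen: set[str] = set()
    for cols in group_cols:
        dup = seen & set(cols)
        if dup:
            raise TableError(f"groups overlap: {sorted(dup)}")
        seen |= set(cols)
    sizes = [len(cols) for cols in group_cols]
    small = [lab for lab, k in zip(labels, sizes) if k < 2]
    if small:
        raise TableError(f"groups with < 2 replicates: {small}")

    all_cols = [c for cols in group_cols for c in cols]
    X = matrix.values[all_cols].to_numpy()
    bounds = np.cumsum([0] + sizes)
    idx_groups = [np.arange(bounds[g], bounds[g + 1]) for g in range(len(sizes))]

    F, dfb, dfw, means = _anova_f(X, idx_groups)
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(F, dfb, dfw)
    p = np.where(np.isinf(F), 0.0, p)

    # permutation null: shuffle which columns belong to which group
    rng = np.random.default_rng(config.seed)
    label_vec = np.concatenate([
        np.full(k, g) for g, k in enumerate(sizes)
    ])
    enumerated = _multiset_permutations(label_vec, config.n_permutations)
    n_total = len(all_cols)
    if enumerated is not None:
        perm_groups = [
            np.stack([np.nonzero(lab == g)[0] for lab in enumerated])
            for g in range(len(sizes))
        ]
    else:
        keys = np.argsort(rng.random((config.n_permutations, n_total)), axis=1)
        perm_groups = [
            np.sort(keys[:, bounds[g]:bounds[g + 1]], axis=1)
            for g in range(len(sizes))
        ]
    F_perm, _, _, _ = _anova_f(X, perm_groups)
    q = _permutation_q(F, F_perm)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        max_diff = np.nanmax(means, axis=0) - np.nanmin(means, axis=0)
    fc_ok = max_diff >= np.log2(min_fc)
    significant = (q <= config.fdr) & fc_ok & np.isfinite(q)

    table = pd.DataFrame(index=matrix.values.index)
    for lab, m in zip(labels, means):
        table[f"mean_{lab}"] = m
    table["F"] = F
    table["p"] = p
    table["q"] = q
    table["max_abs_difference"] = max_diff
    table["significant"] = significant
    return DifferentialResult(table, config, kind="anova", groups=tuple(labels))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1).

    NaN entries propagate and are excluded from the adjustment.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return q
    order = np.argsort(pf, kind="mergesort")
    ranked = pf[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    q[finite] = out
    return q
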