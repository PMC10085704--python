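"""Fisher's exact annotation enrichment and strict-valid-value term counts.

Enrichment is always computed against the background of identified
proteins, with Benjamini-Hochberg correction across the tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .differential_stats import bh_adjust
from .io_tables import AnnotationSet, IntensityMatrix, SampleDesign, TableError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Per-term counts, effect sizes and (adjusted) p-values."""

    table: pd.DataFrame
    foreground_size: int
    background_size: int
    alternative: str

    def significant_terms(self, fdr: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["q"] <= fdr])


def map_identifiers(
    protein_ids: Iterable[str],
    gene_names: pd.Series | None,
    namespace: str,
) -> dict[str, str]:
    """Map protein-group ids into an annotation namespace.

    ``"protein_id"`` uses the id itself; ``"gene_name"`` takes the first
    gene symbol of the group (splitting multi-gene groups on ``;``),
    falling back to the protein id when no symbol is known. Matching is
    case-insensitive (everything upper-cased).
    """
    out: dict[str, str] = {}
    ambiguous = 0
    for pid in protein_ids:
        key = pid
        if namespace == "gene_name" and gene_names is not None:
            symbol = gene_names.get(pid)
            if isinstance(symbol, str) and symbol:
                parts = symbol.split(";")
                if len(parts) > 1:
                    ambiguous += 1
                key = parts[0].strip() or pid
        out[pid] = key.upper()
    if ambiguous:
        logger.info("%d multi-gene groups mapped via their first symbol", ambiguous)
    return out


def fisher_pvalue(
    k: int, K: int, n: int, N: int, alternative: str = "two-sided"
) -> float:
    """Exact p for a 2x2 membership table.

    ``k`` of ``n`` foreground proteins fall in a term of size ``K`` within
    a background of size ``N``.
    """
    table = np.array([[k, n - k], [K - k, N - n - (K - k)]])
    if (table < 0).any():
        raise TableError(f"inconsistent 2x2 counts: k={k}, K={K}, n={n}, N={N}")
    return float(sp_stats.fisher_exact(table, alternative=alternative)[1])


def fisher_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationSet,
    min_term_size: int = 3,
    alternative: str = "two-sided",
    gene_names: pd.Series | None = None,
) -> EnrichmentResult:
    """Per-term Fisher's exact test of foreground vs background membership.

    The 2x2 table for each term counts in/out of the term against in/out
    of the foreground, within the background universe. Terms with fewer
    than ``min_term_size`` background members are skipped. ``alternative``
    is ``"two-sided"`` (default) or ``"greater"`` for pure
    over-representation.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise TableError(f"unknown alternative {alternative!r}")
    fg_ids = list(dict.fromkeys(foreground))
    bg_ids = list(dict.fromkeys(background))
    if not fg_ids:
        raise TableError("empty foreground")
    outside = sorted(set(fg_ids) - set(bg_ids))
    if outside:
        raise TableError(f"foreground not a subset of background: {outside[:10]}")

    mapping = map_identifiers(bg_ids, gene_names, annotations.namespace)
    bg_keys = {mapping[p] for p in bg_ids}
    fg_keys = {mapping[p] for p in fg_ids}
    n_bg, n_fg = len(bg_keys), len(fg_keys)

    records = []
    for term, (name, members) in annotations.terms.items():
        in_bg = members & bg_keys
        K = len(in_bg)
        if K < min_term_size:
            continue
        k = len(in_bg & fg_keys)
        p = fisher_pvalue(k, K, n_fg, n_bg, alternative=alternative)
        a, b, c, dd = k, n_fg - k, K - k, n_bg - n_fg - (K - k)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * dd) / (b * c) if b * c > 0 else np.inf if a * dd > 0 else np.nan
        factor = (k / n_fg) / (K / n_bg)
        records.append(
            {
                "term": term,
                "name": name,
                "n_fg_term": k,
                "n_bg_term": K,
                "n_fg": n_fg,
                "n_bg": n_bg,
                "odds_ratio": odds,
                "enrichment_factor": factor,
                "p": p,
                "direction": "enriched" if factor > 1 else
                ("depleted" if factor < 1 else "none"),
            }
        )
    frame = pd.DataFrame.from_records(records).set_index("term") if records else \
        pd.DataFrame(columns=["name", "n_fg_term", "n_bg_term", "n_fg", "n_bg",
                              "odds_ratio", "enrichment_factor", "p",
                              "direction"]).rename_axis("term")
    if len(frame):
        frame["q"] = bh_adjust(frame["p"].to_numpy())
        frame = frame.sort_values("p")
    else:
        frame["q"] = pd.Series(dtype=float)
    return EnrichmentResult(frame, n_fg, n_bg, alternative)


def annotation_counts(
    matrix: IntensityMatrix,
    design: SampleDesign,
    annotations: AnnotationSet,
    fraction: str | None = None,
    condition: str | None = None,
    require_full_valid: int = 3,
) -> pd.Series:
    """Per-term counts of proteins fully observed in the selected group.

    The strict counting rule: a protein contributes only when it has a
    valid value in every replicate of the group (e.g. 3 of 3).
    """
    cols = [s for s in design.samples(fraction=fraction, condition=condition)
            if s in matrix.values.columns]
    if len(cols) < require_full_valid:
        raise TableError(
            f"group (fraction={fraction!r}, condition={condition!r}) has "
            f"{len(cols)} replicates; {require_full_valid} required"
        )
    fully_valid = matrix.values[cols].notna().all(axis=1)
    ids = list(matrix.values.index[fully_valid])
    mapping = map_identifiers(ids, matrix.gene_names, annotations.namespace)
    keys = {mapping[p] for p in ids}
    counts = {
        term: len(members & keys)
        for term, (_, members) in annotations.terms.items()
    }
    return pd.Series(counts, name="n_proteins").sort_index()
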