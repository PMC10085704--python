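"""Tabular I/O for the pipeline.

Wide protein-group intensity matrices (TSV), sample-design tables,
GMT annotation sets and result exports. All statistical modules consume
the in-memory types defined here; files on disk are plain TSV/GMT/JSON.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_LINEAR = "linear"
SCALE_LOG2 = "log2"

#: Canonical fraction labels. The first six form the fractionation series,
#: ``proteome`` is the matched whole-proteome layer, ``pulldown``/``igg``
#: belong to affinity-purification (ChIP-MS) designs.
FRACTIONS = (
    "whole_cell",
    "cytoplasm",
    "nuclei",
    "chromatome_w1",
    "chromatome_w2",
    "chromatome_w3",
    "proteome",
    "pulldown",
    "igg",
)

#: The chromatin-enriched fractions of the six-fraction series.
CHROMATOME_FRACTIONS = ("chromatome_w1", "chromatome_w2", "chromatome_w3")

#: The full six-fraction series, in processing order.
SIX_FRACTIONS = (
    "whole_cell",
    "cytoplasm",
    "nuclei",
    "chromatome_w1",
    "chromatome_w2",
    "chromatome_w3",
)


class TableError(ValueError):
    """Raised for malformed input tables or design/matrix mismatches."""


@dataclass
class IntensityMatrix:
    """Protein-group x sample intensity matrix.

    Parameters
    ----------
    values
        DataFrame indexed by unique protein-group ids, columns are unique
        sample ids, ``NaN`` marks missing cells.
    scale_tag
        ``"log2"`` or ``"linear"``. All statistical operations require log2;
        CV computation back-transforms internally.
    gene_names
        Optional symbol per protein, aligned with ``values.index``.
    """

    values: pd.DataFrame
    scale_tag: str = SCALE_LOG2
    gene_names: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale_tag not in (SCALE_LINEAR, SCALE_LOG2):
            raise TableError(
                f"scale_tag must be one of {{linear, log2}}, got {self.scale_tag!r}"
            )
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise TableError(f"duplicate protein ids: {dups}")
        cols = self.values.columns
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise TableError(f"duplicate sample ids: {dups}")
        self.values = self.values.astype(float)
        if self.gene_names is not None:
            self.gene_names = self.gene_names.reindex(idx)

    # -- basic accessors -------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_scale(self, tag: str) -> None:
        if self.scale_tag != tag:
            raise TableError(
                f"operation requires {tag}-scale matrix, got {self.scale_tag!r}"
            )

    def copy(self) -> "IntensityMatrix":
        genes = None if self.gene_names is None else self.gene_names.copy()
        return IntensityMatrix(self.values.copy(), self.scale_tag, genes)

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise TableError(f"samples not in matrix: {missing}")
        return IntensityMatrix(
            self.values[list(sample_ids)].copy(), self.scale_tag, self.gene_names
        )

    def subset_proteins(self, protein_ids: Sequence[str]) -> "IntensityMatrix":
        missing = [p for p in protein_ids if p not in self.values.index]
        if missing:
            raise TableError(f"proteins not in matrix: {missing[:10]}")
        genes = None if self.gene_names is None else self.gene_names.loc[list(protein_ids)]
        return IntensityMatrix(
            self.values.loc[list(protein_ids)].copy(), self.scale_tag, genes
        )


@dataclass
class SampleDesign:
    """Maps each sample id to its (fraction, condition, replicate) group.

    ``table`` is indexed by sample id with columns ``fraction``,
    ``condition`` and ``replicate``. Replicates within a
    (fraction, condition) group must be consecutive integers from 1.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"fraction", "condition", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise TableError(f"design table missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise TableError(f"duplicate sample ids in design: {dups}")
        bad = sorted(set(self.table["fraction"]) - set(FRACTIONS))
        if bad:
            raise TableError(f"unknown fraction labels: {bad}; allowed: {FRACTIONS}")
        reps = self.table["replicate"]
        if (reps.astype(int) != reps).any() or (reps < 1).any():
            raise TableError("replicate indices must be positive integers")
        self.table = self.table.copy()
        self.table["replicate"] = self.table["replicate"].astype(int)
        for key, sub in self.table.groupby(["fraction", "condition"], sort=False):
            got = sorted(sub["replicate"].tolist())
            if got != list(range(1, len(got) + 1)):
                raise TableError(
                    f"replicates of group {key} must be consecutive from 1, got {got}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.table["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def fractions(self) -> list[str]:
        seen: list[str] = []
        for f in self.table["fraction"]:
            if f not in seen:
                seen.append(f)
        return seen

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """(fraction, condition) -> sample ids, in replicate order."""
        out: dict[tuple[str, str], list[str]] = {}
        for key, sub in self.table.groupby(["fraction", "condition"], sort=False):
            out[key] = list(sub.sort_values("replicate").index)
        return out

    def samples(
        self, fraction: str | None = None, condition: str | None = None
    ) -> list[str]:
        tab = self.table
        if fraction is not None:
            tab = tab[tab["fraction"] == fraction]
        if condition is not None:
            tab = tab[tab["condition"] == condition]
        return list(tab.sort_values(["fraction", "condition", "replicate"]).index)

    def subset(self, sample_ids: Sequence[str]) -> "SampleDesign":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise TableError(f"samples not in design: {missing}")
        return SampleDesign(self.table.loc[list(sample_ids)].copy())

    def validate_matrix(self, matrix: IntensityMatrix) -> None:
        """Every matrix sample must appear exactly once in the design."""
        unmatched = [s for s in matrix.sample_ids if s not in self.table.index]
        if unmatched:
            raise TableError(f"matrix samples missing from design: {unmatched}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        tab = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(tab)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass
class AnnotationSet:
    """Annotation terms mapping term ids to (name, member identifiers).

    ``namespace`` declares the identifier space of the members
    (``"gene_name"`` or ``"protein_id"``); lookups are case-insensitive,
    members are stored upper-cased.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    namespace: str = "gene_name"

    def __post_init__(self) -> None:
        for term, (_, members) in self.terms.items():
            if not members:
                raise TableError(f"annotation term {term!r} has no members")

    def __len__(self) -> int:
        return len(self.terms)

    def members(self, term: str) -> frozenset[str]:
        return self.terms[term][1]

    def name(self, term: str) -> str:
        return self.terms[term][0]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_intensity_matrix(
    path: str | Path,
    design: SampleDesign,
    value_columns: str | None = None,
    transform: str = "none",
    id_column: str | None = None,
    gene_column: str | None = None,
) -> IntensityMatrix:
    """Read a wide TSV intensity table into an :class:`IntensityMatrix`.

    Raw zeros and non-finite entries are converted to missing (``NaN``):
    a zero in a MaxQuant/DIA-NN style export means "not quantified" and
    would corrupt log2 statistics. ``transform="log2"`` log2-transforms
    positive values; ``"none"`` assumes the file already stores log2 values.

    Parameters
    ----------
    value_columns
        Optional ``fnmatch`` pattern restricting which columns are treated
        as samples; by default all design sample ids present in the file.
    """
    if transform not in ("none", "log2"):
        raise TableError(f"transform must be 'none' or 'log2', got {transform!r}")
    raw = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if raw.shape[1] < 2:
        raise TableError("matrix file needs an id column and >=1 sample column")
    if id_column is None:
        id_column = raw.columns[0]
    if id_column not in raw.columns:
        raise TableError(f"id column {id_column!r} not found")
    ids = raw[id_column].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique().tolist())
        raise TableError(f"duplicate protein ids: {dups}")

    candidates = [c for c in raw.columns if c != id_column and c != gene_column]
    if value_columns is not None:
        candidates = [c for c in candidates if fnmatch.fnmatch(c, value_columns)]
    selected = [c for c in candidates if c in design.table.index]
    unmatched_file = [c for c in candidates if c not in design.table.index]
    unmatched_design = [s for s in design.sample_ids if s not in raw.columns]
    if not selected:
        raise TableError(
            "no sample columns match the design; "
            f"file columns without design entry: {unmatched_file}; "
            f"design samples without file column: {unmatched_design}"
        )
    if unmatched_file and value_columns is not None:
        raise TableError(f"value columns not present in design: {unmatched_file}")

    values = raw[selected].apply(pd.to_numeric, errors="coerce")
    values = values.mask(~np.isfinite(values))
    values = values.mask(values == 0)  # raw zeros -> missing
    values.index = ids

    if transform == "log2":
        values = values.mask(values <= 0)
        values = np.log2(values)
    genes = None
    if gene_column is not None:
        if gene_column not in raw.columns:
            raise TableError(f"gene column {gene_column!r} not found")
        genes = raw.set_index(ids)[gene_column].astype(str)
    return IntensityMatrix(values, scale_tag=SCALE_LOG2, gene_names=genes)


def read_annotation_gmt(path: str | Path, namespace: str = "gene_name") -> AnnotationSet:
    """Parse a GMT file (term, description, members... per tab-separated line).

    Duplicate term ids have their member sets unioned (a warning is logged);
    empty member lists are rejected.
    """
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableError(
                    f"{path}: line {lineno}: expected term, description and "
                    f">=1 member, got {len(parts)} fields"
                )
            term, name = parts[0], parts[1]
            members = {m.strip().upper() for m in parts[2:] if m.strip()}
            if not members:
                raise TableError(f"{path}: line {lineno}: term {term!r} has no members")
            if term in terms:
                logger.warning("duplicate GMT term %r: unioning members", term)
                old_name, old_members = terms[term]
                terms[term] = (old_name, old_members | members)
            else:
                terms[term] = (name, members)
    return AnnotationSet(
        {t: (n, frozenset(m)) for t, (n, m) in terms.items()}, namespace=namespace
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _as_frame(result) -> pd.DataFrame:
    if isinstance(result, pd.DataFrame):
        return result
    if isinstance(result, pd.Series):
        return result.to_frame()
    if hasattr(result, "table") and isinstance(result.table, pd.DataFrame):
        return result.table
    if hasattr(result, "values") and isinstance(result.values, pd.DataFrame):
        return result.values
    raise TableError(f"cannot serialize result of type {type(result).__name__}")


def write_results_table(
    result,
    path: str | Path,
    parameters: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> None:
    """Write any result object holding a DataFrame as TSV.

    A ``#``-prefixed header records the package version, the parameters
    used and the seed, so every exported table is self-describing.
    """
    from . import __version__

    frame = _as_frame(result)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# chromkit-version: {__version__}\n")
        if parameters:
            for key in sorted(parameters):
                fh.write(f"# param {key}: {parameters[key]}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        out = frame.copy()
        if out.index.name is None:
            out.index.name = "id"
        out.to_csv(fh, sep="\t", float_format="%.17g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0,
                       float_precision="round_trip")


def write_intensity_matrix(
    matrix: IntensityMatrix, path: str | Path, gene_column: str = "gene_name"
) -> None:
    """Write matrix as wide TSV: protein_id, optional gene column, samples."""
    out = matrix.values.copy()
    out.index.name = "protein_id"
    if matrix.gene_names is not None:
        out.insert(0, gene_column, matrix.gene_names)
    # %.17g round-trips float64 exactly
    out.to_csv(path, sep="\t", float_format="%.17g")
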