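"""Seeded simulators producing intensity matrices with known ground truth.

Three generators mirror the experimental layouts the analysis modules
expect: a six-fraction fractionation series, a paired chromatome/proteome
multi-condition experiment, and an affinity-purification (pulldown vs IgG)
experiment with absolute-abundance (iBAQ-like) values.

Abundances are log-normal in linear space (Gaussian on the log2 scale) and
missingness is intensity-dependent (MNAR): the probability that a cell is
missing is ``expit(-steepness * (x - midpoint))`` of its true log2 value,
i.e. a decreasing logistic. All randomness comes from
``numpy.random.default_rng`` (PCG64), so a fixed seed reproduces output
across platforms. Ground truth is returned alongside (and can be written
to JSON) but is never consumed by the analysis modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_tables import (
    CHROMATOME_FRACTIONS,
    SIX_FRACTIONS,
    IntensityMatrix,
    SampleDesign,
)

PROTEIN_CLASSES = ("chromatin_binder", "nucleoplasmic", "cytoplasmic", "background")

DEFAULT_CONDITIONS = ("naive", "formative", "primed", "hESC")

#: Mean log2 enrichment of each latent class in each fraction.
#: Chromatin binders are enriched in the wash fractions and depleted from
#: the cytoplasm; the cytoplasmic class is the mirror image.
DEFAULT_FRACTION_EFFECTS: dict[str, dict[str, float]] = {
    "chromatin_binder": {
        "whole_cell": 0.0,
        "cytoplasm": -2.0,
        "nuclei": 0.5,
        "chromatome_w1": 2.0,
        "chromatome_w2": 2.5,
        "chromatome_w3": 3.0,
    },
    "nucleoplasmic": {
        "whole_cell": 0.0,
        "cytoplasm": -1.0,
        "nuclei": 2.0,
        "chromatome_w1": -2.0,
        "chromatome_w2": -2.5,
        "chromatome_w3": -3.0,
    },
    "cytoplasmic": {
        "whole_cell": 0.0,
        "cytoplasm": 2.0,
        "nuclei": -1.0,
        "chromatome_w1": -2.5,
        "chromatome_w2": -3.0,
        "chromatome_w3": -3.5,
    },
    "background": {f: 0.0 for f in SIX_FRACTIONS},
}


@dataclass
class SimulationParams:
    """Hyperparameters shared by the fractionation and phase simulators.

    All effect sizes are explicit configuration, not hidden constants.
    """

    n_proteins: int = 1000
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "chromatin_binder": 0.25,
            "nucleoplasmic": 0.20,
            "cytoplasmic": 0.30,
            "background": 0.25,
        }
    )
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    fraction_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            c: dict(e) for c, e in DEFAULT_FRACTION_EFFECTS.items()
        }
    )
    n_conditions: int = 3
    condition_names: Sequence[str] | None = None
    n_replicates: int = 3
    condition_effect_sd: float = 1.5
    fraction_of_changing_proteins: float = 0.1
    affinity_effect_sd: float = 0.0
    noise_sd: float = 0.3
    mnar_midpoint: float | None = 20.0
    mnar_steepness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.class_fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(PROTEIN_CLASSES)
        if unknown:
            raise ValueError(f"unknown protein classes: {sorted(unknown)}")
        for name in ("baseline_log2_sd", "condition_effect_sd",
                     "affinity_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0 <= self.fraction_of_changing_proteins <= 0.5:
            raise ValueError("fraction_of_changing_proteins must be in [0, 0.5]")

    def conditions(self) -> list[str]:
        if self.condition_names is not None:
            names = list(self.condition_names)
            if len(names) != self.n_conditions:
                raise ValueError("condition_names length != n_conditions")
            return names
        if self.n_conditions > len(DEFAULT_CONDITIONS):
            return [f"cond{i + 1}" for i in range(self.n_conditions)]
        return list(DEFAULT_CONDITIONS[: self.n_conditions])


@dataclass
class GroundTruth:
    """Simulator record of latent truth, used only by tests.

    ``affinity_effects`` is by construction exactly
    ``condition_effects_chromatome - condition_effects_proteome``.
    """

    classes: pd.Series
    fraction_effects: pd.DataFrame | None = None
    condition_effects_chromatome: pd.DataFrame | None = None
    condition_effects_proteome: pd.DataFrame | None = None
    affinity_effects: pd.DataFrame | None = None
    chromatome_enrichment: pd.Series | None = None
    stoichiometry: pd.Series | None = None
    true_values: pd.DataFrame | None = None
    true_values_proteome: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        def enc(obj):
            if obj is None:
                return None
            if isinstance(obj, pd.Series):
                return {"type": "series", "data": obj.to_dict()}
            return {
                "type": "frame",
                "index": list(obj.index),
                "columns": list(obj.columns),
                "data": obj.where(pd.notna(obj), None).values.tolist(),
            }

        payload = {name: enc(getattr(self, name)) for name in (
            "classes", "fraction_effects", "condition_effects_chromatome",
            "condition_effects_proteome", "affinity_effects",
            "chromatome_enrichment", "stoichiometry", "true_values",
            "true_values_proteome",
        )}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        def dec(obj):
            if obj is None:
                return None
            if obj["type"] == "series":
                return pd.Series(obj["data"])
            frame = pd.DataFrame(
                obj["data"], index=obj["index"], columns=obj["columns"]
            )
            return frame.astype(float)

        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(**{k: dec(v) for k, v in payload.items()})


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(1, n + 1)]


def _assign_classes(params: SimulationParams, rng: np.random.Generator) -> pd.Series:
    """Deterministic class counts (largest-remainder), shuffled order."""
    n = params.n_proteins
    fracs = {c: params.class_fractions.get(c, 0.0) for c in PROTEIN_CLASSES}
    counts = {c: int(np.floor(f * n)) for c, f in fracs.items()}
    remainder = n - sum(counts.values())
    by_frac_part = sorted(
        PROTEIN_CLASSES, key=lambda c: fracs[c] * n - counts[c], reverse=True
    )
    for c in by_frac_part[:remainder]:
        counts[c] += 1
    labels = np.repeat(list(PROTEIN_CLASSES), [counts[c] for c in PROTEIN_CLASSES])
    rng.shuffle(labels)
    return pd.Series(labels, index=_protein_ids(n), name="class")


def _apply_mnar(
    values: np.ndarray,
    true_values: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mask cells at random with logistic-in-intensity probability."""
    if params.mnar_midpoint is None:
        return values
    p_miss = expit(-params.mnar_steepness * (true_values - params.mnar_midpoint))
    mask = rng.random(values.shape) < p_miss
    out = values.copy()
    out[mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_fraction_experiment(
    params: SimulationParams,
) -> tuple[IntensityMatrix, SampleDesign, GroundTruth]:
    """Simulate the six-fraction series (one condition, triplicates).

    Each protein draws a log2 baseline, receives its class's per-fraction
    enrichment, replicate noise, and MNAR missingness. Chromatin binders
    end up enriched in the wash fractions and depleted from the cytoplasm;
    the cytoplasmic class shows the reverse profile.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    classes = _assign_classes(params, rng)
    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n)

    effects = pd.DataFrame(
        [
            [params.fraction_effects[classes.iloc[i]][f] for f in SIX_FRACTIONS]
            for i in range(n)
        ],
        index=classes.index,
        columns=list(SIX_FRACTIONS),
        dtype=float,
    )

    condition = params.conditions()[0]
    sample_ids, rows = [], []
    true_cols, noisy_cols = {}, {}
    for f in SIX_FRACTIONS:
        true_f = baseline + effects[f].values
        for r in range(1, params.n_replicates + 1):
            sid = f"{f}_{condition}_{r}"
            sample_ids.append(sid)
            rows.append({"fraction": f, "condition": condition, "replicate": r})
            true_cols[sid] = true_f
            noisy_cols[sid] = true_f + rng.normal(0.0, params.noise_sd, n)

    true_values = pd.DataFrame(true_cols, index=classes.index)
    values = pd.DataFrame(noisy_cols, index=classes.index)
    values[:] = _apply_mnar(values.values, true_values.values, params, rng)

    design = SampleDesign(pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id")))
    genes = pd.Series(
        [f"GENE{i:05d}" for i in range(1, n + 1)], index=classes.index, name="gene_name"
    )
    matrix = IntensityMatrix(values, scale_tag="log2", gene_names=genes)
    truth = GroundTruth(
        classes=classes, fraction_effects=effects, true_values=true_values
    )
    return matrix, design, truth


def simulate_phase_experiment(
    params: SimulationParams,
    affinity_effects: pd.DataFrame | np.ndarray | None = None,
    chromatome_enrichment: np.ndarray | None = None,
) -> tuple[IntensityMatrix, IntensityMatrix, SampleDesign, GroundTruth]:
    """Simulate paired chromatome/proteome matrices over >=2 conditions.

    A declared subset of proteins (``fraction_of_changing_proteins``)
    carries condition effects present in both layers; a second, disjoint
    subset carries chromatome-only "affinity" effects while its proteome
    truth stays constant. ``chromatome_enrichment`` optionally adds a
    per-protein constant offset to the chromatome layer in every condition
    (chromatin-enrichment over expression).

    Returns ``(chromatome, proteome, design, truth)`` where the design
    covers the sample ids of both matrices.
    """
    if params.n_conditions < 2:
        raise ValueError("phase experiment requires n_conditions >= 2")
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    conditions = params.conditions()
    classes = _assign_classes(params, rng)
    pids = classes.index
    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n)

    n_changing = int(round(params.fraction_of_changing_proteins * n))
    order = rng.permutation(n)
    changing_idx = order[:n_changing]
    affinity_idx = order[n_changing : 2 * n_changing]

    cond_eff = np.zeros((n, len(conditions)))
    if n_changing and params.condition_effect_sd > 0:
        cond_eff[changing_idx, 1:] = rng.normal(
            0.0, params.condition_effect_sd, (n_changing, len(conditions) - 1)
        )

    if affinity_effects is not None:
        aff = np.asarray(affinity_effects, dtype=float)
        if aff.shape != (n, len(conditions)):
            raise ValueError(
                f"affinity_effects must have shape ({n}, {len(conditions)})"
            )
        aff = aff.copy()
    else:
        aff = np.zeros((n, len(conditions)))
        if n_changing and params.affinity_effect_sd > 0:
            aff[affinity_idx, 1:] = rng.normal(
                0.0, params.affinity_effect_sd, (n_changing, len(conditions) - 1)
            )

    if chromatome_enrichment is not None:
        enrich = np.asarray(chromatome_enrichment, dtype=float)
        if enrich.shape != (n,):
            raise ValueError(f"chromatome_enrichment must have length {n}")
    else:
        enrich = np.zeros(n)

    chrom_truth = cond_eff + aff  # per-condition log2 offsets, chromatome layer
    prot_truth = cond_eff

    sample_ids, rows = [], []
    chrom_cols, prot_cols = {}, {}
    chrom_true_cols, prot_true_cols = {}, {}
    for ci, cond in enumerate(conditions):
        t_chrom = baseline + chrom_truth[:, ci] + enrich
        t_prot = baseline + prot_truth[:, ci]
        for r in range(1, params.n_replicates + 1):
            sid_c = f"chrom_{cond}_{r}"
            sid_p = f"prot_{cond}_{r}"
            sample_ids += [sid_c, sid_p]
            rows += [
                {"fraction": "chromatome_w3", "condition": cond, "replicate": r},
                {"fraction": "proteome", "condition": cond, "replicate": r},
            ]
            chrom_true_cols[sid_c] = t_chrom
            prot_true_cols[sid_p] = t_prot
            chrom_cols[sid_c] = t_chrom + rng.normal(0.0, params.noise_sd, n)
            prot_cols[sid_p] = t_prot + rng.normal(0.0, params.noise_sd, n)

    chrom_true = pd.DataFrame(chrom_true_cols, index=pids)
    prot_true = pd.DataFrame(prot_true_cols, index=pids)
    chrom_vals = pd.DataFrame(chrom_cols, index=pids)
    prot_vals = pd.DataFrame(prot_cols, index=pids)
    chrom_vals[:] = _apply_mnar(chrom_vals.values, chrom_true.values, params, rng)
    prot_vals[:] = _apply_mnar(prot_vals.values, prot_true.values, params, rng)

    design = SampleDesign(pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id")))
    genes = pd.Series(
        [f"GENE{i:05d}" for i in range(1, n + 1)], index=pids, name="gene_name"
    )
    chrom = IntensityMatrix(chrom_vals, "log2", genes)
    prot = IntensityMatrix(prot_vals, "log2", genes.copy())
    truth = GroundTruth(
        classes=classes,
        condition_effects_chromatome=pd.DataFrame(
            chrom_truth, index=pids, columns=conditions
        ),
        condition_effects_proteome=pd.DataFrame(
            prot_truth, index=pids, columns=conditions
        ),
        affinity_effects=pd.DataFrame(aff, index=pids, columns=conditions),
        chromatome_enrichment=pd.Series(enrich, index=pids, name="enrichment"),
        true_values=chrom_true,
        true_values_proteome=prot_true,
    )
    return chrom, prot, design, truth


@dataclass
class ChipMSParams:
    """Parameters for the pulldown-vs-IgG (affinity purification) simulator.

    ``stoichiometry`` maps subunit ids to their ratio relative to the bait;
    the bait itself must be present with stoichiometry 1.0. Complex members
    are enriched in the pulldown by ``member_enrichment_log2`` over IgG;
    background proteins have equal expected intensity in both groups.
    """

    bait: str = "BAIT"
    stoichiometry: Mapping[str, float] = field(
        default_factory=lambda: {"BAIT": 1.0, "SUBA": 0.5, "SUBB": 1.0}
    )
    n_background: int = 500
    n_replicates: int = 3
    conditions: Sequence[str] = ("naive",)
    bait_log2_ibaq: float = 25.0
    member_enrichment_log2: float = 4.0
    background_log2_mean: float = 20.0
    background_log2_sd: float = 2.0
    noise_sd: float = 0.2
    mnar_midpoint: float | None = None
    mnar_steepness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bait not in self.stoichiometry:
            raise ValueError(f"bait {self.bait!r} absent from stoichiometry map")
        if abs(self.stoichiometry[self.bait] - 1.0) > 1e-12:
            raise ValueError("bait stoichiometry must be 1.0")
        if any(s <= 0 for s in self.stoichiometry.values()):
            raise ValueError("stoichiometries must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


def simulate_chipms(
    params: ChipMSParams,
) -> tuple[IntensityMatrix, SampleDesign, GroundTruth]:
    """Simulate log2 iBAQ-like pulldown and IgG matrices.

    Before noise, each complex member's pulldown intensity equals
    ``bait + log2(stoichiometry)``; its IgG intensity sits
    ``member_enrichment_log2`` below the pulldown. Background proteins
    share the same expected intensity in both groups.
    """
    rng = np.random.default_rng(params.seed)
    members = list(params.stoichiometry)
    n_bg = params.n_background
    bg_ids = [f"BG{i:05d}" for i in range(1, n_bg + 1)]
    pids = members + bg_ids
    n = len(pids)

    stoich = np.array([params.stoichiometry[m] for m in members])
    member_pd = params.bait_log2_ibaq + np.log2(stoich)
    member_igg = member_pd - params.member_enrichment_log2
    bg_level = rng.normal(params.background_log2_mean, params.background_log2_sd, n_bg)

    true_pd = np.concatenate([member_pd, bg_level])
    true_igg = np.concatenate([member_igg, bg_level])

    sample_ids, rows = [], []
    cols, true_cols = {}, {}
    for cond in params.conditions:
        for frac, true_f in (("pulldown", true_pd), ("igg", true_igg)):
            for r in range(1, params.n_replicates + 1):
                sid = f"{frac}_{cond}_{r}"
                sample_ids.append(sid)
                rows.append({"fraction": frac, "condition": cond, "replicate": r})
                true_cols[sid] = true_f
                cols[sid] = true_f + rng.normal(0.0, params.noise_sd, n)

    index = pd.Index(pids, name="protein_id")
    true_values = pd.DataFrame(true_cols, index=index)
    values = pd.DataFrame(cols, index=index)
    if params.mnar_midpoint is not None:
        p_miss = expit(
            -params.mnar_steepness * (true_values.values - params.mnar_midpoint)
        )
        mask = rng.random(values.shape) < p_miss
        vals = values.values
        vals[mask] = np.nan
        values[:] = vals

    design = SampleDesign(pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id")))
    classes = pd.Series(
        ["bait" if p == params.bait else "complex_member" for p in members]
        + ["background"] * n_bg,
        index=index,
        name="class",
    )
    genes = pd.Series(pids, index=index, name="gene_name")
    matrix = IntensityMatrix(values, "log2", genes)
    truth = GroundTruth(
        classes=classes,
        stoichiometry=pd.Series(stoich, index=pd.Index(members), name="stoichiometry"),
        true_values=true_values,
    )
    return matrix, design, truth
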