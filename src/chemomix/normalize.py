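"""Per-layer normalisation ladders and scaling transforms.

Each omic layer is brought to a per-cell comparable unit before
integration:

* elementome: concentration (ug per g dry mass) x dry mass (g) / total
  cells in the sampled aliquot  ->  ug per cell;
* metabolome: peak area / internal-standard area / total cells in the
  50 mL aliquot;
* volatilome: handled in :mod:`chemomix.volatiles` (internal standard
  then cells/mL).

On the shared per-cell scale, joint analysis uses a natural-log
transform with an analyte-specific pseudo-count (half the smallest
detected positive value, applied only when zeros or non-detects are
present), mean-centring, and, for heatmap display, autoscaling
(mean 0, sample sd 1 per analyte).

C:N:P elemental stoichiometry is expressed molar with phosphorus fixed
at 1, the convention of the Redfield ratio (106:16:1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AnalyteTable, StepRecord, ValidationError

# atomic masses, g/mol
ATOMIC_MASS = {"C": 12.011, "N": 14.007, "P": 30.974}


@dataclass(frozen=True)
class StoichiometryRatio:
    """Molar C:N:P ratio scaled so that P = 1."""

    c: float
    n: float
    p: float = 1.0

    def __post_init__(self) -> None:
        if not (self.c > 0 and self.n > 0 and self.p == 1.0):
            raise ValidationError("ratio components must be > 0 with p = 1")

    def __str__(self) -> str:
        return f"{self.c:.3g}:{self.n:.3g}:{self.p:g}"


def cnp_ratio(c_mass: float, n_mass: float, p_mass: float) -> StoichiometryRatio:
    """Convert C, N, P masses (same unit) to a molar ratio with P = 1."""
    if not (c_mass > 0 and n_mass > 0):
        raise ValidationError("carbon and nitrogen masses must be > 0")
    if not p_mass > 0:
        raise ValidationError("phosphorus mass must be > 0")
    c_mol = c_mass / ATOMIC_MASS["C"]
    n_mol = n_mass / ATOMIC_MASS["N"]
    p_mol = p_mass / ATOMIC_MASS["P"]
    return StoichiometryRatio(c=c_mol / p_mol, n=n_mol / p_mol)


def normalise_elementome(table: AnalyteTable) -> AnalyteTable:
    """Elementome ladder: ug/g dry mass -> ug per cell.

    Multiplies each sample's concentrations by its pellet dry mass and
    divides by the total cells in the sampled aliquot (cells/mL x mL).
    """
    factors = {}
    for s in table.samples:
        if s.dry_mass is None:
            raise ValidationError(f"sample {s.sample_id!r} has no dry_mass")
        factors[s.sample_id] = s.dry_mass / s.total_cells
    ab = table.abundance.mul(pd.Series(factors), axis=1)
    return table.evolve(
        abundance=ab,
        step=StepRecord("normalise_elementome", {"unit": "ug_per_cell"}),
    )


def normalise_metabolome(table: AnalyteTable, is_areas: pd.Series) -> AnalyteTable:
    """Metabolome ladder: peak area -> per-cell relative abundance.

    Divides by the internal-standard (D-sorbitol-6-13C) peak area of the
    sample, then by the total cells in the sampled aliquot.
    """
    is_areas = pd.Series(is_areas)
    factors = {}
    for s in table.samples:
        area = is_areas.get(s.sample_id)
        if area is None or not np.isfinite(area) or area <= 0:
            raise ValidationError(
                f"sample {s.sample_id!r}: internal-standard area must be > 0"
            )
        factors[s.sample_id] = 1.0 / (area * s.total_cells)
    ab = table.abundance.mul(pd.Series(factors), axis=1)
    return table.evolve(
        abundance=ab,
        step=StepRecord(
            "normalise_metabolome", {"unit": "per_is_per_cell"}
        ),
    )


def _pseudo_counts(table: AnalyteTable) -> pd.Series:
    """Analyte-specific pseudo-count: half the smallest detected positive
    value when zeros/non-detects are present, else 0."""
    filled = table.filled(0.0)
    deltas = {}
    for analyte, row in filled.iterrows():
        positive = row[row > 0]
        if positive.empty:
            raise ValidationError(
                f"analyte {analyte!r} has no detected positive values"
            )
        has_zero = (row <= 0).any() or (~table.detected.loc[analyte]).any()
        deltas[analyte] = positive.min() / 2.0 if has_zero else 0.0
    return pd.Series(deltas)


def log_transform(table: AnalyteTable) -> AnalyteTable:
    """Natural log of (x + delta_a), non-detects entering as zero.

    delta_a is half the smallest detected positive value of analyte a,
    applied only for analytes with zeros or non-detects; base-e is a
    pure rescaling and never reorders values.
    """
    deltas = _pseudo_counts(table)
    ab = np.log(table.filled(0.0).add(deltas, axis=0))
    return table.evolve(
        abundance=ab,
        detected=pd.DataFrame(True, index=ab.index, columns=ab.columns),
        step=StepRecord("log_transform", {"pseudo_count": "half_min_positive"}),
    )


def mean_centre(table: AnalyteTable) -> AnalyteTable:
    """Subtract each analyte's cross-sample mean (idempotent)."""
    ab = table.abundance.sub(table.abundance.mean(axis=1), axis=0)
    return table.evolve(abundance=ab, step=StepRecord("mean_centre"))


def autoscale(table: AnalyteTable) -> AnalyteTable:
    """Per analyte: subtract mean, divide by sample sd (ddof=1)."""
    sd = table.abundance.std(axis=1, ddof=1)
    zero = sd[~(sd > 0)].index.tolist()
    if zero:
        raise ValidationError(f"zero-variance analytes cannot be autoscaled: {zero}")
    ab = table.abundance.sub(table.abundance.mean(axis=1), axis=0).div(sd, axis=0)
    return table.evolve(abundance=ab, step=StepRecord("autoscale", {"ddof": 1}))
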