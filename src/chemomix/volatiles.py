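"""Volatile (BVOC) peak-table hygiene.

An aligned, library-identified GC×GC peak table still carries
instrument and background artefacts.  The cleanup chain applied here,
in order:

1. :func:`normalise_to_internal_standard` — divide by the per-sample
   internal-standard (chlorobenzene-d5) area;
2. :func:`average_technical_duplicates` — collapse repeated
   measurements of each biological replicate (mean over detected
   duplicates; detected if detected in at least one);
3. :func:`remove_contaminants` — drop known artefacts by
   case-insensitive exact name match;
4. :func:`blank_subtract` — analytes detected in more than half of the
   medium-only water blanks are genuine background; their mean blank
   abundance is subtracted everywhere and values driven to zero or
   below become non-detects;
5. :func:`presence_filter` — retain an analyte only if detected in at
   least four biological replicates within at least one treatment
   group ("present in more than three");
6. :func:`normalise_to_cells` — divide by the sample's cell density
   (cells/mL).

After hygiene, :func:`partition_by_treatment` splits retained analytes
into heat-only / control-only / shared sets and :func:`class_summary`
tabulates the partition by chemical class.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    AnalyteTable,
    SampleMeta,
    StepRecord,
    ValidationError,
)

STAGE_ORDER = [
    "normalise_to_internal_standard",
    "average_technical_duplicates",
    "remove_contaminants",
    "blank_subtract",
    "presence_filter",
    "normalise_to_cells",
]


def normalise_to_internal_standard(
    table: AnalyteTable, is_areas: pd.Series | Mapping[str, float]
) -> AnalyteTable:
    """Divide every abundance by its sample's internal-standard area."""
    is_areas = pd.Series(is_areas)
    factors = {}
    for s in table.samples:
        area = is_areas.get(s.sample_id)
        if area is None or not np.isfinite(area) or area <= 0:
            raise ValidationError(
                f"sample {s.sample_id!r}: internal-standard area must be > 0"
            )
        factors[s.sample_id] = 1.0 / area
    ab = table.abundance.mul(pd.Series(factors), axis=1)
    return table.evolve(
        abundance=ab, step=StepRecord("normalise_to_internal_standard")
    )


def _averaged_id(treatment: str, biological_replicate: int) -> str:
    return f"{treatment}-{biological_replicate}"


def average_technical_duplicates(table: AnalyteTable) -> AnalyteTable:
    """Collapse technical duplicates to one column per biological replicate.

    The mean is taken over *detected* duplicate values, so a single
    detection carries through (thermal-desorption dropouts are common
    and zero-imputing them would bias means down); the averaged entry is
    detected if any duplicate was.  Uneven duplicate counts trigger a
    warning and proceed with whatever is available.
    """
    groups: dict[tuple[str, int], list[SampleMeta]] = {}
    for s in table.samples:
        if s.is_blank:
            continue
        if s.biological_replicate is None:
            raise ValidationError(
                f"sample {s.sample_id!r} has no biological_replicate"
            )
        groups.setdefault((s.treatment, s.biological_replicate), []).append(s)

    counts = {len(v) for v in groups.values()}
    if len(counts) > 1:
        warnings.warn(
            f"uneven technical duplicate counts per replicate: {sorted(counts)}; "
            "averaging over available duplicates",
            stacklevel=2,
        )

    new_samples: list[SampleMeta] = []
    cols = {}
    det_cols = {}
    for (treatment, rep), members in sorted(groups.items()):
        sid = _averaged_id(treatment, rep)
        ids = [m.sample_id for m in members]
        block = table.abundance[ids]
        cols[sid] = block.mean(axis=1)  # NaN-skipping mean over detected
        det_cols[sid] = table.detected[ids].any(axis=1)
        densities = [m.cell_density for m in members if m.cell_density is not None]
        new_samples.append(
            SampleMeta(
                sample_id=sid,
                treatment=treatment,
                biological_replicate=rep,
                technical_replicate=None,
                cell_density=float(np.mean(densities)) if densities else None,
                aliquot_volume=members[0].aliquot_volume,
                dry_mass=members[0].dry_mass,
            )
        )
    ab = pd.DataFrame(cols, index=table.abundance.index)
    det = pd.DataFrame(det_cols, index=table.abundance.index)
    return table.evolve(
        abundance=ab,
        detected=det,
        samples=new_samples,
        step=StepRecord("average_technical_duplicates"),
    )


def remove_contaminants(
    table: AnalyteTable, exclusion_list: Iterable[str]
) -> AnalyteTable:
    """Drop analytes on a known-artefact list (case-insensitive exact match)."""
    excluded = {str(name).lower() for name in exclusion_list}
    removed = [a for a in table.analyte_ids if a.lower() in excluded]
    keep = [a for a in table.analyte_ids if a.lower() not in excluded]
    sub = table.subset_analytes(keep)
    return sub.evolve(step=StepRecord("remove_contaminants", {"removed": removed}))


def blank_subtract(
    table: AnalyteTable,
    blanks: AnalyteTable,
    presence_fraction: float = 0.5,
    mode: str = "subtract",
) -> AnalyteTable:
    """Correct genuine background using medium-only water blanks.

    An analyte detected in strictly more than ``presence_fraction`` of
    the blank samples is flagged as background.  With the default
    ``mode="subtract"``, the mean of its detected blank abundances is
    subtracted from every sample and results <= 0 become non-detects
    (pure removal would delete biological signal exceeding background).
    ``mode="remove"`` drops flagged analytes outright.
    """
    if blanks.n_samples == 0:
        raise ValidationError("no blank samples provided")
    if mode not in ("subtract", "remove"):
        raise ValidationError(f"unknown blank-subtraction mode {mode!r}")

    shared = [a for a in table.analyte_ids if a in set(blanks.analyte_ids)]
    frac = blanks.detected.loc[shared].mean(axis=1)
    flagged = [a for a in shared if frac[a] > presence_fraction]

    if mode == "remove":
        sub = table.subset_analytes([a for a in table.analyte_ids if a not in flagged])
        return sub.evolve(
            step=StepRecord(
                "blank_subtract",
                {"mode": mode, "presence_fraction": presence_fraction,
                 "background": flagged},
            )
        )

    ab = table.abundance.copy()
    if flagged:
        means = blanks.abundance.loc[flagged].mean(axis=1)  # over detected blanks
        ab.loc[flagged] = ab.loc[flagged].sub(means, axis=0)
    det = table.detected & (ab > 0)
    return table.evolve(
        abundance=ab.where(det),
        detected=det,
        step=StepRecord(
            "blank_subtract",
            {"mode": mode, "presence_fraction": presence_fraction,
             "background": flagged},
        ),
    )


def presence_filter(table: AnalyteTable, min_present: int = 4) -> AnalyteTable:
    """Retain analytes detected in >= ``min_present`` biological
    replicates within at least one treatment group."""
    keep = []
    group_cols = {t: table.treatment_columns(t) for t in ("control", "heat")}
    for analyte in table.analyte_ids:
        det = table.detected.loc[analyte]
        if any(det[cols].sum() >= min_present for cols in group_cols.values() if cols):
            keep.append(analyte)
    sub = table.subset_analytes(keep)
    return sub.evolve(
        step=StepRecord(
            "presence_filter",
            {"min_present": min_present,
             "removed": table.n_analytes - len(keep)},
        )
    )


def normalise_to_cells(table: AnalyteTable) -> AnalyteTable:
    """Divide abundances by the sample's cell density (cells/mL)."""
    factors = {}
    for s in table.samples:
        if s.cell_density is None or not s.cell_density > 0:
            raise ValidationError(
                f"sample {s.sample_id!r}: cell density missing or not positive"
            )
        factors[s.sample_id] = 1.0 / s.cell_density
    ab = table.abundance.mul(pd.Series(factors), axis=1)
    return table.evolve(
        abundance=ab, step=StepRecord("normalise_to_cells", {"unit": "per_cell_mL"})
    )


def preprocess_volatiles(
    table: AnalyteTable,
    blanks: AnalyteTable,
    is_areas: pd.Series,
    blank_is_areas: pd.Series | None = None,
    exclusion_list: Iterable[str] = (),
    presence_fraction: float = 0.5,
    min_present: int = 4,
    blank_mode: str = "subtract",
) -> AnalyteTable:
    """Run the full hygiene chain in its fixed order."""
    t = normalise_to_internal_standard(table, is_areas)
    if blank_is_areas is not None:
        blanks = normalise_to_internal_standard(blanks, blank_is_areas)
    t = average_technical_duplicates(t)
    t = remove_contaminants(t, exclusion_list)
    t = blank_subtract(t, blanks, presence_fraction, mode=blank_mode)
    t = presence_filter(t, min_present)
    t = normalise_to_cells(t)
    return t


def partition_by_treatment(table: AnalyteTable) -> dict[str, set[str]]:
    """Split retained analytes into heat-only / control-only / shared.

    An analyte belongs to a treatment if detected in at least one of
    that group's biological replicates; the three sets are disjoint and
    cover all retained analytes.
    """
    heat_cols = table.treatment_columns("heat")
    control_cols = table.treatment_columns("control")
    in_heat = table.detected[heat_cols].any(axis=1)
    in_control = table.detected[control_cols].any(axis=1)
    ids = pd.Index(table.analyte_ids)
    return {
        "unique_to_heat": set(ids[in_heat & ~in_control]),
        "unique_to_control": set(ids[in_control & ~in_heat]),
        "shared": set(ids[in_heat & in_control]),
    }


def class_summary(
    table: AnalyteTable, partition: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Counts per chemical class x {heat_only, control_only, shared}."""
    classes = (
        table.analyte_class
        if table.analyte_class is not None
        else pd.Series(index=table.abundance.index, dtype=object)
    )
    classes = classes.fillna("unclassified").replace("", "unclassified")
    rows = {}
    for analyte in table.analyte_ids:
        cls = classes.get(analyte, "unclassified")
        row = rows.setdefault(cls, {"heat_only": 0, "control_only": 0, "shared": 0})
        if analyte in partition["unique_to_heat"]:
            row["heat_only"] += 1
        elif analyte in partition["unique_to_control"]:
            row["control_only"] += 1
        elif analyte in partition["shared"]:
            row["shared"] += 1
    if not rows:
        return pd.DataFrame(columns=["heat_only", "control_only", "shared"])
    return pd.DataFrame(rows).T.sort_index()[["heat_only", "control_only", "shared"]]
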