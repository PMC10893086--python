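"""Core data containers shared by every pipeline stage.

Three kinds of chemical profiling data move through the pipeline —
elemental concentrations, metabolite peak areas and volatile (BVOC) peak
areas — all held in a single container, :class:`AnalyteTable`: an
analyte x sample abundance matrix with an explicit detection mask, the
per-sample metadata, and an append-only provenance ladder recording
every normalisation or filtering step applied.

Non-detects are represented internally as a boolean mask (abundance is
NaN wherever ``detected`` is False); no sentinel numbers are stored.
Stages that need a numeric stand-in for structural absence (testing,
integration) request zero-filled values explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
HEAT = "heat"
TREATMENTS = (CONTROL, HEAT)

LAYERS = ("element", "metabolite", "volatile", "integrated")


class ValidationError(ValueError):
    """An input failed a structural validity check."""


class UnknownSampleError(ValidationError):
    """A matrix column names a sample absent from the metadata."""


class NegativeAbundanceError(ValidationError):
    """Raw abundances must be non-negative."""


class DuplicateAnalyteError(ValidationError):
    """Analyte identifiers must be unique within a table."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata.

    Parameters
    ----------
    sample_id
        Unique sample key (case-sensitive exact match everywhere).
    treatment
        ``"control"`` or ``"heat"`` for biological samples; None for blanks.
    biological_replicate
        1-based replicate index within the treatment group.
    technical_replicate
        1-based index of repeated measurements of the same biological
        replicate (volatile sampling); None once duplicates are averaged.
    cell_density
        Cells per mL of culture, blank-corrected; strictly positive for
        non-blank samples.
    aliquot_volume
        Volume (mL) of culture sampled for this measurement; the default
        50 mL is the aliquot used for all three layers in this design.
    dry_mass
        Freeze-dried pellet mass in grams (elementome samples only).
    is_blank
        True for medium-only water blanks.
    """

    sample_id: str
    treatment: str | None
    biological_replicate: int | None
    technical_replicate: int | None = None
    cell_density: float | None = None
    aliquot_volume: float = 50.0
    dry_mass: float | None = None
    is_blank: bool = False

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.is_blank:
            return
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: treatment must be one of "
                f"{TREATMENTS}, got {self.treatment!r}"
            )
        if self.cell_density is not None and not self.cell_density > 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: cell_density must be > 0"
            )
        if not self.aliquot_volume > 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: aliquot_volume must be > 0"
            )
        if self.dry_mass is not None and not self.dry_mass > 0:
            raise ValidationError(f"sample {self.sample_id!r}: dry_mass must be > 0")

    @property
    def total_cells(self) -> float:
        """Total cells in the sampled aliquot (cells/mL x mL)."""
        if self.cell_density is None:
            raise ValidationError(
                f"sample {self.sample_id!r} has no cell_density recorded"
            )
        return self.cell_density * self.aliquot_volume


@dataclass
class StepRecord:
    """One entry of a table's provenance ladder."""

    step_name: str
    parameters: dict[str, Any] = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def __post_init__(self) -> None:
        if not self.step_name:
            raise ValidationError("step_name must be non-empty")


def blank_correct_cytometry(events: float, blank_events: Sequence[float]) -> float:
    """Blank-correct a flow-cytometry event count.

    The mean event count of the blank runs is subtracted from the sample
    count; counts cannot be negative, so results are floored at zero.
    """
    blanks = list(blank_events)
    if not blanks:
        raise ValidationError("blank_events must be non-empty")
    if events < 0 or any(b < 0 for b in blanks):
        raise ValidationError("event counts must be >= 0")
    return max(0.0, float(events) - float(np.mean(blanks)))


@dataclass
class AnalyteTable:
    """One omic layer as an analyte x sample abundance matrix.

    ``abundance`` rows are analytes, columns are samples, aligned with
    ``samples`` (one :class:`SampleMeta` per column, same order).
    ``detected`` is a boolean mask of the same shape; undetected entries
    hold NaN in ``abundance``.  ``ladder`` is the append-only list of
    processing steps that produced the current values.
    """

    layer: str
    abundance: pd.DataFrame
    detected: pd.DataFrame
    samples: list[SampleMeta]
    analyte_class: pd.Series | None = None
    ladder: list[StepRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        ab = self.abundance
        if ab.index.has_duplicates:
            dups = ab.index[ab.index.duplicated()].unique().tolist()
            raise DuplicateAnalyteError(f"duplicate analyte ids: {dups}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in metadata")
        if list(ab.columns) != ids:
            raise ValidationError(
                "abundance columns do not match sample metadata order"
            )
        det = self.detected.astype(bool)
        if not det.index.equals(ab.index) or not det.columns.equals(ab.columns):
            raise ValidationError("detected mask does not align with abundance")
        # enforce: not detected <=> NaN abundance
        ab = ab.astype(float).where(det)
        det = det & ab.notna()
        self.abundance = ab.where(det)
        self.detected = det
        if self.analyte_class is not None:
            self.analyte_class = self.analyte_class.reindex(ab.index)

    # -- accessors ---------------------------------------------------------

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_analytes(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise UnknownSampleError(f"unknown sample {sample_id!r}")

    def treatment_columns(self, treatment: str) -> list[str]:
        """Sample ids of non-blank samples in a treatment group."""
        return [
            s.sample_id
            for s in self.samples
            if not s.is_blank and s.treatment == treatment
        ]

    def filled(self, fill: float = 0.0) -> pd.DataFrame:
        """Abundance with non-detects replaced by ``fill``."""
        return self.abundance.fillna(fill)

    # -- evolution ---------------------------------------------------------

    def evolve(
        self,
        *,
        abundance: pd.DataFrame | None = None,
        detected: pd.DataFrame | None = None,
        samples: list[SampleMeta] | None = None,
        analyte_class: pd.Series | None | str = "keep",
        step: StepRecord | None = None,
    ) -> "AnalyteTable":
        """Return a copy with replaced fields and ``step`` appended."""
        ab = self.abundance if abundance is None else abundance
        det = self.detected if detected is None else detected
        if detected is None and abundance is not None:
            det = self.detected.reindex(index=ab.index, columns=ab.columns)
        smp = self.samples if samples is None else samples
        if isinstance(analyte_class, str) and analyte_class == "keep":
            cls = None if self.analyte_class is None else self.analyte_class.copy()
        else:
            cls = analyte_class
        ladder = list(self.ladder) + ([step] if step is not None else [])
        return AnalyteTable(
            layer=self.layer,
            abundance=ab.copy(),
            detected=det.copy(),
            samples=list(smp),
            analyte_class=cls,
            ladder=ladder,
        )

    def with_step(self, step_name: str, **parameters: Any) -> StepRecord:
        """Build a :class:`StepRecord` (convenience for ``evolve(step=...)``)."""
        return StepRecord(step_name=step_name, parameters=parameters)

    def subset_analytes(self, ids: Iterable[str]) -> "AnalyteTable":
        ids = [i for i in ids]
        missing = set(ids) - set(self.analyte_ids)
        if missing:
            raise ValidationError(f"unknown analytes: {sorted(missing)}")
        return self.evolve(
            abundance=self.abundance.loc[ids],
            detected=self.detected.loc[ids],
            analyte_class=None
            if self.analyte_class is None
            else self.analyte_class.loc[ids],
        )

    def select_samples(self, ids: Sequence[str]) -> "AnalyteTable":
        keep = list(ids)
        missing = set(keep) - set(self.sample_ids)
        if missing:
            raise UnknownSampleError(f"unknown samples: {sorted(missing)}")
        metas = {s.sample_id: s for s in self.samples}
        return self.evolve(
            abundance=self.abundance[keep],
            detected=self.detected[keep],
            samples=[metas[i] for i in keep],
        )

    def ladder_steps(self) -> list[str]:
        return [s.step_name for s in self.ladder]
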