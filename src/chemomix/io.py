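"""Delimited-text readers and writers.

All on-disk formats are plain CSV: analyte matrices with analytes as
rows (first column the analyte id, optional second column ``class``),
and a metadata sidecar keyed by ``sample_id``.  Missing matrix cells are
empty on disk and become non-detects in memory.  Floats are written with
Python's shortest round-trip repr, so write -> read is numerically the
identity.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AnalyteTable,
    DuplicateAnalyteError,
    NegativeAbundanceError,
    SampleMeta,
    StepRecord,
    UnknownSampleError,
    ValidationError,
)

_META_COLUMNS = [
    "sample_id",
    "treatment",
    "biological_replicate",
    "technical_replicate",
    "cell_density",
    "aliquot_volume",
    "dry_mass",
    "is_blank",
]


def _opt(value, cast):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return cast(value)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read the sample-metadata sidecar CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str, "treatment": str})
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: metadata must have a sample_id column")
    metas = []
    for _, row in df.iterrows():
        r = row.to_dict()
        metas.append(
            SampleMeta(
                sample_id=str(r["sample_id"]),
                treatment=_opt(r.get("treatment"), str),
                biological_replicate=_opt(r.get("biological_replicate"), int),
                technical_replicate=_opt(r.get("technical_replicate"), int),
                cell_density=_opt(r.get("cell_density"), float),
                aliquot_volume=_opt(r.get("aliquot_volume"), float) or 50.0,
                dry_mass=_opt(r.get("dry_mass"), float),
                is_blank=bool(r.get("is_blank", False))
                and str(r.get("is_blank")).lower() not in ("false", "0"),
            )
        )
    return metas


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> Path:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "treatment": s.treatment,
                "biological_replicate": s.biological_replicate,
                "technical_replicate": s.technical_replicate,
                "cell_density": s.cell_density,
                "aliquot_volume": s.aliquot_volume,
                "dry_mass": s.dry_mass,
                "is_blank": s.is_blank,
            }
        )
    path = Path(path)
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)
    return path


def read_analyte_table(
    path: str | Path,
    layer: str,
    meta: str | Path | Sequence[SampleMeta],
) -> AnalyteTable:
    """Read an analyte x sample matrix CSV plus its metadata.

    The first CSV column is the analyte id; a column named ``class``
    (any case) is taken as the per-analyte chemical class.  Remaining
    columns must name samples present in the metadata.  Empty cells
    become non-detects.
    """
    if isinstance(meta, (str, Path)):
        metas = read_sample_meta(meta)
    else:
        metas = list(meta)
    by_id = {m.sample_id: m for m in metas}

    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateAnalyteError(f"{path}: duplicate analyte ids {dups}")

    cls = None
    class_cols = [c for c in df.columns if c.lower() == "class"]
    if class_cols:
        cls = df[class_cols[0]].astype(str)
        df = df.drop(columns=class_cols)

    unknown = [c for c in df.columns if c not in by_id]
    if unknown:
        raise UnknownSampleError(f"{path}: samples not in metadata: {unknown}")

    values = df.astype(float)
    if (values.to_numpy() < 0).any():
        bad = values.index[(values < 0).any(axis=1)].tolist()
        raise NegativeAbundanceError(f"{path}: negative raw abundance in {bad}")

    samples = [by_id[c] for c in df.columns]
    return AnalyteTable(
        layer=layer,
        abundance=values,
        detected=values.notna(),
        samples=samples,
        analyte_class=cls,
        ladder=[StepRecord("read", {"path": str(path)})],
    )


def write_analyte_table(
    table: AnalyteTable,
    path: str | Path,
    meta_path: str | Path | None = None,
) -> Path:
    """Write a table to CSV (non-detects as empty cells)."""
    path = Path(path)
    out = table.abundance.copy()
    if table.analyte_class is not None:
        out.insert(0, "class", table.analyte_class)
    out.to_csv(path, index_label="analyte")
    if meta_path is not None:
        write_sample_meta(table.samples, meta_path)
    return path


def write_ladder(table: AnalyteTable, path: str | Path) -> Path:
    """Write the provenance ladder as JSON (step names and parameters)."""
    path = Path(path)
    records = [
        {"step_name": s.step_name, "parameters": s.parameters} for s in table.ladder
    ]
    path.write_text(json.dumps(records, indent=2, default=str) + "\n")
    return path


def read_series(path: str | Path, value_column: str | None = None) -> pd.Series:
    """Read a two-column CSV (sample_id, value) as a Series."""
    df = pd.read_csv(path, dtype={0: str})
    idx = df.columns[0]
    col = value_column or df.columns[1]
    return df.set_index(idx)[col].astype(float)


def write_results(results: Iterable, path: str | Path) -> Path:
    """Write a list of per-analyte test results to CSV.

    Accepts the :class:`~chemomix.univariate.TestResult` dataclass (or
    anything with its fields); an empty list produces a headers-only file.
    """
    cols = [
        "analyte_id",
        "layer",
        "test",
        "statistic",
        "df",
        "p",
        "p_adj",
        "direction",
        "significant",
    ]
    rows = [{c: getattr(r, c, None) for c in cols} for r in results]
    path = Path(path)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def read_results(path: str | Path):
    from .univariate import TestResult

    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            TestResult(
                analyte_id=str(row["analyte_id"]),
                layer=str(row["layer"]),
                test=str(row["test"]),
                statistic=float(row["statistic"]),
                df=_opt(row.get("df"), float),
                p=float(row["p"]),
                p_adj=float(row["p_adj"]),
                direction=str(row["direction"]),
                significant=bool(row["significant"]),
            )
        )
    return out


def write_pca(result, out_dir: str | Path, prefix: str = "pca") -> list[Path]:
    """Write PCA scores, loadings and explained variance as CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (
        ("scores", result.scores),
        ("loadings", result.loadings),
    ):
        p = out_dir / f"{prefix}_{name}.csv"
        df.to_csv(p)
        paths.append(p)
    p = out_dir / f"{prefix}_variance.csv"
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(result.explained_variance_pct))],
            "explained_variance_pct": result.explained_variance_pct,
        }
    ).to_csv(p, index=False)
    paths.append(p)
    return paths
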