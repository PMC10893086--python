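"""Cross-layer integration.

Once every layer is on the per-cell scale, integration is plain
row-concatenation over the shared biological samples: analyte ids are
prefixed with their layer ("element:K", "metabolite:citric acid", ...),
and sample columns are harmonised to a canonical (sorted) order.
Volatile non-detects stay masked and enter downstream computations as
zeros on the raw scale (the analyte-specific pseudo-count of the log
transform handles them); ``drop_incomplete=True`` instead performs
complete-case analysis by dropping analytes with any non-detect.  No
per-layer block scaling is applied by default — the log transform plus
mean-centring is the only harmonisation — but unit-variance block
scaling is available for sensitivity checks since unequal layer
variances can dominate a PCA.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AnalyteTable,
    DuplicateAnalyteError,
    StepRecord,
    ValidationError,
)


def layer_of(prefixed_id: str) -> str:
    """Layer tag encoded in an integrated analyte id ("element:K" -> "element")."""
    if ":" not in prefixed_id:
        raise ValidationError(f"analyte id {prefixed_id!r} carries no layer prefix")
    return prefixed_id.split(":", 1)[0]


def integrate_layers(
    tables: Sequence[AnalyteTable],
    drop_incomplete: bool = False,
    block_scale: bool = False,
) -> AnalyteTable:
    """Concatenate normalised layers into one analyte x sample table."""
    if not tables:
        raise ValidationError("no layers to integrate")
    sample_sets = [frozenset(t.sample_ids) for t in tables]
    if len(set(sample_sets)) != 1:
        raise ValidationError(
            "layers do not share an identical sample set: "
            + "; ".join(f"{t.layer}={sorted(s)}" for t, s in zip(tables, sample_sets))
        )
    order = sorted(sample_sets[0])

    blocks, det_blocks, classes = [], [], []
    for t in tables:
        t = t.select_samples(order)
        ab = t.abundance
        if block_scale:
            sd = float(np.nanstd(ab.to_numpy(), ddof=1))
            if sd > 0:
                ab = ab / sd
        ab = ab.rename(index=lambda a: f"{t.layer}:{a}")
        blocks.append(ab)
        det_blocks.append(t.detected.rename(index=lambda a: f"{t.layer}:{a}"))
        cls = (
            t.analyte_class
            if t.analyte_class is not None
            else pd.Series(index=t.abundance.index, dtype=object)
        )
        classes.append(cls.rename(index=lambda a: f"{t.layer}:{a}"))

    abundance = pd.concat(blocks)
    detected = pd.concat(det_blocks)
    if abundance.index.has_duplicates:
        dups = abundance.index[abundance.index.duplicated()].unique().tolist()
        raise DuplicateAnalyteError(f"duplicate prefixed analyte ids: {dups}")
    if drop_incomplete:
        keep = detected.all(axis=1)
        abundance, detected = abundance[keep], detected[keep]

    metas = {s.sample_id: s for s in tables[0].samples}
    return AnalyteTable(
        layer="integrated",
        abundance=abundance,
        detected=detected,
        samples=[metas[i] for i in order],
        analyte_class=pd.concat(classes).reindex(abundance.index),
        ladder=[
            StepRecord(
                "integrate_layers",
                {
                    "layers": [t.layer for t in tables],
                    "rows": [t.n_analytes for t in tables],
                    "block_scale": block_scale,
                    "drop_incomplete": drop_incomplete,
                },
            )
        ],
    )
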