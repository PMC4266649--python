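"""Per subject × region × condition voxel counts, percent volumes, means."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .phantom import RegionSpec
from .segmentation import BASE_CONDITION, RegionMaskSet
from .tensor import ScalarMaps

__all__ = ["TABLE_COLUMNS", "summarize_subject", "cohort_table", "pivot_measure"]

TABLE_COLUMNS = [
    "subject",
    "region",
    "hemisphere",
    "condition",
    "n_voxels",
    "n_voxels_atlas",
    "percent_volume",
    "percent_volume_of_atlas",
    "mean_fa",
    "mean_ad",
    "mean_rd",
    "excluded",
]


def summarize_subject(
    subject_id: str,
    mask_set: RegionMaskSet,
    scalars: ScalarMaps,
    regions: Sequence[RegionSpec],
    atlas_counts: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Long-format rows for one subject.

    ``percent_volume`` is 100 · n(condition) / n(base) with the trace-masked
    base as denominator; ``percent_volume_of_atlas`` is the diagnostic
    alternative with the raw atlas label count as denominator.  Excluded
    cells (below the minimum voxel count, or with an empty base) keep their
    counts but carry no means.
    """
    rows = []
    for r in regions:
        n_base = mask_set.count(r.label_id, BASE_CONDITION)
        n_atlas = (atlas_counts or {}).get(r.label_id, np.nan)
        for cond in mask_set.conditions:
            mask = mask_set.masks[r.label_id, cond]
            n = int(mask.sum())
            excluded = bool(mask_set.excluded.get((r.label_id, cond), False))
            unanalyzable = n_base == 0
            pct = 100.0 * n / n_base if n_base else np.nan
            pct_atlas = (
                100.0 * n / n_atlas if np.isfinite(n_atlas) and n_atlas else np.nan
            )
            if excluded or unanalyzable:
                mean_fa = mean_ad = mean_rd = np.nan
            else:
                mean_fa = float(scalars.fa[mask].mean())
                mean_ad = float(scalars.ad[mask].mean())
                mean_rd = float(scalars.rd[mask].mean())
            rows.append(
                {
                    "subject": subject_id,
                    "region": r.name,
                    "hemisphere": r.hemisphere,
                    "condition": cond,
                    "n_voxels": n,
                    "n_voxels_atlas": n_atlas,
                    "percent_volume": pct,
                    "percent_volume_of_atlas": pct_atlas,
                    "mean_fa": mean_fa,
                    "mean_ad": mean_ad,
                    "mean_rd": mean_rd,
                    "excluded": excluded or unanalyzable,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def cohort_table(summaries: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject summaries into one long table.

    One row per (subject, region, hemisphere, condition); duplicates raise
    :class:`IntegrityError`.  An empty input yields an empty table with the
    schema intact.
    """
    if not summaries:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    table = pd.concat(summaries, ignore_index=True)
    key = ["subject", "region", "hemisphere", "condition"]
    if table.duplicated(subset=key).any():
        dupes = table[table.duplicated(subset=key, keep=False)]
        raise IntegrityError(
            "duplicate (subject, region, hemisphere, condition) cells:\n"
            f"{dupes[key].drop_duplicates().to_string(index=False)}"
        )
    return table


def pivot_measure(
    table: pd.DataFrame, measure: str, agg: str = "mean"
) -> pd.DataFrame:
    """Figure-ready (region, hemisphere) × condition grid of one measure."""
    usable = table[~table["excluded"]]
    return usable.pivot_table(
        index=["region", "hemisphere"],
        columns="condition",
        values=measure,
        aggfunc=agg,
    )
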