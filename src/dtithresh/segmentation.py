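"""Threshold masking cascade: atlas labels → CSF exclusion → FA cutoffs.

The cascade reproduces the standard atlas-based WM selection procedure:
a region starts as its atlas label, voxels whose trace exceeds the CSF
cutoff (strictly greater) are excluded, and each FA cutoff then keeps
voxels with FA strictly greater than the cutoff.  Conditions are ordered
base (trace-masked atlas), then the FA cutoffs ascending; masks are
nested by construction.  Region/condition cells with fewer than
``min_voxels`` voxels are flagged excluded and carry no statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GridMismatchError
from .phantom import RegionSpec
from .tensor import ScalarMaps

__all__ = ["ThresholdConfig", "RegionMaskSet", "BASE_CONDITION",
           "base_mask", "fa_masks", "apply_min_voxel_rule", "segment"]

BASE_CONDITION = "base"


@dataclass(frozen=True)
class ThresholdConfig:
    """Cutoffs of the masking cascade.

    trace_cutoff : mm²/s; voxels with trace strictly above are CSF.
    fa_cutoffs : ascending FA cutoffs, each applied as FA > cutoff.
    min_voxels : cells with fewer voxels than this are excluded.
    """

    trace_cutoff: float = 0.006
    fa_cutoffs: tuple[float, ...] = (0.15, 0.20, 0.25)
    min_voxels: int = 10

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.fa_cutoffs)
        if any(not 0 < c < 1 for c in cuts):
            raise ValueError("fa_cutoffs must lie in (0, 1)")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("fa_cutoffs must be strictly increasing")
        if self.trace_cutoff <= 0:
            raise ValueError("trace_cutoff must be positive")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        object.__setattr__(self, "fa_cutoffs", cuts)

    @property
    def conditions(self) -> tuple[str, ...]:
        """Ordered condition labels: base then one per FA cutoff."""
        return (BASE_CONDITION,) + tuple(
            f"FA>{c:g}" for c in self.fa_cutoffs
        )


@dataclass
class RegionMaskSet:
    """Per region × condition boolean masks plus exclusion flags."""

    masks: dict[tuple[int, str], np.ndarray]
    excluded: dict[tuple[int, str], bool] = field(default_factory=dict)
    conditions: tuple[str, ...] = ()

    def count(self, label_id: int, condition: str) -> int:
        return int(self.masks[label_id, condition].sum())


def _check_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape:
        raise GridMismatchError(
            f"{what}: shapes {a.shape} and {b.shape} do not match"
        )


def base_mask(
    labels: np.ndarray,
    trace: np.ndarray,
    cfg: ThresholdConfig,
    regions: Sequence[RegionSpec],
    valid: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Atlas label ∩ (trace ≤ cutoff) ∩ valid, per region.

    Voxels with trace exactly at the cutoff are retained (exclusion is a
    strict inequality).  A region absent from the label volume yields an
    empty mask and a warning, not an error.
    """
    _check_grid(labels, trace, "labels vs trace map")
    if valid is None:
        valid = np.ones(labels.shape, dtype=bool)
    _check_grid(labels, valid, "labels vs validity mask")
    keep = (trace <= cfg.trace_cutoff) & valid
    out: dict[int, np.ndarray] = {}
    for r in regions:
        region_vox = labels == r.label_id
        if not region_vox.any():
            warnings.warn(
                f"region {r.name!r} (label {r.label_id}) absent from label "
                "volume; empty mask",
                stacklevel=2,
            )
        out[r.label_id] = region_vox & keep
    return out


def fa_masks(
    base: dict[int, np.ndarray],
    fa: np.ndarray,
    cfg: ThresholdConfig,
) -> RegionMaskSet:
    """Nest FA > cutoff masks inside each base mask (strict inequality)."""
    masks: dict[tuple[int, str], np.ndarray] = {}
    for label_id, bmask in base.items():
        _check_grid(bmask, fa, "base mask vs FA map")
        masks[label_id, BASE_CONDITION] = bmask
        for cond, cut in zip(cfg.conditions[1:], cfg.fa_cutoffs):
            masks[label_id, cond] = bmask & (fa > cut)
    return RegionMaskSet(masks=masks, conditions=cfg.conditions)


def apply_min_voxel_rule(mask_set: RegionMaskSet, cfg: ThresholdConfig) -> RegionMaskSet:
    """Flag cells with fewer than ``min_voxels`` voxels as excluded.

    Exclusion is per region × condition (and, upstream, per subject): a
    cell excluded at one cutoff still contributes at the others.
    """
    for key, mask in mask_set.masks.items():
        mask_set.excluded[key] = int(mask.sum()) < cfg.min_voxels
    return mask_set


def segment(
    labels: np.ndarray,
    scalars: ScalarMaps,
    cfg: ThresholdConfig,
    regions: Sequence[RegionSpec],
) -> RegionMaskSet:
    """Full cascade for one subject: base masks, FA nesting, voxel rule."""
    base = base_mask(labels, scalars.trace, cfg, regions, valid=scalars.valid)
    mask_set = fa_masks(base, scalars.fa, cfg)
    return apply_min_voxel_rule(mask_set, cfg)
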