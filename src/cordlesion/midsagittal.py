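"""Midsagittal 2D lesion parameters: tissue bridges and lesion type.

Tissue bridges are the spared cord tissue ventral (anterior) and dorsal
(posterior) to the post-traumatic lesion, measured on the single sagittal
slice through the cord's centroid. The bridge width reported is the
*narrowest* spared corridor: the minimum, over all superior–inferior rows
that the lesion intersects, of the anterior (ventral) or posterior (dorsal)
gap between the lesion and the cord boundary, in mm.

The presence/absence pattern of the two bridges classifies the lesion:

========  =======================================
central   both ventral and dorsal bridges intact
ventral   only dorsal bridges intact
dorsal    only ventral bridges intact
complete  no intact bridges
========  =======================================

Bridges are conventionally measured on hard boundaries, so both masks are
binarized (default threshold 0.5) before the gap scan. A lesion with no
voxels on the midsagittal slice leaves the metric undefined (flagged, never
fabricated): the 2D measure genuinely does not apply to such lesions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes_io import SoftMask, assert_cogrid

__all__ = [
    "TissueBridges",
    "BridgeError",
    "midsagittal_slice",
    "tissue_bridges",
    "classify_lesion_type",
    "LESION_TYPES",
]

LESION_TYPES = ("central", "ventral", "dorsal", "complete")


class BridgeError(ValueError):
    """Invalid tissue-bridge input."""


@dataclass(frozen=True)
class TissueBridges:
    """Ventral and dorsal bridge widths (mm) on the midsagittal slice.

    ``defined`` is False when the lesion does not appear on the midsagittal
    slice; widths are then meaningless and must not be read.
    """

    ventral_mm: float = 0.0
    dorsal_mm: float = 0.0
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and (self.ventral_mm < 0 or self.dorsal_mm < 0):
            raise BridgeError("bridge widths must be >= 0 mm")

    @property
    def total_mm(self) -> float:
        """Total bridge width: ventral + dorsal."""
        return self.ventral_mm + self.dorsal_mm


def midsagittal_slice(cord: SoftMask) -> int:
    """Right–left slice index through the cord's mass centroid (rounded)."""
    vals = cord.values
    total = vals.sum()
    if total <= 0:
        raise BridgeError("cord mask is empty; cannot locate midsagittal slice")
    idx = np.arange(cord.grid.shape[0], dtype=np.float64)
    centroid = float((vals.sum(axis=(1, 2)) * idx).sum() / total)
    return int(round(centroid))


def tissue_bridges(
    lesion: SoftMask,
    cord: SoftMask,
    slice_index: int,
    binarize_at: float = 0.5,
) -> TissueBridges:
    """Measure ventral/dorsal tissue bridges on one sagittal slice.

    For every superior–inferior row of the slice where the binarized lesion
    intersects the binarized cord, the ventral gap is the count of spared
    cord voxels anterior to the lesion and the dorsal gap the count
    posterior to it, each times the anterior–posterior voxel spacing.
    Reported widths are the minima over those rows; a row where the lesion
    reaches the cord boundary gives width 0.
    """
    assert_cogrid([lesion, cord])
    n_rl = lesion.grid.shape[0]
    if not (0 <= slice_index < n_rl):
        raise BridgeError(f"slice index {slice_index} outside right-left axis [0, {n_rl - 1}]")

    ap_spacing = lesion.grid.spacing[1]
    les2d = lesion.values[slice_index] >= binarize_at  # (PA, IS)
    cord2d = cord.values[slice_index] >= binarize_at
    if not cord2d.any():
        raise BridgeError(f"cord is empty on sagittal slice {slice_index}")

    ventral = np.inf
    dorsal = np.inf
    any_lesion_row = False
    for j in range(les2d.shape[1]):  # each S-I row
        cord_col = np.flatnonzero(cord2d[:, j])
        if cord_col.size == 0:
            continue
        les_col = np.flatnonzero(les2d[:, j] & cord2d[:, j])
        if les_col.size == 0:
            continue
        any_lesion_row = True
        # axis 1 runs posterior -> anterior: ventral tissue sits at higher
        # indices than the lesion, dorsal tissue at lower indices.
        n_ventral = int((cord_col > les_col.max()).sum())
        n_dorsal = int((cord_col < les_col.min()).sum())
        ventral = min(ventral, n_ventral * ap_spacing)
        dorsal = min(dorsal, n_dorsal * ap_spacing)

    if not any_lesion_row:
        return TissueBridges(defined=False)
    return TissueBridges(ventral_mm=float(ventral), dorsal_mm=float(dorsal))


def classify_lesion_type(bridges: TissueBridges) -> str:
    """Classify the lesion by which bridges are intact (width > 0 mm)."""
    if not bridges.defined:
        raise BridgeError("cannot classify: bridges undefined (no lesion on midsagittal slice)")
    ventral_intact = bridges.ventral_mm > 0
    dorsal_intact = bridges.dorsal_mm > 0
    if ventral_intact and dorsal_intact:
        return "central"
    if dorsal_intact:
        return "ventral"
    if ventral_intact:
        return "dorsal"
    return "complete"
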