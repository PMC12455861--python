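"""White-matter tract atlas: tract membership, sides, and merged group masks.

Spinal white-matter tracts are modelled as probabilistic masks on the same
template grid as the lesion and cord segmentations. Each tract belongs to a
functional group — *sensory* (ascending pathways assessed by light-touch and
pinprick testing) or *motor* (descending pathways assessed by key-muscle
strength) — and to one *side* (left or right hemicord), so that lateralized
damage can be quantified.

The atlas is declared by a manifest CSV (columns ``filename, tract_name,
group, side``) pointing at one NIfTI volume per tract, in the spirit of the
PAM50 probabilistic tract atlas. Tract composition is whatever the manifest
declares; the canonical tract name lists below document the conventional
grouping and drive the synthetic phantom atlas.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes_io import SoftMask, assert_cogrid, read_mask

__all__ = [
    "SENSORY_TRACTS",
    "MOTOR_TRACTS",
    "GROUPS",
    "SIDES",
    "TractAtlas",
    "AtlasError",
    "load_atlas",
    "group_mask",
    "split_left_right",
    "cord_midline",
]

#: Ascending (sensory) tracts, one instance per side.
SENSORY_TRACTS: tuple[str, ...] = (
    "fasciculus_gracilis",
    "fasciculus_cuneatus",
    "ventral_spinocerebellar",
    "spinothalamic",
    "spinoreticular",
    "spino_olivary",
)

#: Descending (motor) tracts, one instance per side.
MOTOR_TRACTS: tuple[str, ...] = (
    "lateral_corticospinal",
    "ventral_corticospinal",
    "rubrospinal",
    "lateral_reticulospinal",
    "ventral_reticulospinal",
    "lateral_vestibulospinal",
    "ventral_vestibulospinal",
    "tectospinal",
    "medial_reticulospinal",
)

GROUPS = ("motor", "sensory")
SIDES = ("left", "right")


class AtlasError(ValueError):
    """Invalid atlas manifest or atlas query."""


@dataclass
class TractAtlas:
    """Named collection of tract masks with group and side labels.

    Invariants (checked at construction): all masks share one grid; every
    tract has exactly one group in {motor, sensory} and one side in
    {left, right}.
    """

    tracts: dict[str, SoftMask]
    group_of: dict[str, str]
    side_of: dict[str, str]

    def __post_init__(self) -> None:
        if not self.tracts:
            raise AtlasError("atlas has no tracts")
        names = set(self.tracts)
        if set(self.group_of) != names or set(self.side_of) != names:
            raise AtlasError("group_of / side_of must label exactly the atlas tracts")
        for name in self.tracts:
            if self.group_of[name] not in GROUPS:
                raise AtlasError(f"tract {name!r}: unknown group {self.group_of[name]!r} (expected one of {GROUPS})")
            if self.side_of[name] not in SIDES:
                raise AtlasError(f"tract {name!r}: unknown side {self.side_of[name]!r} (expected one of {SIDES})")
        if len(self.tracts) >= 2:
            assert_cogrid(list(self.tracts.values()))

    @property
    def grid(self):
        return next(iter(self.tracts.values())).grid

    def members(self, group: str, side: str) -> list[str]:
        """Tract names in the given group and side ('both' pools sides)."""
        if group not in GROUPS:
            raise AtlasError(f"unknown group {group!r}")
        if side not in SIDES + ("both",):
            raise AtlasError(f"unknown side {side!r}")
        sides = SIDES if side == "both" else (side,)
        return sorted(
            name
            for name in self.tracts
            if self.group_of[name] == group and self.side_of[name] in sides
        )

    def __len__(self) -> int:
        return len(self.tracts)


def load_atlas(directory: str | Path, manifest: str | Path) -> TractAtlas:
    """Load a tract atlas from a directory of NIfTI masks plus a manifest.

    Parameters
    ----------
    directory
        Directory containing one mask volume per tract.
    manifest
        CSV with columns ``filename, tract_name, group, side``. ``group``
        must be ``motor`` or ``sensory``; ``side`` must be ``left`` or
        ``right``.
    """
    directory = Path(directory)
    table = pd.read_csv(manifest)
    required = {"filename", "tract_name", "group", "side"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise AtlasError(f"manifest missing columns: {sorted(missing_cols)}")
    if table.empty:
        raise AtlasError(f"manifest {manifest} declares no tracts")
    if table["tract_name"].duplicated().any():
        dup = table.loc[table["tract_name"].duplicated(), "tract_name"].iloc[0]
        raise AtlasError(f"duplicate tract name in manifest: {dup!r}")

    tracts: dict[str, SoftMask] = {}
    group_of: dict[str, str] = {}
    side_of: dict[str, str] = {}
    for row in table.itertuples(index=False):
        path = directory / str(row.filename)
        if not path.exists():
            raise AtlasError(f"tract file not found: {path}")
        name = str(row.tract_name)
        group, side = str(row.group), str(row.side)
        if group not in GROUPS:
            raise AtlasError(f"tract {name!r}: unknown group label {group!r}")
        if side not in SIDES:
            raise AtlasError(f"tract {name!r}: unknown side label {side!r}")
        tracts[name] = read_mask(path)
        group_of[name] = group
        side_of[name] = side
    return TractAtlas(tracts=tracts, group_of=group_of, side_of=side_of)


def group_mask(atlas: TractAtlas, group: str, side: str) -> SoftMask:
    """Merge the member tracts of a group/side into one soft mask.

    Member probabilities are summed voxelwise and capped at 1: overlapping
    probabilistic tracts may sum above 1, but a voxel cannot be more than
    100% white matter.
    """
    names = atlas.members(group, side)
    if not names:
        raise AtlasError(f"atlas has no tracts with group={group!r}, side={side!r}")
    total = np.zeros(atlas.grid.shape, dtype=np.float64)
    for name in names:
        total += atlas.tracts[name].values
    np.clip(total, 0.0, 1.0, out=total)
    return SoftMask(atlas.grid, total, copy=False)


def split_left_right(mask: SoftMask, midline_index: float) -> tuple[SoftMask, SoftMask]:
    """Partition a mask into (left, right) halves about a sagittal midline.

    Axis 0 runs right -> left, so voxels with index above ``midline_index``
    fall on the left. The two outputs sum voxelwise to the input: a voxel
    exactly on an integral midline contributes half its value to each side,
    so mass is conserved exactly.
    """
    n = mask.grid.shape[0]
    if not (-0.5 <= midline_index <= n - 0.5):
        raise AtlasError(f"midline index {midline_index} outside right-left axis range [0, {n - 1}]")
    idx = np.arange(n, dtype=np.float64)
    left_w = np.where(idx > midline_index, 1.0, 0.0)
    if float(midline_index).is_integer() and 0 <= int(midline_index) < n:
        left_w[int(midline_index)] = 0.5
    left_w = left_w[:, None, None]
    left = SoftMask(mask.grid, mask.values * left_w, copy=False)
    right = SoftMask(mask.grid, mask.values * (1.0 - left_w), copy=False)
    return left, right


def cord_midline(cord: SoftMask) -> float:
    """Default sagittal midline: mean of per-slice cord centroids.

    For each superior–inferior slice with any cord mass, the mass-weighted
    centroid along the right–left axis is computed; the midline is the plain
    average over those slices. Template-space cords are nearly straight, so
    this is robust to small asymmetries.
    """
    vals = cord.values
    slice_mass = vals.sum(axis=(0, 1))  # per S-I slice
    nonempty = slice_mass > 0
    if not nonempty.any():
        raise AtlasError("cord mask is empty; cannot locate midline")
    idx = np.arange(cord.grid.shape[0], dtype=np.float64)
    weighted = (vals * idx[:, None, None]).sum(axis=(0, 1))
    centroids = weighted[nonempty] / slice_mass[nonempty]
    return float(centroids.mean())
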