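"""Two-point Dixon fat-fraction mapping and region extraction.

In-phase and opposed-phase magnitude images are composites of the water (W)
and fat (F) signals, IP = W + F and OP = |W - F|. Under a water-dominant
assumption (F <= W, true in liver for fat fractions below 50%) the pair is
inverted voxel-by-voxel as W = (IP + OP)/2, F = (IP - OP)/2, and the signal
fat-fraction map is 100 * F / (F + W). Fat-dominant voxels are mis-separated
by construction (magnitude data carry no phase to resolve the ambiguity) —
the map is a "signal fat-fraction", not a confounder-free PDFF.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .grid import GeometryError, PDFFMap, VOISpec, VolumeGrid

__all__ = [
    "SeparationResult",
    "FatFractionResult",
    "separate_two_point",
    "fat_fraction_map",
    "place_voi",
    "mean_pdff",
]


class SeparationResult(NamedTuple):
    water: VolumeGrid
    fat: VolumeGrid
    #: voxels where IP < OP (noise) produced negative fat, floored at 0
    n_floored: int


class FatFractionResult(NamedTuple):
    pdff: PDFFMap
    #: masked voxels with zero total signal, set to 0% and flagged
    n_zero_signal: int


def separate_two_point(in_phase: VolumeGrid, opposed_phase: VolumeGrid) -> SeparationResult:
    """Invert IP/OP composites into water and fat images.

    Water-dominant convention: water = (IP + OP)/2, fat = (IP - OP)/2.
    Voxels where noise makes OP exceed IP would yield negative fat; these are
    floored at zero and counted in ``n_floored``.
    """
    in_phase.require_congruent(opposed_phase, "in-phase and opposed-phase images")
    if in_phase.values.min() < 0 or opposed_phase.values.min() < 0:
        raise ValueError("magnitude images must be non-negative")
    water = (in_phase.values + opposed_phase.values) / 2.0
    fat = (in_phase.values - opposed_phase.values) / 2.0
    negative = fat < 0
    n_floored = int(negative.sum())
    if n_floored:
        fat = np.where(negative, 0.0, fat)
    return SeparationResult(in_phase.like(water), in_phase.like(fat), n_floored)


def fat_fraction_map(water: VolumeGrid, fat: VolumeGrid, mask: VolumeGrid) -> FatFractionResult:
    """Voxel-wise signal fat-fraction map, 100 * fat / (fat + water), in percent.

    Voxels with zero total signal are set to 0% and counted; the map is
    clipped to [0, 100].
    """
    water.require_congruent(fat, "water and fat images")
    water.require_congruent(mask, "images and mask")
    if water.values.min() < 0 or fat.values.min() < 0:
        raise ValueError("water and fat images must be non-negative")
    total = water.values + fat.values
    zero = total == 0
    n_zero = int((zero & (mask.values > 0.5)).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(zero, 0.0, 100.0 * fat.values / np.where(zero, 1.0, total))
    ff = np.clip(ff, 0.0, 100.0)
    return FatFractionResult(PDFFMap(water.like(ff), mask), n_zero)


def place_voi(pdff: PDFFMap | VolumeGrid, voi: VOISpec) -> VolumeGrid:
    """Select the voxels whose centres fall inside a cubic VOI.

    A voxel belongs to the VOI iff its centre lies in the closed cube
    [center - side/2, center + side/2] on every axis, in world mm.
    """
    grid = pdff.map if isinstance(pdff, PDFFMap) else pdff
    half = voi.side / 2.0
    sel_1d = []
    for ax in range(3):
        c = grid.axis_coords(ax)
        sel_1d.append((c >= voi.center[ax] - half - 1e-9) & (c <= voi.center[ax] + half + 1e-9))
    sel = sel_1d[0][:, None, None] & sel_1d[1][None, :, None] & sel_1d[2][None, None, :]
    if not sel.any():
        raise GeometryError(
            f"VOI (center {voi.center} mm, side {voi.side} mm) selects no voxel"
        )
    return grid.like(sel.astype(np.float64))


def mean_pdff(pdff: PDFFMap, region: VolumeGrid | None = None) -> float:
    """Mean fat fraction (%) over region ∩ liver mask (whole mask if region is None)."""
    if region is None:
        sel = pdff.mask_bool
    else:
        pdff.map.require_congruent(region, "PDFF map and region")
        sel = (region.values > 0.5) & pdff.mask_bool
        if not sel.any():
            raise GeometryError("region does not intersect the liver mask")
    return float(pdff.map.values[sel].mean())
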