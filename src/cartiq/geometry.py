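"""Cartilage boundary sets, laminar splitting, slice selection,
grid resampling and thickness morphometry.

All distances are computed in-plane (2-D, per sagittal slice), centre to
centre between voxel centres, in millimetres.  Slice spacing is an order
of magnitude larger than the in-plane pixel, and segmentation is
slice-wise, so 3-D distances would mix scales without gaining accuracy.

A cartilage region has two boundary types: the articular surface, where
cartilage touches background (synovial space), and the bone-cartilage
interface, where it touches bone.  The laminar split assigns each
cartilage voxel to the superficial lamina when its Euclidean distance to
the nearest articular-boundary voxel does not exceed its distance to the
nearest bone-boundary voxel (ties are superficial), so the border between
laminae is equidistant between the two surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .images import (
    BACKGROUND,
    BONE,
    LAMINA_DEEP,
    LAMINA_SUPERFICIAL,
    CartilageMask,
    Grid,
    LaminarMask,
)

_EDGE = -1  # sentinel for out-of-volume when testing adjacency


@dataclass(frozen=True)
class ThicknessSummary:
    """Mean cartilage thickness of one region over a slice range."""

    region: int
    slices: tuple[int, int]  # inclusive (first, last)
    mean_thickness: float  # mm
    n_voxels: int


def _padded_slice(labels2d: np.ndarray) -> np.ndarray:
    """Pad a label slice with an edge sentinel so out-of-volume neighbours
    count as neither background nor bone."""
    return np.pad(labels2d, 1, constant_values=_EDGE)


def _adjacent_to(labels2d: np.ndarray, region: int, neighbour_label: int) -> np.ndarray:
    """Region voxels with a 4-adjacent in-plane neighbour of the given label."""
    p = _padded_slice(labels2d)
    hit = np.zeros_like(labels2d, dtype=bool)
    core = labels2d == region
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nb = p[1 + dr : 1 + dr + labels2d.shape[0], 1 + dc : 1 + dc + labels2d.shape[1]]
        hit |= core & (nb == neighbour_label)
    return hit


def boundary_sets(mask: CartilageMask, region: int) -> tuple[np.ndarray, np.ndarray]:
    """Articular and bone-facing boundary voxels of a region.

    Returns two boolean volumes: cartilage voxels of ``region`` 4-adjacent
    in-plane to background, and those 4-adjacent to bone.  A voxel may be
    in both (single-voxel-thick sheet).  Raises on degenerate geometry
    with no articular or no bone contact.
    """
    if region not in mask.regions:
        raise ValueError(f"region {region} not present in mask")
    articular = np.zeros(mask.labels.shape, dtype=bool)
    bone = np.zeros(mask.labels.shape, dtype=bool)
    for s in range(mask.labels.shape[0]):
        sl = mask.labels[s]
        if not (sl == region).any():
            continue
        articular[s] = _adjacent_to(sl, region, BACKGROUND)
        bone[s] = _adjacent_to(sl, region, BONE)
    if not articular.any():
        raise ValueError(f"region {region}: no articular (background-facing) boundary")
    if not bone.any():
        raise ValueError(f"region {region}: no bone-cartilage interface")
    return articular, bone


def _boundary_distances(
    mask: CartilageMask, region: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel in-plane distances (mm) to the nearest articular and bone
    boundary voxel, NaN outside the region.  Distances are measured within
    each slice against that slice's boundary members."""
    articular, bone = boundary_sets(mask, region)
    s_mm = mask.grid.pixel_size
    d_art = np.full(mask.labels.shape, np.nan)
    d_bone = np.full(mask.labels.shape, np.nan)
    for s in range(mask.labels.shape[0]):
        core = mask.labels[s] == region
        if not core.any():
            continue
        pts = np.argwhere(core) * s_mm
        for boundary, out in ((articular[s], d_art), (bone[s], d_bone)):
            b = np.argwhere(boundary)
            if b.size == 0:
                raise ValueError(
                    f"region {region}, slice {s}: boundary set empty in-plane"
                )
            dist, _ = cKDTree(b * s_mm).query(pts)
            out[s][core] = dist
    return d_art, d_bone


def laminar_split(mask: CartilageMask, region: int) -> LaminarMask:
    """Split one cartilage region into superficial and deep laminae.

    Superficial iff the distance to the articular surface is <= the
    distance to the bone-cartilage interface; the two laminae partition
    the region's voxels exactly.
    """
    d_art, d_bone = _boundary_distances(mask, region)
    core = mask.labels == region
    codes = np.zeros(mask.labels.shape, dtype=np.int8)
    codes[core & (d_art <= d_bone)] = LAMINA_SUPERFICIAL
    codes[core & (d_art > d_bone)] = LAMINA_DEEP
    regions = np.where(core, mask.labels, 0).astype(mask.labels.dtype)
    return LaminarMask(codes=codes, regions=regions, grid=mask.grid)


def split_all_regions(mask: CartilageMask) -> LaminarMask:
    """Laminar split of every region present, merged into one volume."""
    codes = np.zeros(mask.labels.shape, dtype=np.int8)
    regions = np.zeros_like(mask.labels)
    for region in mask.regions:
        lam = laminar_split(mask, region)
        sel = lam.regions == region
        codes[sel] = lam.codes[sel]
        regions[sel] = region
    return LaminarMask(codes=codes, regions=regions, grid=mask.grid)


def select_loadbearing_slices(
    n_slices_total: int, central_slice: int, n_slices: int
) -> range:
    """The ``n_slices`` consecutive slice indices centred on the landmark
    central slice (0-based, inclusive).  ``n_slices`` must be odd and the
    range must fit the volume."""
    if n_slices < 1 or n_slices % 2 == 0:
        raise ValueError("slice count must be a positive odd number")
    half = n_slices // 2
    first, last = central_slice - half, central_slice + half
    if first < 0 or last >= n_slices_total:
        raise ValueError(
            f"slice range [{first}, {last}] exceeds volume of {n_slices_total} slices"
        )
    return range(first, last + 1)


def resample_mask(mask: CartilageMask, target_grid: Grid, target_shape: tuple[int, int, int]) -> CartilageMask:
    """Nearest-neighbour label resampling onto another voxel grid.

    Each target voxel centre is mapped to world coordinates through the
    target affine and back into source voxel space through the inverse
    source affine; the nearest source voxel's label is copied.  Labels are
    never interpolated.  Voxels mapping outside the source volume become
    background.
    """
    try:
        src_inv = np.linalg.inv(mask.grid.affine)
    except np.linalg.LinAlgError as exc:
        raise ValueError("source affine is singular") from exc
    if abs(np.linalg.det(target_grid.affine)) < 1e-300:
        raise ValueError("target affine is singular")

    voxel_map = src_inv @ target_grid.affine  # target voxel -> source voxel
    idx = np.indices(target_shape, dtype=float).reshape(3, -1)
    src_coords = voxel_map[:3, :3] @ idx + voxel_map[:3, 3:4]
    out = map_coordinates(
        mask.labels.astype(np.int32),
        src_coords,
        order=0,
        mode="grid-constant",
        cval=BACKGROUND,
    ).reshape(target_shape)
    return CartilageMask(
        out.astype(mask.labels.dtype), target_grid, dict(mask.region_names)
    )


def regional_thickness(
    mask: CartilageMask, region: int, slices: range | None = None
) -> ThicknessSummary:
    """Mean cartilage thickness (mm) of a region over a slice range.

    Local thickness at a voxel is ``d_art + d_bone + s``, the sum of the
    in-plane distances to the two surfaces plus one pixel size — exact on
    slabs of any integer thickness (``k`` voxels measure ``k*s``) and
    requiring no surface meshing.  The regional value is the mean over the
    region's voxels in the slice range.
    """
    if slices is None:
        slices = range(mask.labels.shape[0])
    sel = np.zeros(mask.labels.shape, dtype=bool)
    sel[list(slices)] = True
    core = (mask.labels == region) & sel
    if not core.any():
        raise ValueError(f"region {region} empty on slices {list(slices)}")

    # distances are in-plane, so slices outside the range cannot influence them
    d_art, d_bone = _boundary_distances(mask, region)
    t = d_art[core] + d_bone[core] + mask.grid.pixel_size
    return ThicknessSummary(
        region=int(region),
        slices=(min(slices), max(slices)),
        mean_thickness=float(t.mean()),
        n_voxels=int(core.sum()),
    )
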