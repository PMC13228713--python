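"""Core in-memory containers for image volumes, masks and parametric maps.

Arrays are indexed ``(slice, row, col)`` (sagittal slices along axis 0);
echo series add a leading echo axis. World coordinates are millimetres and
are reached through a 4x4 affine mapping homogeneous voxel indices
``(slice, row, col, 1)`` to world space, following the NIfTI convention as
exposed by nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reserved labels in cartilage masks.  Region ids start at 2.
BACKGROUND = 0
BONE = 1

#: Default label dictionary for the six load-bearing cartilage regions.
REGION_NAMES: dict[int, str] = {
    2: "medial_femur",
    3: "medial_tibia",
    4: "lateral_femur",
    5: "lateral_tibia",
    6: "patella",
    7: "trochlea",
}

#: Laminar codes used by :class:`LaminarMask`.
LAMINA_NONE = 0
LAMINA_SUPERFICIAL = 1
LAMINA_DEEP = 2


@dataclass(frozen=True)
class Grid:
    """Voxel grid geometry: in-plane pixel size, slice thickness, affine.

    Parameters
    ----------
    pixel_size : float
        In-plane pixel edge length in mm (isotropic within a slice).
    slice_thickness : float
        Slice-to-slice spacing in mm.
    affine : ndarray, optional
        4x4 voxel-to-world transform.  Defaults to a diagonal scaling by
        ``(slice_thickness, pixel_size, pixel_size)``.
    """

    pixel_size: float
    slice_thickness: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.slice_thickness <= 0:
            raise ValueError("pixel size and slice thickness must be positive")
        if self.affine is None:
            aff = np.diag([self.slice_thickness, self.pixel_size, self.pixel_size, 1.0])
            object.__setattr__(self, "affine", aff)
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            object.__setattr__(self, "affine", aff)

    def with_pixel_size(self, pixel_size: float) -> "Grid":
        """Return a grid rescaled in-plane, keeping voxel-edge alignment.

        The new grid shares the outer edge of voxel (.., 0, 0) with the
        old one, so an integer refinement maps every source voxel onto an
        exact block of finer voxels."""
        aff = self.affine.copy()
        scale = pixel_size / self.pixel_size
        for ax in (1, 2):
            aff[:3, 3] += 0.5 * (scale - 1.0) * aff[:3, ax]
            aff[:3, ax] *= scale
        return Grid(pixel_size, self.slice_thickness, aff)


@dataclass
class EchoSeries:
    """A multi-echo image stack: one volume per echo time.

    ``data`` has shape ``(n_echoes, n_slices, n_rows, n_cols)`` in arbitrary
    intensity units; ``echo_times`` are in ms, strictly increasing.
    """

    data: np.ndarray
    echo_times: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("echo data must be 4-D (echo, slice, row, col)")
        if self.echo_times.ndim != 1 or len(self.echo_times) != self.data.shape[0]:
            raise ValueError("one echo time per echo volume is required")
        if np.any(self.echo_times <= 0) or np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape (slices, rows, cols)."""
        return self.data.shape[1:]


@dataclass
class CartilageMask:
    """Integer label volume: 0 background, 1 bone, >=2 cartilage regions."""

    labels: np.ndarray
    grid: Grid
    region_names: dict[int, str] = field(default_factory=lambda: dict(REGION_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("mask must be 3-D (slice, row, col)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integer")

    @property
    def regions(self) -> list[int]:
        """Region ids actually present in the volume, sorted."""
        present = np.unique(self.labels)
        return [int(r) for r in present if r >= 2]

    def region_mask(self, region: int) -> np.ndarray:
        return self.labels == region

    @property
    def cartilage(self) -> np.ndarray:
        return self.labels >= 2


@dataclass
class LaminarMask:
    """Per-voxel laminar code on cartilage voxels, with region ids carried.

    ``codes`` is 0 outside cartilage, 1 for superficial, 2 for deep;
    ``regions`` repeats the cartilage region label so downstream
    aggregation can group by (region, lamina) without the source mask.
    """

    codes: np.ndarray
    regions: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        if self.codes.shape != self.regions.shape:
            raise ValueError("codes and regions must share a shape")
        on_cart = self.regions >= 2
        if np.any((self.codes != LAMINA_NONE) & ~on_cart):
            raise ValueError("laminar codes defined outside cartilage voxels")

    def lamina_mask(self, region: int, code: int) -> np.ndarray:
        return (self.regions == region) & (self.codes == code)


@dataclass
class T2Map:
    """Fitted per-voxel T2 (ms) and proton density with validity flags.

    Invalid voxels carry NaN in ``t2``/``pd`` and False in ``valid``; all
    downstream means exclude them.
    """

    t2: np.ndarray
    pd: np.ndarray
    rss: np.ndarray
    valid: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        shapes = {self.t2.shape, self.pd.shape, self.rss.shape, self.valid.shape}
        if len(shapes) != 1:
            raise ValueError("t2/pd/rss/valid must share a shape")


def same_grid(a: Grid, b: Grid, atol: float = 1e-9) -> bool:
    return (
        abs(a.pixel_size - b.pixel_size) <= atol
        and abs(a.slice_thickness - b.slice_thickness) <= atol
        and np.allclose(a.affine, b.affine, atol=atol)
    )
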