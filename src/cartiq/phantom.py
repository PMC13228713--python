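"""Multi-echo knee-like phantoms with known ground truth.

The phantom stands in for a scanned knee: a bone disc with a cartilage
shell over part of its circumference, surrounded by background (synovial
space).  The shell carries a two-layer T2 structure — a superficial layer
facing the articular surface and a deep layer facing the bone–cartilage
interface — so that laminar splitting, relaxometry and thickness
measurement can all be validated against analytic truth.  A slab layout
(flat cartilage plate on flat bone) is available for cases where exact
voxel-counting symmetry is wanted.

The forward signal model is the mono-exponential spin-echo decay
``S(TE) = PD * exp(-TE / T2)``.  The first echo of a multi-echo spin-echo
train is contaminated by stimulated echoes in practice; this is modelled
as a multiplicative inflation ``alpha >= 1`` applied to echo 1 only, which
gives the first-echo-exclusion rule of the fitting stage a measurable
consequence.  Noise is Rician: the magnitude of the true signal perturbed
by complex Gaussian noise of scale ``sigma`` per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import (
    BACKGROUND,
    BONE,
    LAMINA_DEEP,
    LAMINA_NONE,
    LAMINA_SUPERFICIAL,
    CartilageMask,
    EchoSeries,
    Grid,
)

#: Echo times (ms) of a seven-echo sagittal 2D MESE T2-mapping protocol.
DEFAULT_ECHO_TIMES: tuple[float, ...] = (11.1, 22.2, 33.3, 44.4, 55.5, 66.6, 77.7)


def signal_model(
    pd: float | np.ndarray,
    t2: float | np.ndarray,
    te: float | np.ndarray,
    alpha: float = 1.0,
    echo_index: int = 2,
) -> float | np.ndarray:
    """Mono-exponential spin-echo signal ``PD * exp(-TE/T2)``.

    Parameters
    ----------
    pd : float or ndarray
        Proton density (signal amplitude at TE=0), >= 0.
    t2 : float or ndarray
        Transverse relaxation time in ms, > 0.
    te : float or ndarray
        Echo time in ms, >= 0.
    alpha : float
        Stimulated-echo inflation factor applied when ``echo_index == 1``.
    echo_index : int
        1-based position of the echo in the train; only the first echo is
        inflated.

    Returns
    -------
    Signal intensity in the units of ``pd``.
    """
    pd = np.asarray(pd, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    te = np.asarray(te, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be positive")
    if np.any(pd < 0):
        raise ValueError("PD must be non-negative")
    if np.any(te < 0):
        raise ValueError("TE must be non-negative")
    s = pd * np.exp(-te / t2)
    if echo_index == 1:
        s = alpha * s
    return s if s.ndim else float(s)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue and acquisition parameters of a synthetic phantom.

    Defaults describe a small sagittal stack: 0.365 mm in-plane pixels,
    3 mm slices, a 2.19 mm cartilage shell (6 pixels) over an 18-pixel
    bone disc, superficial/deep T2 of 52/39 ms — the order of magnitude of
    load-bearing knee cartilage at 3 T.
    """

    shape: tuple[int, int, int] = (9, 64, 64)
    pixel_size: float = 0.365  # mm in-plane
    slice_thickness: float = 3.0  # mm
    bone_center: tuple[float, float] = (40.0, 31.5)  # (row, col) voxels
    bone_radius: float = 18.0  # voxels
    shell_thickness: float = 2.19  # mm
    region_ids: tuple[int, ...] = (2,)
    t2_superficial: float = 52.0  # ms
    t2_deep: float = 39.0  # ms
    pd: float = 800.0  # arbitrary intensity units
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    alpha: float = 1.0  # first-echo inflation, >= 1
    sigma: float = 0.0  # Rician noise scale, intensity units
    geometry: str = "annulus"  # "annulus" | "slab"
    arc: tuple[float, float] = (200.0, 340.0)  # degrees, annulus only

    def validate(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 2 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.shell_thickness <= 0:
            raise ValueError("shell thickness must be positive")
        if self.t2_superficial <= 0 or self.t2_deep <= 0:
            raise ValueError("T2 values must be positive")
        if self.pd <= 0:
            raise ValueError("PD must be positive")
        if self.alpha < 1:
            raise ValueError("first-echo inflation alpha must be >= 1")
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.geometry not in ("annulus", "slab"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if len(self.region_ids) < 1 or any(r < 2 for r in self.region_ids):
            raise ValueError("region ids must be >= 2 and at least one is required")
        if self.shell_thickness < self.pixel_size:
            raise ValueError("cartilage shell thinner than one voxel")

    @property
    def shell_voxels(self) -> int:
        """Shell thickness in whole voxels (used by the slab layout)."""
        return int(round(self.shell_thickness / self.pixel_size))

    @property
    def grid(self) -> Grid:
        return Grid(self.pixel_size, self.slice_thickness)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom.

    ``t2`` is NaN outside cartilage; ``laminar`` uses the laminar codes of
    :mod:`cartiq.images` and is defined exactly on cartilage voxels;
    ``thickness`` maps region id to the true shell thickness in mm.
    """

    t2: np.ndarray
    laminar: np.ndarray
    thickness: dict[int, float]
    bone_mask: np.ndarray
    background_mask: np.ndarray


def _annulus_layout(spec: PhantomSpec) -> np.ndarray:
    """One slice of the annular-arc layout: bone disc, cartilage shell."""
    _, n_rows, n_cols = spec.shape
    r0, c0 = spec.bone_center
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    radius = np.hypot(rows - r0, cols - c0)
    shell_vox = spec.shell_thickness / spec.pixel_size
    outer = spec.bone_radius + shell_vox

    labels = np.zeros((n_rows, n_cols), dtype=np.int16)
    labels[radius <= spec.bone_radius] = BONE

    theta = np.degrees(np.arctan2(rows - r0, cols - c0)) % 360.0
    lo, hi = spec.arc
    in_arc = (theta >= lo) & (theta < hi) if lo <= hi else (theta >= lo) | (theta < hi)
    shell = (radius > spec.bone_radius) & (radius <= outer) & in_arc

    # Angular sectors assign region ids.
    span = (hi - lo) % 360.0 or 360.0
    rel = (theta - lo) % 360.0
    n_regions = len(spec.region_ids)
    sector = np.minimum((rel / span * n_regions).astype(int), n_regions - 1)
    for k, rid in enumerate(spec.region_ids):
        labels[shell & (sector == k)] = rid
    return labels


def _slab_layout(spec: PhantomSpec) -> np.ndarray:
    """Flat cartilage plate spanning the full width: background above,
    bone below, regions split by column.  Spanning the width keeps the
    lateral edges off the articular boundary (out-of-volume neighbours
    count as neither background nor bone)."""
    _, n_rows, n_cols = spec.shape
    k = spec.shell_voxels
    bone_top = 2 * n_rows // 3
    cart_top = bone_top - k
    if cart_top < 1:
        raise ValueError("slab shell does not fit the grid")
    labels = np.zeros((n_rows, n_cols), dtype=np.int16)
    labels[bone_top:, :] = BONE
    n_regions = len(spec.region_ids)
    edges = (np.arange(n_regions + 1) * n_cols) // n_regions
    for i, rid in enumerate(spec.region_ids):
        labels[cart_top:bone_top, edges[i] : edges[i + 1]] = rid
    return labels


def generate_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[EchoSeries, CartilageMask, PhantomTruth]:
    """Generate a multi-echo phantom, its label mask and its ground truth.

    Echo volumes equal :func:`signal_model` at each voxel's true (PD, T2),
    with the first-echo inflation applied, plus Rician noise of scale
    ``spec.sigma``.  Background and bone have zero true signal; their
    measured intensity is pure noise magnitude.

    A seed is mandatory: reproducibility is part of the contract, and two
    calls with the same spec and seed return bit-identical volumes.
    """
    spec.validate()
    if seed is None:
        raise ValueError("a seed is required for reproducible phantom generation")

    layout = _slab_layout if spec.geometry == "slab" else _annulus_layout
    labels2d = layout(spec)
    labels = np.broadcast_to(labels2d, spec.shape).copy()
    cart = labels >= 2
    if not cart.any():
        raise ValueError("phantom geometry produced no cartilage voxels")

    # Laminar truth follows the equidistance rule: a cartilage voxel is
    # superficial iff its in-plane distance to the articular boundary does
    # not exceed its distance to the bone-cartilage interface.  Computed
    # on one slice (the layout is constant along the stack) and broadcast.
    from .geometry import split_all_regions

    one_slice = CartilageMask(labels2d[None, :, :], spec.grid)
    laminar2d = split_all_regions(one_slice).codes[0]
    laminar = np.broadcast_to(laminar2d, spec.shape).copy().astype(np.int8)
    laminar[~cart] = LAMINA_NONE

    true_t2 = np.full(spec.shape, np.nan)
    true_t2[laminar == LAMINA_SUPERFICIAL] = spec.t2_superficial
    true_t2[laminar == LAMINA_DEEP] = spec.t2_deep

    te = np.asarray(spec.echo_times, dtype=float)
    data = np.zeros((te.size, *spec.shape))
    t2_filled = np.where(cart, true_t2, 1.0)  # placeholder where PD is 0
    pd_map = np.where(cart, spec.pd, 0.0)
    for k, t in enumerate(te):
        data[k] = signal_model(pd_map, t2_filled, t, spec.alpha, echo_index=k + 1)

    if spec.sigma > 0:
        rng = np.random.default_rng(seed)
        re = rng.normal(0.0, spec.sigma, size=data.shape)
        im = rng.normal(0.0, spec.sigma, size=data.shape)
        data = np.hypot(data + re, im)

    thickness = {
        rid: (
            spec.shell_voxels * spec.pixel_size
            if spec.geometry == "slab"
            else spec.shell_thickness
        )
        for rid in spec.region_ids
    }
    truth = PhantomTruth(
        t2=true_t2,
        laminar=laminar,
        thickness=thickness,
        bone_mask=labels == BONE,
        background_mask=labels == BACKGROUND,
    )
    series = EchoSeries(data, te, spec.grid)
    mask = CartilageMask(labels, spec.grid)
    return series, mask, truth
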