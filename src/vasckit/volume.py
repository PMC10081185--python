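"""Voxel-level operators: filtering, region growing, distance transforms and
centreline-normal cross-sections.

All operators work on :class:`~vasckit.graph.VoxelVolume` rasters indexed
(z, y, x) with isotropic voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .graph import VoxelVolume

__all__ = [
    "CrossSection",
    "median_filter_3d",
    "region_grow",
    "distance_transform",
    "extract_cross_section",
    "perimeter_of_component",
]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def median_filter_3d(vol: VoxelVolume, iterations: int = 2, neighbourhood: int = 26) -> VoxelVolume:
    """Iterated 3D median filter (neighbourhood includes the voxel itself).

    The 26-neighbourhood is the full 3x3x3 box; the 6-neighbourhood is the
    face-adjacent cross.  Borders replicate the edge voxel.
    """
    if np.asarray(vol.data).dtype == bool or vol.data.ndim != 3:
        raise ValueError("median filter expects a scalar 3D volume")
    footprint = _structure(neighbourhood)
    out = vol.data
    for _ in range(iterations):
        out = ndimage.median_filter(out, footprint=footprint, mode="nearest")
    return VoxelVolume(data=out, voxel_size=vol.voxel_size, origin=vol.origin)


def region_grow(
    vol: VoxelVolume,
    seeds: list[tuple[int, int, int]],
    intensity_range: tuple[float, float],
    connectivity: int = 26,
) -> VoxelVolume:
    """Seeded region growing: voxels connected to a seed within [lo, hi]."""
    lo, hi = intensity_range
    if lo > hi:
        raise ValueError(f"empty intensity range [{lo}, {hi}]")
    within = (vol.data >= lo) & (vol.data <= hi)
    labels, _ = ndimage.label(within, structure=_structure(connectivity))
    keep = set()
    for seed in seeds:
        seed = tuple(int(v) for v in seed)
        if any(s < 0 or s >= n for s, n in zip(seed, vol.data.shape)):
            raise ValueError(f"seed {seed} outside the grid")
        if not within[seed]:
            raise ValueError(f"seed {seed} intensity {vol.data[seed]} outside [{lo}, {hi}]")
        keep.add(labels[seed])
    mask = np.isin(labels, sorted(keep))
    return VoxelVolume(data=mask, voxel_size=vol.voxel_size, origin=vol.origin)


def distance_transform(mask: VoxelVolume) -> VoxelVolume:
    """Euclidean distance (μm) of every voxel to the nearest foreground voxel."""
    fg = np.asarray(mask.data) != 0
    if not fg.any():
        raise ValueError("distance transform of an empty mask")
    dist = ndimage.distance_transform_edt(~fg, sampling=mask.voxel_size)
    return VoxelVolume(data=dist, voxel_size=mask.voxel_size, origin=mask.origin)


@dataclass
class CrossSection:
    """2D plane sample through a volume, normal to a centreline tangent.

    ``image[j, i]`` is the sample at world position
    ``origin + offsets_u[i] * axis_u + offsets_v[j] * axis_v``.
    """

    image: np.ndarray
    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    spacing: float

    @property
    def center_index(self) -> tuple[int, int]:
        return (self.image.shape[0] // 2, self.image.shape[1] // 2)


def plane_axes(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane axes for a plane normal.

    The world axis with the smallest |tangent| component is crossed with the
    tangent to give the first axis; the second completes the right-handed
    frame.  This makes cross-sections reproducible bit-for-bit.
    """
    t = np.asarray(tangent, dtype=float)
    norm = np.linalg.norm(t)
    if norm == 0:
        raise ValueError("zero tangent vector")
    t = t / norm
    e = np.zeros(3)
    e[int(np.argmin(np.abs(t)))] = 1.0
    u = np.cross(e, t)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def extract_cross_section(
    vol: VoxelVolume,
    point: np.ndarray,
    tangent: np.ndarray,
    half_width: float,
    spacing: float,
) -> CrossSection:
    """Sample the plane through ``point`` with normal ``tangent``.

    Scalar volumes are sampled with trilinear interpolation; binary and
    integer-label volumes with nearest-neighbour, so sections stay crisp for
    contour extraction.  Samples outside the grid read as 0.
    """
    point = np.asarray(point, dtype=float)
    u, v = plane_axes(tangent)
    offs = np.arange(-half_width, half_width + spacing / 2, spacing)
    uu, vv = np.meshgrid(offs, offs, indexing="xy")
    world = point[None, None, :] + uu[..., None] * u[None, None, :] + vv[..., None] * v[None, None, :]
    zyx = vol.world_to_index(world.reshape(-1, 3)).T  # (3, n) in (z, y, x)
    inside = np.all((zyx >= -0.5) & (zyx <= np.array(vol.data.shape)[:, None] - 0.5), axis=0)
    if not inside.any():
        raise ValueError("cross-section window lies fully outside the grid")
    data = np.asarray(vol.data)
    crisp = data.dtype == bool or np.issubdtype(data.dtype, np.integer)
    img = ndimage.map_coordinates(
        data.astype(float), zyx, order=0 if crisp else 1, mode="constant", cval=0.0
    ).reshape(uu.shape)
    return CrossSection(image=img, origin=point, axis_u=u, axis_v=v, spacing=spacing)


#: Marching-squares contour length of an isolated single pixel, in pixels.
SINGLE_PIXEL_CONTOUR = 2.0 * np.sqrt(2.0)


def perimeter_of_component(section: CrossSection, hint: tuple[float, float] | None = None,
                           smooth_sigma: float = 0.8) -> float:
    """Perimeter (μm) of the hinted foreground component of a cross-section.

    ``hint`` is an in-plane (u, v) offset in μm from the plane origin; the
    default is the plane origin itself (the projected centreline point).  The
    boundary is the sub-pixel marching-squares iso-contour at level 0.5 of
    the component mollified by a Gaussian of ``smooth_sigma`` pixels, which
    removes the staircase bias of binary digitization (raw binary contours
    overestimate a disc's circumference by ~6%; mollified ones are within
    ~2% for discs, squares and ellipses a few pixels across or larger).
    Components too small to survive mollification fall back to the raw
    binary contour; an isolated pixel therefore measures
    ``2*sqrt(2)*spacing``.
    """
    fg = section.image > 0.5
    if hint is None:
        hint = (0.0, 0.0)
    n_rows, n_cols = fg.shape
    # offsets run symmetrically about the plane origin
    i = int(round(hint[0] / section.spacing)) + n_cols // 2
    j = int(round(hint[1] / section.spacing)) + n_rows // 2
    if not (0 <= j < n_rows and 0 <= i < n_cols) or not fg[j, i]:
        raise ValueError("hint does not fall on a foreground pixel")
    labels = measure.label(fg, connectivity=2)
    comp = (labels == labels[j, i]).astype(float)
    field = ndimage.gaussian_filter(np.pad(comp, 2), smooth_sigma) if smooth_sigma > 0 else np.pad(comp, 2)
    if field.max() < 0.5:  # component too small for the mollified contour
        field = np.pad(comp, 2)
    total = 0.0
    for contour in measure.find_contours(field, 0.5):
        total += float(np.linalg.norm(np.diff(contour, axis=0), axis=1).sum())
    return total * section.spacing
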