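"""Per-slice and per-segment geometry of tubular masks.

Centroid paths and total length
-------------------------------
The length of a segment is the polyline length through its per-slice
centroids: for coronal slices k_1..k_n with in-plane centroids c_i, the
total length is

    TL = sum_i D_i,      D_i = ||c_{i+1} - c_i||  (full 3-D Euclidean step)

so D_i includes the in-plane drift of the nerve between slices, not just
the axial pitch.

Cross-sectional shape
---------------------
CSA is the set-voxel count times the pixel area. The ellipticity index

    epsilon = (h1 - h2) / h1,   h1 >= h2

uses the hemi-axes of the equivalent ellipse of the in-plane second
central moments: a filled ellipse with hemi-axes (a, b) has coordinate
variances (a^2/4, b^2/4), so h = 2 sqrt(lambda) for the eigenvalues
lambda_1 >= lambda_2 of the slice's coordinate covariance. The covariance
is pixel-broadened (voxel-center covariance plus the uniform per-pixel
term s^2/12, i.e. the exact covariance of the union of pixel squares):
this removes the discretization bias of bare voxel centers and keeps
epsilon in [0, 1) even for degenerate (single-voxel or collinear) slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mask_io import LabeledMask

log = logging.getLogger("avpnorm")


class GeometryError(ValueError):
    """Raised for empty or non-contiguous inputs."""


# ---------------------------------------------------------------------------
# Slice-level primitives


def slice_centroid(slice_2d: np.ndarray, spacing: tuple[float, float]) -> tuple[float, float]:
    """Centroid of a 2-D binary slice in mm (mean of set-voxel centers)."""
    coords = np.argwhere(slice_2d)
    if coords.size == 0:
        raise GeometryError("slice_centroid: empty slice")
    cx, cz = coords.mean(axis=0)
    return float(cx * spacing[0]), float(cz * spacing[1])


def slice_csa(slice_2d: np.ndarray, spacing: tuple[float, float]) -> float:
    """Cross-sectional area in mm^2 = set-voxel count x pixel area."""
    return float(np.count_nonzero(slice_2d) * spacing[0] * spacing[1])


@dataclass
class SliceShape:
    """Equivalent-ellipse description of one coronal cross-section."""

    csa: float  # mm^2
    h1: float  # major hemi-axis, mm
    h2: float  # minor hemi-axis, mm
    epsilon: float  # (h1 - h2) / h1, in [0, 1)
    n_voxels: int


def slice_shape(slice_2d: np.ndarray, spacing: tuple[float, float]) -> SliceShape:
    """CSA, equivalent-ellipse hemi-axes and ellipticity of one slice.

    Multiple connected components are measured over their union (the
    nerve cross-section may fragment at segment boundaries); a debug
    message is logged when that happens.
    """
    coords = np.argwhere(slice_2d).astype(float)
    n = coords.shape[0]
    if n == 0:
        raise GeometryError("slice_shape: empty slice")
    if n >= 2:
        n_comp = ndimage.label(slice_2d)[1]
        if n_comp > 1:
            log.debug("slice_shape: %d connected components, measuring their union", n_comp)
    coords *= np.asarray(spacing)
    cov = np.zeros((2, 2))
    if n > 1:
        cov = np.cov(coords, rowvar=False, ddof=0)
    # pixel-broadening: each voxel is a uniform square, variance s^2/12
    cov += np.diag([spacing[0] ** 2 / 12.0, spacing[1] ** 2 / 12.0])
    lam = np.linalg.eigvalsh(cov)  # ascending
    h2, h1 = 2.0 * np.sqrt(np.maximum(lam, 0.0))
    eps = float((h1 - h2) / h1) if h1 > 0 else 0.0
    return SliceShape(
        csa=slice_csa(slice_2d, spacing), h1=float(h1), h2=float(h2),
        epsilon=eps, n_voxels=int(n),
    )


# ---------------------------------------------------------------------------
# Centroid paths


@dataclass
class CentroidPath:
    """Ordered per-slice centroids of one segment and the derived length.

    ``slice_indices`` are coronal (y) indices, anterior first;
    ``centroids_mm`` holds (cx, y_mm, cz) world coordinates per slice;
    ``distances_mm`` the 3-D Euclidean steps D_i between consecutive
    centroids; ``tl_mm`` their sum.
    """

    segment: str
    slice_indices: np.ndarray
    centroids_mm: np.ndarray  # (n, 3): x, y, z in mm
    csa_mm2: np.ndarray
    distances_mm: np.ndarray  # (n - 1,)
    tl_mm: float
    spacing: tuple[float, float, float] = (0.6, 0.6, 0.6)

    @property
    def n_slices(self) -> int:
        return len(self.slice_indices)

    @property
    def n_gaps(self) -> int:
        return len(self.distances_mm)


def centroid_path(mask: LabeledMask) -> CentroidPath:
    """Per-slice centroids, inter-centroid distances and total length.

    The mask must be nonempty and contiguous along y (every slice between
    the first and last nonempty coronal slice nonempty).
    """
    sx, sy, sz = mask.spacing
    y0, y1 = mask.y_extent()  # raises on empty
    ks, cents, csas = [], [], []
    for k in range(y0, y1 + 1):
        sl = mask.coronal_slice(k)
        if not sl.any():
            raise GeometryError(
                f"{mask.subject_id}/{mask.side}/{mask.segment}: "
                f"empty intermediate slice y={k} (non-contiguous mask)"
            )
        cx, cz = slice_centroid(sl, (sx, sz))
        ks.append(k)
        cents.append((cx, k * sy, cz))
        csas.append(slice_csa(sl, (sx, sz)))
    cents = np.asarray(cents, dtype=float)
    dists = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    return CentroidPath(
        segment=mask.segment,
        slice_indices=np.asarray(ks),
        centroids_mm=cents,
        csa_mm2=np.asarray(csas),
        distances_mm=dists,
        tl_mm=float(dists.sum()),
        spacing=mask.spacing,
    )


# ---------------------------------------------------------------------------
# Segment biometrics


@dataclass
class BiometryRecord:
    """Volume, length, mean CSA and ellipticity of one segment and side."""

    subject_id: str
    side: str
    segment: str
    volume_mm3: float
    length_mm: float
    mcsa_mm2: float
    epsilon: float
    n_slices: int = 0

    def as_dict(self) -> dict:
        return {
            "subject": self.subject_id,
            "side": self.side,
            "segment": self.segment,
            "volume_mm3": self.volume_mm3,
            "length_mm": self.length_mm,
            "mcsa_mm2": self.mcsa_mm2,
            "epsilon": self.epsilon,
        }


#: slices with fewer voxels than this are moment-degenerate and excluded
#: from the segment ellipticity mean
MIN_VOXELS_FOR_EPSILON = 3


def segment_biometrics(mask: LabeledMask) -> BiometryRecord:
    """Geometrically unbiased biometrics of one segment mask.

    * volume = voxel count x voxel volume,
    * length = centroid-path total length TL,
    * mCSA = volume / length (the spinal-cord convention),
    * epsilon = unweighted mean of per-slice ellipticity over slices with
      at least :data:`MIN_VOXELS_FOR_EPSILON` voxels.

    A single-slice segment has TL = 0 and therefore undefined mCSA; this
    is signalled as an error.
    """
    sx, sy, sz = mask.spacing
    volume = mask.voxel_count * mask.voxel_volume_mm3
    path = centroid_path(mask)
    if path.tl_mm == 0.0:
        raise GeometryError(
            f"{mask.subject_id}/{mask.side}/{mask.segment}: single-slice segment, "
            "zero centroid-path length (mCSA undefined)"
        )
    eps_vals = []
    for k in path.slice_indices:
        sl = mask.coronal_slice(int(k))
        if np.count_nonzero(sl) >= MIN_VOXELS_FOR_EPSILON:
            eps_vals.append(slice_shape(sl, (sx, sz)).epsilon)
    epsilon = float(np.mean(eps_vals)) if eps_vals else float("nan")
    return BiometryRecord(
        subject_id=mask.subject_id,
        side=mask.side,
        segment=mask.segment,
        volume_mm3=float(volume),
        length_mm=path.tl_mm,
        mcsa_mm2=float(volume / path.tl_mm),
        epsilon=epsilon,
        n_slices=path.n_slices,
    )
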