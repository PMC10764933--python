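"""Straightening of segment masks by slice-wise centroid alignment.

Each coronal slice's in-plane pattern is translated (by a whole number of
voxels, never resampled) so that its centroid sits on the grid centerline;
the cross-sectional area of every slice is therefore preserved exactly.
Translating the slices shortens the centroid polyline to the plain axial
pitch, so the axial dimension is rebuilt at a fine pitch of 0.06 mm (one
tenth of the acquisition slice thickness): each inter-centroid gap D_i is
replaced by n_i = round(D_i / 0.06) fine slices, each a replica of the
nearer of the two flanking source slices. The straightened length
(fine-slice count x 0.06 mm) then equals the original TL to within half a
fine slice per gap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CentroidPath, GeometryError, centroid_path
from .mask_io import SEGMENTS, LabeledMask, write_mask

log = logging.getLogger("avpnorm")

#: fine axial pitch in mm: one tenth of the 0.6 mm acquisition slice pitch
FINE_PITCH = 0.06
#: default working in-plane grid (x, z) in voxels at 0.6 mm — padded so no
#: cohort slice is clipped after shifting to the centerline
DEFAULT_PLANE_DIMS = (64, 64)


class StraightenError(ValueError):
    """Raised when a slice pattern cannot be placed on the working grid."""


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reproducible)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Slice centering


def center_shift(
    slice_2d: np.ndarray,
    grid_dims: tuple[int, int] | None = None,
    spacing: tuple[float, float] = (0.6, 0.6),
) -> tuple[np.ndarray, tuple[float, float]]:
    """Translate a slice pattern to the center of the working grid.

    The pattern is moved by the integer voxel offset nearest to
    (center - centroid), where the grid center is the voxel-coordinate
    midline ((N-1)/2 per axis, so that a left-right mirror flip maps the
    centerline onto itself). Returns the shifted pattern on a grid of
    ``grid_dims`` and the residual sub-voxel centroid offset in mm (below
    half a voxel per axis by construction).

    Raises :class:`StraightenError` if the shifted pattern would be
    clipped at the border — the working grid is undersized.
    """
    coords = np.argwhere(slice_2d)
    if coords.size == 0:
        raise GeometryError("center_shift: empty slice")
    if grid_dims is None:
        grid_dims = slice_2d.shape
    nx, nz = grid_dims
    center = np.array([(nx - 1) / 2.0, (nz - 1) / 2.0])
    centroid = coords.mean(axis=0)
    shift = np.array([round_half_away(v) for v in center - centroid])
    new_coords = coords + shift
    if (new_coords < 0).any() or (new_coords[:, 0] >= nx).any() or (new_coords[:, 1] >= nz).any():
        raise StraightenError(
            f"pattern clipped after centering shift {tuple(shift)} on grid {grid_dims}; "
            "increase the working in-plane grid"
        )
    out = np.zeros((nx, nz), dtype=bool)
    out[new_coords[:, 0], new_coords[:, 1]] = True
    residual = (center - (centroid + shift)) * np.asarray(spacing)
    return out, (float(residual[0]), float(residual[1]))


# ---------------------------------------------------------------------------
# Sub-slice planning


def plan_subslices(path: CentroidPath, pitch: float = FINE_PITCH) -> np.ndarray:
    """Fine-slice count per centroid gap: n_i = round(D_i / pitch), min 1.

    For the straight 0.6 mm gap this is the ten-fold replication; curved
    gaps get proportionally more replicas so that sum(n_i) * pitch matches
    TL within pitch/2 per gap.
    """
    if pitch <= 0:
        raise ValueError(f"pitch must be positive, got {pitch}")
    if path.n_slices < 2:
        raise GeometryError("plan_subslices: need at least 2 slices")
    return np.array(
        [max(1, round_half_away(d / pitch)) for d in path.distances_mm], dtype=int
    )


# ---------------------------------------------------------------------------
# Straightened volumes


@dataclass
class Gap:
    """One inter-centroid gap of the straightened volume.

    ``src_a``/``src_b`` index the centered source-slice patterns flanking
    the gap (anterior, posterior); ``n_sub`` fine slices are emitted for
    it, the first ceil(n/2) replicating the anterior pattern.
    """

    segment: str
    src_a: int
    src_b: int
    d_mm: float
    n_sub: int

    def sources(self) -> list[int]:
        n_a = (self.n_sub + 1) // 2  # odd middle slice goes to the anterior source
        return [self.src_a] * n_a + [self.src_b] * (self.n_sub - n_a)


@dataclass
class StraightenedVolume:
    """A centerline-aligned fine-pitch rebuild of one or more segments.

    ``patterns`` holds one centered in-plane pattern per original coronal
    slice; ``pattern_meta`` its (segment, source y-index) provenance;
    ``gaps`` the per-gap replication plan. The fine grid and per-fine-slice
    provenance are materialized on demand.
    """

    patterns: list[np.ndarray]
    pattern_meta: list[tuple[str, int]]
    gaps: list[Gap]
    in_plane_spacing: tuple[float, float] = (0.6, 0.6)
    pitch: float = FINE_PITCH
    subject_id: str = ""
    side: str = ""
    residuals_mm: list[tuple[float, float]] = field(default_factory=list)

    @property
    def plane_dims(self) -> tuple[int, int]:
        return self.patterns[0].shape

    @property
    def n_fine(self) -> int:
        return int(sum(g.n_sub for g in self.gaps))

    @property
    def length_mm(self) -> float:
        return self.n_fine * self.pitch

    @property
    def tl_mm(self) -> float:
        return float(sum(g.d_mm for g in self.gaps))

    def source_sequence(self) -> list[int]:
        """Pattern index of every fine slice, anterior to posterior."""
        seq: list[int] = []
        for g in self.gaps:
            seq.extend(g.sources())
        return seq

    def provenance(self) -> list[tuple[str, int]]:
        """(segment, source slice index) for every fine slice."""
        return [self.pattern_meta[i] for i in self.source_sequence()]

    def fine_grid(self) -> np.ndarray:
        """Materialize the (nx, n_fine, nz) boolean fine grid."""
        nx, nz = self.plane_dims
        seq = self.source_sequence()
        grid = np.empty((nx, len(seq), nz), dtype=bool)
        for j, i in enumerate(seq):
            grid[:, j, :] = self.patterns[i]
        return grid

    def segment_boundaries_fine(self) -> dict[str, tuple[int, int]]:
        """Half-open fine-slice index range [start, end) per segment."""
        bounds: dict[str, tuple[int, int]] = {}
        pos = 0
        for g in self.gaps:
            start, _ = bounds.get(g.segment, (pos, pos))
            bounds[g.segment] = (start, pos + g.n_sub)
            pos += g.n_sub
        return bounds

    def fine_slice_counts(self) -> np.ndarray:
        """Set-voxel count of every fine slice (CSA conservation check)."""
        counts = np.array([int(p.sum()) for p in self.patterns])
        return counts[self.source_sequence()]


def straighten_segment(
    mask: LabeledMask,
    plane_dims: tuple[int, int] = DEFAULT_PLANE_DIMS,
    pitch: float = FINE_PITCH,
) -> StraightenedVolume:
    """Straighten one segment mask onto the fine-pitch centerline grid.

    Every fine slice is a center-shifted copy of exactly one source slice
    (the nearer of the two flanking a gap, ties to the anterior one), so
    per-slice CSA is conserved bit-exactly and the multiset of output CSA
    values is a subset of the input's.
    """
    path = centroid_path(mask)
    if path.n_slices < 2:
        raise GeometryError(
            f"{mask.subject_id}/{mask.side}/{mask.segment}: need >= 2 slices to straighten"
        )
    sx, sy, sz = mask.spacing
    patterns, meta, residuals = [], [], []
    for k in path.slice_indices:
        shifted, res = center_shift(mask.coronal_slice(int(k)), plane_dims, (sx, sz))
        patterns.append(shifted)
        meta.append((mask.segment, int(k)))
        residuals.append(res)
    counts = plan_subslices(path, pitch)
    gaps = [
        Gap(mask.segment, i, i + 1, float(path.distances_mm[i]), int(counts[i]))
        for i in range(path.n_gaps)
    ]
    log.debug(
        "straightened %s/%s/%s: %d slices, %d fine slices, TL=%.2f mm",
        mask.subject_id, mask.side, mask.segment, path.n_slices, int(counts.sum()),
        path.tl_mm,
    )
    return StraightenedVolume(
        patterns=patterns, pattern_meta=meta, gaps=gaps,
        in_plane_spacing=(sx, sz), pitch=pitch,
        subject_id=mask.subject_id, side=mask.side, residuals_mm=residuals,
    )


def concatenate_segments(parts: list[StraightenedVolume]) -> StraightenedVolume:
    """Concatenate straightened segments anterior -> posterior.

    All parts must share the in-plane grid and fine pitch. The segment
    boundary table of the result records each part's fine-index range.
    """
    if not parts:
        raise ValueError("concatenate_segments: no parts")
    first = parts[0]
    for p in parts[1:]:
        if p.plane_dims != first.plane_dims or p.pitch != first.pitch:
            raise ValueError(
                "concatenate_segments: mismatched grids "
                f"({p.plane_dims}@{p.pitch} vs {first.plane_dims}@{first.pitch})"
            )
    patterns, meta, gaps, residuals = [], [], [], []
    for p in parts:
        offset = len(patterns)
        patterns.extend(p.patterns)
        meta.extend(p.pattern_meta)
        residuals.extend(p.residuals_mm)
        gaps.extend(
            replace(g, src_a=g.src_a + offset, src_b=g.src_b + offset) for g in p.gaps
        )
    return StraightenedVolume(
        patterns=patterns, pattern_meta=meta, gaps=gaps,
        in_plane_spacing=first.in_plane_spacing, pitch=first.pitch,
        subject_id=first.subject_id, side=first.side, residuals_mm=residuals,
    )


def straighten_side(
    segment_masks: dict[str, LabeledMask],
    plane_dims: tuple[int, int] = DEFAULT_PLANE_DIMS,
    pitch: float = FINE_PITCH,
) -> StraightenedVolume:
    """Straighten all five segments of one side and concatenate them."""
    parts = [
        straighten_segment(segment_masks[s], plane_dims, pitch)
        for s in SEGMENTS
        if s in segment_masks
    ]
    return concatenate_segments(parts)


def write_straightened(v: StraightenedVolume, path: str | Path) -> Path:
    """Export the fine grid as NIfTI (axial spacing = pitch) plus a
    tab-delimited provenance sidecar (fine index, segment, source slice)."""
    path = Path(path)
    sx, sz = v.in_plane_spacing

    class _Vol:  # minimal duck-typed volume for mask_io.write_mask
        grid = v.fine_grid()
        spacing = (sx, v.pitch, sz)

    write_mask(_Vol, path)
    prov = pd.DataFrame(
        [(j, seg, src) for j, (seg, src) in enumerate(v.provenance())],
        columns=["fine_slice", "segment", "source_slice"],
    )
    sidecar = path.with_name(path.name.split(".")[0] + "_provenance.tsv")
    prov.to_csv(sidecar, sep="\t", index=False)
    return path
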