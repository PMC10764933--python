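"""Length normalization and isotropic resampling of straightened aVPs.

Every subject's straightened pathway is linearly rescaled along the tube
axis to a common target length (by default the cohort mean TL), keeping
each subdivision's proportional share of the length, and then resampled
back to the 0.6 mm isotropic grid shared by the whole cohort, with the
world origin at the nerve head (the centerline of the most anterior
intraorbital slice).

Rescaling never interpolates in-plane patterns: it only re-plans how many
whole fine slices each centroid gap contributes (total fine count
N' = round(N * s) for scale s, apportioned largest-remainder first across
segments and then across gaps), so per-slice CSA stays exactly conserved
and every segment boundary lands within one fine slice of its ideal
proportional position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from numbers import Real
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CentroidPath
from .mask_io import write_mask
from .straighten import Gap, StraightenedVolume, round_half_away

log = logging.getLogger("avpnorm")

DEFAULT_OUT_SPACING = 0.6
#: cohort-wide output grid (x, y, z) at 0.6 mm: 76.8 mm axial coverage
DEFAULT_GRID_DIMS = (64, 128, 64)


class NormalizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Target length


def target_tl(cohort) -> float:
    """Mean whole-aVP total length over all subjects and sides, in mm.

    Accepts an iterable (or mapping to) per-side entries, each either a
    TL in mm, a :class:`CentroidPath`, or a list of per-segment
    :class:`CentroidPath` whose TLs are summed.
    """
    entries = cohort.values() if hasattr(cohort, "values") else cohort
    tls = []
    for entry in entries:
        if isinstance(entry, Real):
            tls.append(float(entry))
        elif isinstance(entry, CentroidPath):
            tls.append(entry.tl_mm)
        else:
            tls.append(float(sum(p.tl_mm for p in entry)))
    if not tls:
        raise NormalizeError("target_tl: empty cohort")
    return float(np.mean(tls))


# ---------------------------------------------------------------------------
# Length rescaling


def _apportion(weights, total: int, min_each=0) -> np.ndarray:
    """Split ``total`` into integers proportional to ``weights``.

    Largest-remainder method with per-entry floors (``min_each`` scalar
    or array); ties broken toward the earlier (more anterior) entry for
    reproducibility.
    """
    w = np.asarray(weights, dtype=float)
    n = len(w)
    floors = np.broadcast_to(np.asarray(min_each, dtype=int), (n,))
    if total < floors.sum():
        raise NormalizeError(f"cannot apportion {total} slices over {n} parts (min {floors.sum()})")
    q = w * (total / w.sum())
    alloc = np.maximum(np.floor(q).astype(int), floors)
    frac = q - np.floor(q)
    diff = int(total - alloc.sum())
    if diff > 0:
        order = np.lexsort((np.arange(n), -frac))
        i = 0
        while diff > 0:
            alloc[order[i % n]] += 1
            diff -= 1
            i += 1
    elif diff < 0:
        order = np.lexsort((np.arange(n), frac))
        i = 0
        while diff < 0:
            j = order[i % n]
            if alloc[j] > floors[j]:
                alloc[j] -= 1
                diff += 1
            i += 1
    return alloc


def rescale_length(v: StraightenedVolume, target_mm: float) -> StraightenedVolume:
    """Rescale a straightened volume to ``target_mm`` total length.

    The scale factor s = target / current fine length multiplies every
    gap distance; the new total fine-slice count round(N * s) is
    apportioned hierarchically (segments, then gaps within each segment,
    each gap keeping at least one slice), and each gap re-emits its
    slices by the same nearest-source replication as straightening.
    Both lengthening (s > 1) and shrinking (s < 1) are supported.
    """
    if target_mm <= 0:
        raise NormalizeError(f"target length must be positive, got {target_mm}")
    current = v.length_mm
    s = target_mm / current
    n_new_total = round_half_away(target_mm / v.pitch)

    seg_order: list[str] = []
    seg_gaps: dict[str, list[int]] = {}
    for gi, g in enumerate(v.gaps):
        if g.segment not in seg_gaps:
            seg_order.append(g.segment)
            seg_gaps[g.segment] = []
        seg_gaps[g.segment].append(gi)

    seg_counts = np.array([sum(v.gaps[i].n_sub for i in seg_gaps[s_]) for s_ in seg_order])
    seg_floors = np.array([len(seg_gaps[s_]) for s_ in seg_order])
    seg_alloc = _apportion(seg_counts, n_new_total, min_each=seg_floors)
    new_gaps: list[Gap] = []
    for seg, n_seg in zip(seg_order, seg_alloc):
        idx = seg_gaps[seg]
        gap_counts = np.array([v.gaps[i].n_sub for i in idx])
        gap_alloc = _apportion(gap_counts, int(n_seg), min_each=1)
        for i, n_i in zip(idx, gap_alloc):
            g = v.gaps[i]
            new_gaps.append(replace(g, d_mm=g.d_mm * s, n_sub=int(n_i)))
    out = replace(v, gaps=new_gaps)
    log.debug(
        "rescaled %s/%s: %d -> %d fine slices (s=%.4f, target %.2f mm)",
        v.subject_id, v.side, v.n_fine, out.n_fine, s, target_mm,
    )
    return out


# ---------------------------------------------------------------------------
# Isotropic resampling


@dataclass
class NormalizedAVP:
    """A length-normalized whole-aVP mask on the shared cohort grid.

    World (0, 0, 0) sits at the nerve head: the in-plane centerline of
    the most anterior (y = 0) slice. ``boundaries_mm`` maps each segment
    to its [start, end) axial range in mm from the origin.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    boundaries_mm: dict[str, tuple[float, float]]
    subject_id: str = ""
    side: str = ""
    origin_index: tuple[float, float, float] | None = None

    @property
    def voxel_count(self) -> int:
        return int(self.grid.sum())

    def y_length_mm(self) -> float:
        occ = np.flatnonzero(self.grid.any(axis=(0, 2)))
        return float((occ[-1] - occ[0] + 1) * self.spacing[1]) if occ.size else 0.0

    def segment_grid(self, segment: str) -> np.ndarray:
        """The mask restricted to one segment's axial range."""
        start_mm, end_mm = self.boundaries_mm[segment]
        sy = self.spacing[1]
        k0 = int(round(start_mm / sy))
        k1 = max(k0 + 1, int(round(end_mm / sy)))
        out = np.zeros_like(self.grid)
        out[:, k0:k1, :] = self.grid[:, k0:k1, :]
        return out


def resample_isotropic(
    v: StraightenedVolume,
    out_spacing: float = DEFAULT_OUT_SPACING,
    grid_dims: tuple[int, int, int] = DEFAULT_GRID_DIMS,
) -> NormalizedAVP:
    """Aggregate fine slices back to the isotropic cohort grid.

    ``out_spacing`` must be an integer multiple of the fine pitch
    (default 10 x 0.06 mm). Each output slice pools that many consecutive
    fine slices; an output voxel is set iff it is occupied in at least
    half of them (majority occupancy — unbiased for monotone tube
    boundaries, and verified to conserve per-slice CSA on phantoms).
    """
    ratio = out_spacing / v.pitch
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise NormalizeError(
            f"output spacing {out_spacing} is not an integer multiple of pitch {v.pitch}"
        )
    nx, nz = v.plane_dims
    gx, gy, gz = grid_dims
    if (nx, nz) != (gx, gz):
        raise NormalizeError(
            f"working plane dims {(nx, nz)} do not match output grid {(gx, gz)}"
        )
    fine = v.fine_grid()
    n_fine = fine.shape[1]
    n_out = math.ceil(n_fine / factor)
    if n_out > gy:
        raise NormalizeError(
            f"normalized length needs {n_out} slices but grid has {gy}; enlarge grid_dims"
        )
    grid = np.zeros((gx, gy, gz), dtype=bool)
    for j in range(n_out):
        block = fine[:, j * factor : (j + 1) * factor, :]
        grid[:, j, :] = block.mean(axis=1) >= 0.5
    sx, sz = v.in_plane_spacing
    boundaries = {
        seg: (start * v.pitch, end * v.pitch)
        for seg, (start, end) in v.segment_boundaries_fine().items()
    }
    return NormalizedAVP(
        grid=grid,
        spacing=(sx, out_spacing, sz),
        boundaries_mm=boundaries,
        subject_id=v.subject_id,
        side=v.side,
    )


def set_origin(v: NormalizedAVP) -> NormalizedAVP:
    """Place world (0,0,0) at the nerve head (idempotent).

    The origin voxel index is the in-plane grid center of slice y = 0,
    which is the centerline of the most anterior intraorbital slice by
    construction. Boundary values are already expressed in mm from that
    slice, so only the header origin changes.
    """
    if not v.boundaries_mm:
        raise NormalizeError("set_origin: missing segment boundary table")
    gx, _, gz = v.grid.shape
    origin = ((gx - 1) / 2.0, 0.0, (gz - 1) / 2.0)
    return replace(v, origin_index=origin)


def normalize_side(
    v: StraightenedVolume,
    target_mm: float,
    out_spacing: float = DEFAULT_OUT_SPACING,
    grid_dims: tuple[int, int, int] = DEFAULT_GRID_DIMS,
) -> NormalizedAVP:
    """rescale -> resample -> set origin, for one straightened side."""
    return set_origin(resample_isotropic(rescale_length(v, target_mm), out_spacing, grid_dims))


def write_normalized(v: NormalizedAVP, path: str | Path) -> Path:
    """Write the normalized mask as NIfTI plus a boundary-table sidecar."""
    path = Path(path)
    write_mask(v, path, origin_index=v.origin_index or (0.0, 0.0, 0.0))
    rows = [
        {"segment": seg, "start_mm": round(a, 4), "end_mm": round(b, 4)}
        for seg, (a, b) in v.boundaries_mm.items()
    ]
    sidecar = path.with_name(path.name.split(".")[0] + "_boundaries.tsv")
    pd.DataFrame(rows).to_csv(sidecar, sep="\t", index=False)
    return path
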