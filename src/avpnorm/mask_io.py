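"""Reading, validation and writing of binary aVP segment masks.

All masks are NIfTI-1 volumes. On load every grid is reoriented to a single
canonical in-memory layout:

* axis 0 (x): left -> right
* axis 1 (y): anterior -> posterior (slice 0 is the most anterior slice,
  indices increase toward the brain)
* axis 2 (z): inferior -> superior

so that a "coronal slice" is always ``grid[:, k, :]``. Voxel indexing is
0-based, a voxel's world position is its center, and coordinates in mm are
index * spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger("avpnorm")

#: Anatomical order of the five aVP subdivisions, anterior to posterior:
#: intraorbital, intracanalicular and intracranial optic nerve, optic chiasm
#: (hemi-trunk) and optic tract.
SEGMENTS = ("iOrb", "iCan", "iCran", "OC", "OT")
#: Compound segments derived downstream: the optic nerve (iOrb+iCan+iCran)
#: and the whole anterior visual pathway.
COMPOUND_SEGMENTS = ("ON", "wholeAVP")
SIDES = ("left", "right", "right-flipped")

DEFAULT_SPACING = (0.6, 0.6, 0.6)


class MaskError(ValueError):
    """Raised for unreadable, empty or non-conforming mask volumes."""


@dataclass
class LabeledMask:
    """A binary occupancy grid for one aVP segment of one side.

    Parameters
    ----------
    grid
        3-D boolean array in the canonical orientation described in the
        module docstring.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm; default 0.6 mm isotropic.
    segment
        One of :data:`SEGMENTS`, a compound tag, or ``"wholeAVP"``.
    side
        ``"left"``, ``"right"`` or ``"right-flipped"``.
    subject_id
        Opaque subject identifier.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    segment: str = "wholeAVP"
    side: str = "left"
    subject_id: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise MaskError(f"mask grid must be 3-D, got {grid.ndim}-D")
        self.grid = grid.astype(bool)
        if any(s <= 0 for s in self.spacing):
            raise MaskError(f"spacing must be strictly positive: {self.spacing}")

    @property
    def voxel_count(self) -> int:
        return int(self.grid.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def y_extent(self) -> tuple[int, int]:
        """First and last nonempty coronal (y) slice index, inclusive."""
        occupied = np.flatnonzero(self.grid.any(axis=(0, 2)))
        if occupied.size == 0:
            raise MaskError(f"mask {self.subject_id}/{self.side}/{self.segment} is empty")
        return int(occupied[0]), int(occupied[-1])

    def coronal_slice(self, k: int) -> np.ndarray:
        """The (x, z) binary pattern of coronal slice ``k``."""
        return self.grid[:, k, :]


@dataclass
class SegmentSet:
    """The five segment masks of one subject's aVP side, anatomical order."""

    subject_id: str
    side: str
    masks: dict[str, LabeledMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in SEGMENTS if s not in self.masks]
        if missing:
            raise MaskError(f"SegmentSet missing segments: {missing}")

    def ordered(self) -> list[LabeledMask]:
        return [self.masks[s] for s in SEGMENTS]

    def union_grid(self) -> np.ndarray:
        grid = np.zeros_like(self.masks[SEGMENTS[0]].grid)
        for m in self.ordered():
            grid |= m.grid
        return grid


# ---------------------------------------------------------------------------
# NIfTI I/O


def _canonical(img: "nib.Nifti1Image") -> "nib.Nifti1Image":
    """Reorient a NIfTI image to RAS+; idempotent."""
    return nib.as_closest_canonical(img)


def read_mask(
    path: str | Path,
    segment: str = "wholeAVP",
    side: str = "left",
    subject_id: str = "",
) -> LabeledMask:
    """Load a NIfTI volume as a canonically oriented binary mask.

    Any nonzero voxel value maps to 1 (label files often store integer
    labels). Spacing is taken from the header. Raises :class:`MaskError`
    for non-3-D volumes and for all-zero masks, which signal an empty
    segmentation upstream.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable header / not a NIfTI
        raise MaskError(f"cannot read {path}: {exc}") from exc
    img = _canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise MaskError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    # RAS+ has +y anterior; flip so slice 0 is the most anterior slice.
    grid = (data != 0)[:, ::-1, :]
    if not grid.any():
        raise MaskError(f"{path}: mask is all zero (empty segmentation)")
    zooms = img.header.get_zooms()[:3]
    return LabeledMask(
        grid=grid,
        spacing=tuple(float(z) for z in zooms),
        segment=segment,
        side=side,
        subject_id=subject_id,
    )


def _ap_affine(spacing, origin_index=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Affine mapping our anterior-first voxel layout into RAS+ world mm.

    ``origin_index`` is the (possibly fractional) voxel index placed at
    world (0, 0, 0).
    """
    sx, sy, sz = spacing
    aff = np.diag([sx, -sy, sz, 1.0])
    aff[:3, 3] = -aff[:3, :3] @ np.asarray(origin_index, dtype=float)
    return aff


def write_mask(mask, path: str | Path, origin_index=(0.0, 0.0, 0.0)) -> Path:
    """Write a binary mask (uint8) or a float grid (e.g. an atlas) to NIfTI.

    Binary grids round-trip bit-exactly through :func:`read_mask`. The
    header encodes spacing, canonical orientation and the world origin.
    """
    path = Path(path)
    grid = mask.grid if hasattr(mask, "grid") else getattr(mask, "values")
    spacing = mask.spacing
    if grid.dtype == bool:
        data = grid.astype(np.uint8)
    else:
        data = grid.astype(np.float32)
    # the -sy affine encodes the anterior-first axis, so the grid is stored as is
    img = nib.Nifti1Image(data, _ap_affine(spacing, origin_index))
    img.header.set_zooms([abs(s) for s in spacing])
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise MaskError(f"cannot write {path}: {exc}") from exc
    return path


def read_atlas_grid(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a float (probabilistic-atlas) volume in the canonical layout."""
    img = _canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj).astype(np.float64)[:, ::-1, :]
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


# ---------------------------------------------------------------------------
# Optic-chiasm splitting


def split_oc_midsagittal(
    oc: LabeledMask, plane_x: int | str = "auto"
) -> tuple[LabeledMask, LabeledMask]:
    """Split an optic-chiasm mask into left and right hemi-trunks.

    The chiasm is the single trunk where left and right pathways merge; it
    is divided at a sagittal plane at voxel index ``plane_x`` (``"auto"`` =
    the grid x-midline). In the canonical orientation low x is the
    subject's left, so voxels with ``x < plane_x`` form the left hemi-trunk
    and ``x >= plane_x`` the right. The outputs partition the input.
    """
    if oc.segment != "OC":
        raise MaskError(f"split_oc_midsagittal expects an OC mask, got {oc.segment!r}")
    nx = oc.grid.shape[0]
    plane = nx // 2 if plane_x == "auto" else int(plane_x)
    if not 0 < plane < nx:
        raise MaskError(f"split plane x={plane} outside grid x-range (0, {nx})")
    left_grid = oc.grid.copy()
    left_grid[plane:, :, :] = False
    right_grid = oc.grid.copy()
    right_grid[:plane, :, :] = False
    if not left_grid.any() or not right_grid.any():
        raise MaskError(
            f"OC split at x={plane} leaves an empty hemi-trunk (off-center plane)"
        )
    mk = lambda g, side: LabeledMask(  # noqa: E731
        g, oc.spacing, "OC", side, oc.subject_id
    )
    return mk(left_grid, "left"), mk(right_grid, "right")


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    """Report-only outcome of :func:`validate_segment_set`."""

    subject_id: str
    side: str
    disjointness_violations: list[tuple[str, str, int]] = field(default_factory=list)
    gaps: list[tuple[str, str, int, int]] = field(default_factory=list)
    overlaps: list[tuple[str, str, int]] = field(default_factory=list)
    empty_slices: list[tuple[str, int]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (
            self.disjointness_violations or self.gaps or self.overlaps or self.empty_slices
        )

    def summary(self) -> str:
        if self.passed:
            return f"{self.subject_id}/{self.side}: OK"
        lines = [f"{self.subject_id}/{self.side}: FAILED"]
        for a, b, n in self.disjointness_violations:
            lines.append(f"  segments {a} and {b} share {n} voxel(s)")
        for a, b, y0, y1 in self.gaps:
            lines.append(f"  axial gap between {a} and {b}: empty slices {y0}..{y1}")
        for a, b, n in self.overlaps:
            lines.append(f"  y-extents of {a} and {b} overlap by {n} slice(s)")
        for seg, y in self.empty_slices:
            lines.append(f"  {seg}: empty intermediate slice at y={y}")
        return "\n".join(lines)


def validate_segment_set(s: SegmentSet) -> ValidationReport:
    """Check disjointness, anterior->posterior ordering and contiguity.

    Consecutive segments must abut (a gap of at most one slice is
    tolerated, matching segmentation boundary ambiguity); y-extents must
    not overlap; every slice between a segment's first and last nonempty
    slice must be nonempty. Report-only: no exception is raised.
    """
    report = ValidationReport(s.subject_id, s.side)
    masks = s.ordered()
    for i, a in enumerate(masks):
        for b in masks[i + 1 :]:
            shared = int((a.grid & b.grid).sum())
            if shared:
                report.disjointness_violations.append((a.segment, b.segment, shared))
    extents = [m.y_extent() for m in masks]
    for (a, (a0, a1)), (b, (b0, b1)) in zip(
        zip(masks, extents), zip(masks[1:], extents[1:])
    ):
        gap = b0 - a1 - 1
        if gap > 1:
            report.gaps.append((a.segment, b.segment, a1 + 1, b0 - 1))
        elif gap < 0:
            report.overlaps.append((a.segment, b.segment, -gap))
    for m, (y0, y1) in zip(masks, extents):
        for y in range(y0, y1 + 1):
            if not m.grid[:, y, :].any():
                report.empty_slices.append((m.segment, y))
    return report


# ---------------------------------------------------------------------------
# Cohort manifests


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a plain-text cohort manifest (subject, side, segment, path).

    Comma- or tab-delimited with a header row; relative mask paths are
    resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject", "side", "segment", "path"}
    missing = required - set(df.columns)
    if missing:
        raise MaskError(f"manifest {path} missing columns: {sorted(missing)}")
    bad_seg = set(df["segment"]) - set(SEGMENTS) - {"OC-unsplit"}
    if bad_seg:
        raise MaskError(f"manifest {path}: unknown segment tags {sorted(bad_seg)}")
    df = df.copy()
    df["path"] = [str((path.parent / p).resolve()) for p in df["path"]]
    return df


def load_cohort(manifest: str | Path) -> list[SegmentSet]:
    """Load every (subject, side) SegmentSet listed in a manifest.

    Rows with segment tag ``OC-unsplit`` are split at the midsagittal
    x-midline and contribute an OC hemi-trunk to each side.
    """
    df = read_manifest(manifest)
    sets: dict[tuple[str, str], dict[str, LabeledMask]] = {}
    for row in df.itertuples(index=False):
        subject, side, segment = str(row.subject), str(row.side), str(row.segment)
        if segment == "OC-unsplit":
            oc = read_mask(row.path, "OC", "unsplit", subject)
            left, right = split_oc_midsagittal(oc)
            sets.setdefault((subject, "left"), {})["OC"] = left
            sets.setdefault((subject, "right"), {})["OC"] = right
            continue
        if side not in ("left", "right"):
            raise MaskError(f"manifest row {subject}/{segment}: unknown side {side!r}")
        mask = read_mask(row.path, segment, side, subject)
        sets.setdefault((subject, side), {})[segment] = mask
    out = []
    for (subject, side), masks in sorted(sets.items()):
        out.append(SegmentSet(subject_id=subject, side=side, masks=masks))
    return out


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Write a cohort manifest; ``rows`` hold subject/side/segment/path."""
    path = Path(path)
    pd.DataFrame(rows, columns=["subject", "side", "segment", "path"]).to_csv(
        path, index=False
    )
    return path
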