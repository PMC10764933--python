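"""Synthetic aVP phantoms with analytic ground truth.

A phantom is a curved elliptical tube voxelized on the 0.6 mm grid: each
coronal slice is the filled ellipse of the local cross-section profile
centered on a smooth centerline, and the five subdivisions are assigned
by arc-length fraction along that centerline. Because the tube is built
slice-by-slice, its exact volume, centroid-polyline length, mCSA and
ellipticity are known in closed form, so every pipeline stage can be
tested against analytic truth without any scan data.

Defaults place the cohort in the anatomically plausible regime for the
adult anterior visual pathway: total length around 61 mm, segment length
shares of roughly 37/11/26/11/16 % (intraorbital, canalicular,
intracranial, chiasm hemi-trunk, tract), cross-sections of 5-15 mm^2 and
ellipticity rising from ~0.15 in the orbit to ~0.57 at the chiasm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .mask_io import SEGMENTS, LabeledMask, SegmentSet, write_manifest, write_mask

log = logging.getLogger("avpnorm")

DEFAULT_TOTAL_LENGTH = 61.1  # mm, cohort mean aVP length
DEFAULT_FRACTIONS = (0.366, 0.114, 0.257, 0.107, 0.156)
DEFAULT_EPSILON = (0.15, 0.20, 0.43, 0.57, 0.39)
DEFAULT_CSA = (7.67, 5.62, 6.92, 14.37, 7.61)  # mm^2 per segment
#: centerline control offsets (mm) at equally spaced stations, emulating
#: the orbital bend and the gentler chiasmal course
DEFAULT_BEND_X = (0.0, 1.4, 2.2, 1.5, 0.8, 0.4)
DEFAULT_BEND_Z = (0.0, 0.6, 1.0, 0.5, 0.1, 0.0)
#: fine-scale tortuosity superimposed on the smooth course: real nerves
#: wobble by a fraction of a voxel from slice to slice, which also keeps
#: the cross-section from sitting lattice-locked at one sub-voxel phase
DEFAULT_TORTUOSITY_AMP = 0.25  # mm
DEFAULT_TORTUOSITY_CYCLES = (4.0, 3.0)  # full periods along the path (x, z)
#: oblique lateral/vertical drift of the course (mm over the full path):
#: the pathway runs posterolaterally, not parallel to the y axis
DEFAULT_DRIFT = (6.3, 4.7)


class PhantomError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Parameters of one synthetic aVP side.

    ``segment_fractions`` are arc-length shares (must sum to 1);
    ``segment_csa_mm2`` and ``segment_epsilon`` fix the piecewise-constant
    elliptical profile, from which the hemi-axes follow as
    h1 = sqrt(CSA / (pi (1 - eps))), h2 = (1 - eps) h1.
    """

    subject_id: str = "phantom"
    side: str = "left"
    total_length_mm: float = DEFAULT_TOTAL_LENGTH
    segment_fractions: tuple = DEFAULT_FRACTIONS
    segment_epsilon: tuple = DEFAULT_EPSILON
    segment_csa_mm2: tuple = DEFAULT_CSA
    bend_x_mm: tuple = DEFAULT_BEND_X
    bend_z_mm: tuple = DEFAULT_BEND_Z
    tortuosity_amp_mm: float = DEFAULT_TORTUOSITY_AMP
    tortuosity_cycles: tuple = DEFAULT_TORTUOSITY_CYCLES
    tortuosity_phase: tuple = (0.0, 1.0)
    drift_mm: tuple = DEFAULT_DRIFT
    rotation_deg: float = 0.0
    spacing: float = 0.6
    seed: int | None = None

    def __post_init__(self) -> None:
        total = float(np.sum(self.segment_fractions))
        if abs(total - 1.0) > 1e-6:
            raise PhantomError(f"segment fractions sum to {total}, expected 1")
        for eps in self.segment_epsilon:
            if not 0 <= eps < 1:
                raise PhantomError(f"epsilon {eps} outside [0, 1)")
        h1, h2 = self.hemi_axes()
        if (h2 <= self.spacing).any():
            raise PhantomError(
                "minor hemi-axis at or below one voxel; tube would vanish on the grid"
            )

    def hemi_axes(self) -> tuple[np.ndarray, np.ndarray]:
        csa = np.asarray(self.segment_csa_mm2, dtype=float)
        eps = np.asarray(self.segment_epsilon, dtype=float)
        h1 = np.sqrt(csa / (np.pi * (1.0 - eps)))
        return h1, (1.0 - eps) * h1


def _centerline(spec: PhantomSpec, n_slices: int, plane_center: tuple[float, float]):
    """Slice-center coordinates (x, z) in mm, cubic through control points."""
    u_ctrl = np.linspace(0.0, 1.0, len(spec.bend_x_mm))
    fx = CubicSpline(u_ctrl, spec.bend_x_mm)
    fz = CubicSpline(u_ctrl, spec.bend_z_mm)
    u = np.linspace(0.0, 1.0, n_slices)
    amp = spec.tortuosity_amp_mm
    cx_cyc, cz_cyc = spec.tortuosity_cycles
    px, pz = spec.tortuosity_phase
    wob_x = amp * np.sin(2 * np.pi * cx_cyc * u + px)
    wob_z = amp * np.sin(2 * np.pi * cz_cyc * u + pz)
    dx, dz = spec.drift_mm
    # keep the drifting course centered on the grid
    drift_x = dx * (u - 0.5)
    drift_z = dz * (u - 0.5)
    return (
        plane_center[0] + fx(u) + wob_x + drift_x,
        plane_center[1] + fz(u) + wob_z + drift_z,
    )


def _polyline_tl(x: np.ndarray, z: np.ndarray, sy: float) -> np.ndarray:
    """Per-gap 3-D distances of the slice-center polyline."""
    return np.sqrt(np.diff(x) ** 2 + sy**2 + np.diff(z) ** 2)


def _check_curvature(x: np.ndarray, z: np.ndarray, sy: float, max_h1: float) -> None:
    """Reject centerlines whose curvature radius drops below the tube radius."""
    pts = np.column_stack([x, np.arange(len(x)) * sy, z])
    for a, b, c in zip(pts, pts[1:], pts[2:]):
        ab, bc, ca = b - a, c - b, a - c
        area2 = np.linalg.norm(np.cross(ab, bc))
        if area2 < 1e-12:
            continue
        r = np.linalg.norm(ab) * np.linalg.norm(bc) * np.linalg.norm(ca) / (2 * area2)
        if r < max_h1:
            raise PhantomError(
                f"centerline curvature radius {r:.2f} mm below tube radius {max_h1:.2f} mm "
                "(self-intersection)"
            )


def generate_phantom(
    spec: PhantomSpec,
    grid_dims: tuple[int, int, int] = (64, 128, 64),
) -> tuple[SegmentSet, pd.DataFrame]:
    """Voxelize one phantom side and return its masks plus ground truth.

    A voxel is set iff its center lies inside the local ellipse
    (center-sampling, matching the counting-based CSA used throughout).
    The truth table holds the analytic per-segment length (centroid
    polyline), volume (sum of slice ellipse areas x slice pitch), mCSA
    (volume / length) and profile ellipticity, plus the derived ON and
    whole-aVP compound rows.
    """
    s = spec.spacing
    gx, gy, gz = grid_dims
    plane_center = ((gx - 1) / 2.0 * s, (gz - 1) / 2.0 * s)
    h1_seg, h2_seg = spec.hemi_axes()

    # choose the slice count whose polyline length best matches the target
    base = int(round(spec.total_length_mm / s)) + 1
    best = None
    for ny in range(max(3, base - 4), base + 4):
        x, z = _centerline(spec, ny, plane_center)
        tl = _polyline_tl(x, z, s).sum()
        err = abs(tl - spec.total_length_mm)
        if best is None or err < best[0]:
            best = (err, ny, x, z)
    _, n_slices, cx, cz = best
    if n_slices > gy:
        raise PhantomError(f"phantom needs {n_slices} slices, grid has {gy}")
    dists = _polyline_tl(cx, cz, s)
    _check_curvature(cx, cz, s, float(h1_seg.max()))

    # Segment assignment by arc-length share. The fractions are shares of
    # the summed within-segment lengths (the way length proportions are
    # tabulated), so the four inter-segment boundary gaps are excluded
    # from the budget before slicing it up.
    cum = np.concatenate([[0.0], np.cumsum(dists)])
    within_budget = cum[-1] - 4.0 * float(dists.mean())
    seg_idx = np.empty(n_slices, dtype=int)
    fracs = np.asarray(spec.segment_fractions, dtype=float)
    start = 0
    for k in range(5):
        if k == 4:
            end = n_slices
        else:
            target = cum[start] + fracs[k] * within_budget
            j = int(np.searchsorted(cum, target, side="left"))
            j = min(j, n_slices - 1)
            # last slice of this segment = the cum position nearest the target
            if j > 0 and abs(cum[j - 1] - target) <= abs(cum[j] - target):
                j -= 1
            end = min(max(j + 1, start + 2), n_slices - 2 * (4 - k))
        seg_idx[start:end] = k
        start = end
    for k in range(5):
        if (seg_idx == k).sum() < 2:
            raise PhantomError(f"segment {SEGMENTS[k]} would get fewer than 2 slices")

    # voxelize
    theta = np.deg2rad(spec.rotation_deg)
    ct, st = np.cos(theta), np.sin(theta)
    xs = np.arange(gx) * s
    zs = np.arange(gz) * s
    gxx, gzz = np.meshgrid(xs, zs, indexing="ij")
    grids = {seg: np.zeros(grid_dims, dtype=bool) for seg in SEGMENTS}
    for j in range(n_slices):
        k = int(seg_idx[j])
        dx, dz = gxx - cx[j], gzz - cz[j]
        a = (dx * ct + dz * st) / h1_seg[k]
        b = (-dx * st + dz * ct) / h2_seg[k]
        inside = a * a + b * b <= 1.0
        if inside[0, :].any() or inside[-1, :].any() or inside[:, 0].any() or inside[:, -1].any():
            raise PhantomError("phantom tube reaches the grid border; enlarge grid_dims")
        grids[SEGMENTS[k]][:, j, :] = inside

    masks = {
        seg: LabeledMask(grids[seg], (s, s, s), seg, spec.side, spec.subject_id)
        for seg in SEGMENTS
    }
    segment_set = SegmentSet(spec.subject_id, spec.side, masks)

    # analytic truth, slice-stacked: volume = sum over slices of the
    # continuous ellipse area x pitch; length = within-segment polyline
    rows = []
    for k, seg in enumerate(SEGMENTS):
        slices = np.flatnonzero(seg_idx == k)
        length = float(dists[slices[0] : slices[-1]].sum())
        volume = float(len(slices) * np.pi * h1_seg[k] * h2_seg[k] * s)
        rows.append(
            {
                "subject": spec.subject_id, "side": spec.side, "segment": seg,
                "volume_mm3": volume, "length_mm": length,
                "mcsa_mm2": volume / length,
                "epsilon": float(spec.segment_epsilon[k]),
                "n_slices": int(len(slices)),
            }
        )
    truth = pd.DataFrame(rows)
    for name, members in (("ON", SEGMENTS[:3]), ("wholeAVP", SEGMENTS)):
        sub = truth[truth["segment"].isin(members)]
        vol, length = sub["volume_mm3"].sum(), sub["length_mm"].sum()
        truth = pd.concat(
            [
                truth,
                pd.DataFrame(
                    [{
                        "subject": spec.subject_id, "side": spec.side, "segment": name,
                        "volume_mm3": vol, "length_mm": length, "mcsa_mm2": vol / length,
                        "epsilon": float(np.average(sub["epsilon"], weights=sub["length_mm"])),
                        "n_slices": int(sub["n_slices"].sum()),
                    }]
                ),
            ],
            ignore_index=True,
        )
    return segment_set, truth


def cylinder_spec(
    radius_mm: float = 1.5,
    length_mm: float = 30.0,
    subject_id: str = "cylinder",
    side: str = "left",
) -> PhantomSpec:
    """A straight circular cylinder, mildly oblique to the slice axis.

    The ~3 degree obliquity sweeps the cross-section through a full
    voxel of sub-voxel phases along the tube, so lattice counts average
    to the analytic area; it lengthens the centroid path by < 0.2 %.
    Segment labels split the cylinder into five equal parts.
    """
    csa = float(np.pi * radius_mm**2)
    return PhantomSpec(
        subject_id=subject_id, side=side, total_length_mm=length_mm,
        segment_fractions=(0.2,) * 5, segment_epsilon=(0.0,) * 5,
        segment_csa_mm2=(csa,) * 5,
        bend_x_mm=(0.0,) * 6, bend_z_mm=(0.0,) * 6,
        tortuosity_amp_mm=0.0,
        drift_mm=(0.055 * length_mm, 0.04 * length_mm),
    )


# ---------------------------------------------------------------------------
# Cohorts


def generate_cohort(
    n_subjects: int,
    variability: float = 0.05,
    seed: int = 0,
    sides: tuple = ("left", "right"),
    grid_dims: tuple[int, int, int] = (64, 128, 64),
    mean_length_mm: float = DEFAULT_TOTAL_LENGTH,
) -> tuple[list[SegmentSet], pd.DataFrame]:
    """Generate a reproducible synthetic cohort with mild variability.

    Per subject, the total length is drawn lognormally around
    ``mean_length_mm`` with fractional spread ``variability``; segment
    fractions, cross-section profiles and centerline bends are jittered
    with the same fractional spread, independently for the two sides.
    ``variability = 0`` yields identical subjects; the same seed yields
    the identical cohort.
    """
    if n_subjects < 1:
        raise PhantomError("need at least one subject")
    if variability < 0:
        raise PhantomError("variability must be >= 0")
    rng = np.random.default_rng(seed)
    sets: list[SegmentSet] = []
    truths: list[pd.DataFrame] = []
    for i in range(n_subjects):
        subject = f"sub{i:03d}"
        tl = mean_length_mm * float(np.exp(rng.normal(0.0, variability)))
        fractions = np.asarray(DEFAULT_FRACTIONS) * (
            1.0 + rng.normal(0.0, variability, 5)
        )
        fractions = np.abs(fractions)
        fractions /= fractions.sum()
        for side in sides:
            eps = np.clip(
                np.asarray(DEFAULT_EPSILON) * (1.0 + rng.normal(0.0, variability, 5)),
                0.03, 0.75,
            )
            csa = np.clip(
                np.asarray(DEFAULT_CSA) * (1.0 + rng.normal(0.0, variability, 5)),
                3.0, None,
            )
            bend_scale = 1.0 + rng.normal(0.0, variability)
            bend_x = tuple(np.asarray(DEFAULT_BEND_X) * bend_scale
                           + rng.normal(0.0, 0.3 * variability * 10, len(DEFAULT_BEND_X)))
            bend_z = tuple(np.asarray(DEFAULT_BEND_Z) * bend_scale
                           + rng.normal(0.0, 0.2 * variability * 10, len(DEFAULT_BEND_Z)))
            phases = tuple(rng.uniform(0.0, 2.0 * np.pi, 2)) if variability > 0 else (0.0, 1.0)
            spec = PhantomSpec(
                subject_id=subject, side=side, total_length_mm=tl,
                segment_fractions=tuple(fractions), segment_epsilon=tuple(eps),
                segment_csa_mm2=tuple(csa), bend_x_mm=bend_x, bend_z_mm=bend_z,
                tortuosity_phase=phases, seed=seed,
            )
            segment_set, truth = generate_phantom(spec, grid_dims)
            sets.append(segment_set)
            truths.append(truth)
    return sets, pd.concat(truths, ignore_index=True)


def write_cohort(
    sets: list[SegmentSet], out_dir: str | Path, truth: pd.DataFrame | None = None
) -> Path:
    """Write cohort masks as NIfTI files plus a manifest (and truth table)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sets:
        for seg in SEGMENTS:
            name = f"{s.subject_id}_{s.side}_{seg}.nii.gz"
            write_mask(s.masks[seg], out_dir / name)
            rows.append(
                {"subject": s.subject_id, "side": s.side, "segment": seg, "path": name}
            )
    manifest = write_manifest(rows, out_dir / "manifest.csv")
    if truth is not None:
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return manifest
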