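"""Probabilistic atlas construction and leave-one-out Dice validation.

The atlas value at a voxel is the percentage of contributing normalized
masks that cover it: 100 x (coverage count) / n_masks, on the shared
cohort grid with the origin at the nerve head. Right-side masks are
mirrored to the left before averaging so that all 2n masks of an
n-subject cohort contribute to one left-space atlas.

Atlas generalizability is estimated by leave-one-out cross-validation:
for each subject, an atlas is rebuilt from the remaining subjects' masks,
thresholded at the 50 % probability level, and compared to the withheld
subject's masks with the Dice Similarity Index

    DSI(A, B) = 2 |A n B| / (|A| + |B|).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .mask_io import SEGMENTS, LabeledMask, write_mask
from .normalize import NormalizedAVP

log = logging.getLogger("avpnorm")

DEFAULT_THRESHOLD = 50.0


class AtlasError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mirroring


def flip_right_to_left(m: NormalizedAVP) -> NormalizedAVP:
    """Mirror a right-side normalized mask about the left-right midplane.

    The grid is reversed along x (index i -> nx-1-i), which maps the
    straightening centerline onto itself; axial geometry and segment
    boundaries are untouched. Flipping a left mask is almost surely a
    bookkeeping error and triggers a warning, not an exception.
    """
    if m.side == "left":
        warnings.warn(f"flip_right_to_left: mask {m.subject_id} is already left-sided")
    new_side = "left" if m.side == "right-flipped" else "right-flipped"
    return replace(m, grid=m.grid[::-1, :, :].copy(), side=new_side)


def _left_space_grid(m: NormalizedAVP) -> NormalizedAVP:
    return flip_right_to_left(m) if m.side == "right" else m


# ---------------------------------------------------------------------------
# Atlas


@dataclass
class ProbabilisticAtlas:
    """Voxel-wise overlap percentages (0-100) over a cohort of masks."""

    values: np.ndarray  # float, percent
    n_masks: int
    spacing: tuple[float, float, float]
    origin_index: tuple[float, float, float] | None = None
    segment_atlases: dict[str, "ProbabilisticAtlas"] = field(default_factory=dict)

    @property
    def grid(self) -> np.ndarray:  # for write_mask duck typing
        return self.values


def build_atlas(
    masks: list[NormalizedAVP],
    flip_right: bool = True,
    per_segment: bool = True,
) -> ProbabilisticAtlas:
    """Average binary normalized masks into overlap percentages.

    value(v) = 100 x (number of masks containing v) / n_masks. With
    ``flip_right`` every right-side mask is mirrored to the left first.
    Per-segment child atlases are built identically from each mask
    restricted to its segment's axial range.
    """
    if not masks:
        raise AtlasError("build_atlas: empty mask list")
    shape = masks[0].grid.shape
    for m in masks[1:]:
        if m.grid.shape != shape:
            raise AtlasError(f"build_atlas: grid mismatch {m.grid.shape} vs {shape}")
    prepared = [_left_space_grid(m) if flip_right else m for m in masks]
    n = len(prepared)
    acc = np.zeros(shape, dtype=np.float64)
    for m in prepared:
        acc += m.grid
    atlas = ProbabilisticAtlas(
        values=acc * (100.0 / n),
        n_masks=n,
        spacing=masks[0].spacing,
        origin_index=masks[0].origin_index,
    )
    if per_segment:
        for seg in SEGMENTS:
            if not all(seg in m.boundaries_mm for m in prepared):
                continue
            acc_s = np.zeros(shape, dtype=np.float64)
            for m in prepared:
                acc_s += m.segment_grid(seg)
            atlas.segment_atlases[seg] = ProbabilisticAtlas(
                values=acc_s * (100.0 / n), n_masks=n,
                spacing=masks[0].spacing, origin_index=masks[0].origin_index,
            )
    return atlas


def threshold_atlas(a: ProbabilisticAtlas, level: float = DEFAULT_THRESHOLD) -> LabeledMask:
    """Binary mask of voxels with overlap >= ``level`` percent.

    The comparison is inclusive so the 50 % level is well defined for an
    even number of masks. level -> 0+ approaches the union of masks,
    level = 100 their intersection.
    """
    if not 0 < level <= 100:
        raise AtlasError(f"threshold level must be in (0, 100], got {level}")
    return LabeledMask(
        grid=a.values >= level, spacing=a.spacing,
        segment="wholeAVP", side="left", subject_id=f"atlas>={level:g}%",
    )


# ---------------------------------------------------------------------------
# Dice similarity


def dsi(a, b) -> float:
    """Dice Similarity Index 2|A n B| / (|A| + |B|) of two binary masks.

    Accepts boolean arrays or LabeledMask/NormalizedAVP objects on the
    same grid. Two empty masks are identically empty (DSI = 1); one empty
    operand gives 0 — segment-restricted comparisons can produce both.
    """
    ga = a.grid if hasattr(a, "grid") else np.asarray(a, dtype=bool)
    gb = b.grid if hasattr(b, "grid") else np.asarray(b, dtype=bool)
    if ga.shape != gb.shape:
        raise AtlasError(f"dsi: grid mismatch {ga.shape} vs {gb.shape}")
    na, nb = int(ga.sum()), int(gb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ga & gb).sum()) / (na + nb)


@dataclass
class DSIResult:
    subject_id: str
    side: str
    dsi: float
    threshold: float


# ---------------------------------------------------------------------------
# Leave-one-out validation


def loo_validation(
    masks_by_subject: dict[str, list[NormalizedAVP]],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[DSIResult], dict[str, float]]:
    """Leave-one-out Dice validation of the atlas, one score per subject.

    For each subject, both of that subject's masks are withheld (leaving
    one side in would leak the contralateral anatomy into the reference);
    the atlas of the remaining 2(n-1) masks is thresholded at ``threshold``
    percent and compared with each withheld mask (right masks mirrored to
    the left space first). The subject's score is the mean of its two
    DSIs. The summary reports the 50th percentile (median subject) and
    the 5th percentile (the level reached in 95 % of participants).
    """
    subjects = sorted(masks_by_subject)
    if len(subjects) < 2:
        raise AtlasError("loo_validation: need at least 2 subjects")
    results: list[DSIResult] = []
    scores = []
    for held_out in subjects:
        rest = [m for s in subjects if s != held_out for m in masks_by_subject[s]]
        ref = threshold_atlas(build_atlas(rest, per_segment=False), threshold)
        subject_dsis = []
        for m in masks_by_subject[held_out]:
            d = dsi(_left_space_grid(m), ref)
            subject_dsis.append(d)
            results.append(DSIResult(held_out, m.side, d, threshold))
        scores.append(float(np.mean(subject_dsis)))
    scores = np.asarray(scores)
    summary = {
        "n_subjects": float(len(subjects)),
        "median_dsi": float(np.percentile(scores, 50)),
        "p5_dsi": float(np.percentile(scores, 5)),
    }
    log.info(
        "LOO validation: median DSI %.3f, 5th percentile %.3f over %d subjects",
        summary["median_dsi"], summary["p5_dsi"], len(subjects),
    )
    return results, summary


# ---------------------------------------------------------------------------
# Export


def write_atlas(a: ProbabilisticAtlas, path: str | Path) -> Path:
    """Write the atlas (and any per-segment children) as float NIfTI."""
    path = Path(path)
    write_mask(a, path, origin_index=a.origin_index or (0.0, 0.0, 0.0))
    for seg, child in a.segment_atlases.items():
        child_path = path.with_name(path.name.split(".")[0] + f"_{seg}.nii.gz")
        write_mask(child, child_path, origin_index=child.origin_index or (0.0, 0.0, 0.0))
    return path


def write_dsi_report(
    results: list[DSIResult], summary: dict[str, float], table_path: str | Path,
    summary_path: str | Path | None = None,
) -> Path:
    table_path = Path(table_path)
    pd.DataFrame(
        [(r.subject_id, r.side, r.dsi, r.threshold) for r in results],
        columns=["subject", "side", "dsi", "threshold_pct"],
    ).to_csv(table_path, sep="\t", index=False)
    if summary_path is not None:
        lines = [f"{k}: {v:.4f}" for k, v in summary.items()]
        Path(summary_path).write_text("\n".join(lines) + "\n")
    return table_path
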