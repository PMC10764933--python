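"""Cohort-level biometry summaries.

Works on long-format tables with one row per (subject, side, segment) and
columns volume_mm3, length_mm, mcsa_mm2, epsilon — the layout produced by
:func:`avpnorm.geometry.segment_biometrics`. Provides the derived
compound segments (ON = iOrb + iCan + iCran, and the entire aVP),
descriptive statistics with paired left-right comparisons, between-subject
coefficients of variation, and standardized (proportion-of-total /
variation-from-mean) metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mask_io import SEGMENTS

log = logging.getLogger("avpnorm")

METRICS = ("volume_mm3", "length_mm", "mcsa_mm2", "epsilon")
ON_PARTS = ("iOrb", "iCan", "iCran")
WHOLE = "wholeAVP"


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Compound segments


def derive_compound_segments(records: pd.DataFrame) -> pd.DataFrame:
    """Append ON and whole-aVP rows for every (subject, side).

    Compound volume and length are exact sums of the member segments
    (same voxels, same centroid path); compound mCSA is compound volume
    over compound length. Compound epsilon is the length-weighted mean of
    the member segment values — the closest table-level stand-in for the
    slice-mean over the compound extent (slice counts are proportional to
    length at fixed pitch).
    """
    required = set(SEGMENTS)
    out_rows = []
    for (subject, side), grp in records.groupby(["subject", "side"], sort=False):
        present = set(grp["segment"])
        missing = required - present
        if missing:
            raise StatsError(f"{subject}/{side}: missing segments {sorted(missing)}")
        by_seg = grp.set_index("segment")
        for name, members in (("ON", ON_PARTS), (WHOLE, SEGMENTS)):
            sub = by_seg.loc[list(members)]
            vol = float(sub["volume_mm3"].sum())
            length = float(sub["length_mm"].sum())
            eps = float(np.average(sub["epsilon"], weights=sub["length_mm"]))
            out_rows.append(
                {
                    "subject": subject, "side": side, "segment": name,
                    "volume_mm3": vol, "length_mm": length,
                    "mcsa_mm2": vol / length, "epsilon": eps,
                }
            )
    return pd.concat([records, pd.DataFrame(out_rows)], ignore_index=True)


# ---------------------------------------------------------------------------
# Paired left-right comparison


@dataclass
class PairedComparison:
    """Closed-form paired t-test on left - right differences."""

    n: int
    mean_diff: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    degenerate: bool = False  # zero-variance, nonzero differences


def paired_lr_comparison(left, right) -> PairedComparison:
    """Paired t-test of left vs right values with a 95 % CI on the mean
    difference (positive = left larger).

    Identical sides give t = 0, p = 1. Constant nonzero differences have
    zero variance, so t is undefined: signalled with ``degenerate=True``
    and NaN statistics.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise StatsError(f"unpaired lengths: {left.shape} vs {right.shape}")
    n = left.size
    if n < 2:
        raise StatsError("paired comparison needs n >= 2 pairs")
    d = left - right
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedComparison(n, 0.0, 0.0, 0.0, 0.0, 1.0)
        return PairedComparison(
            n, mean, float("nan"), float("nan"), float("nan"), float("nan"),
            degenerate=True,
        )
    se = sd / np.sqrt(n)
    t = mean / se
    tcrit = stats.t.ppf(0.975, n - 1)
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedComparison(
        n, mean, mean - tcrit * se, mean + tcrit * se, float(t), float(p)
    )


# ---------------------------------------------------------------------------
# Dispersion


def coefficient_of_variation(values) -> float:
    """Between-subject CV in percent: 100 x sample SD / mean (n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise StatsError("coefficient_of_variation needs n >= 2")
    mean = v.mean()
    if mean == 0:
        raise StatsError("coefficient_of_variation undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def lr_average(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject left/right average of each metric, by segment."""
    return (
        records.groupby(["subject", "segment"], sort=False)[list(METRICS)]
        .mean()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Standardized (Table-2-style) metrics


def standardized_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Per-record standardized metrics relative to the whole aVP.

    Volume and length become proportions of the entire aVP
    (100 x segment / whole, summing to 100 % over the five segments);
    mCSA and epsilon become the percent variation from the mean-aVP value
    (100 x (segment / whole - 1)) — the deviation from a hypothetical
    nerve of the same volume and length but constant cross-section.
    """
    if WHOLE not in set(records["segment"]):
        records = derive_compound_segments(records)
    rows = []
    for (subject, side), grp in records.groupby(["subject", "side"], sort=False):
        by_seg = grp.set_index("segment")
        whole = by_seg.loc[WHOLE]
        if whole["volume_mm3"] == 0 or whole["mcsa_mm2"] == 0 or whole["epsilon"] == 0:
            raise StatsError(f"{subject}/{side}: zero whole-aVP denominator")
        for seg in (*SEGMENTS, "ON"):
            if seg not in by_seg.index:
                continue
            s = by_seg.loc[seg]
            rows.append(
                {
                    "subject": subject, "side": side, "segment": seg,
                    "volume_pct_of_total": 100.0 * s["volume_mm3"] / whole["volume_mm3"],
                    "length_pct_of_total": 100.0 * s["length_mm"] / whole["length_mm"],
                    "mcsa_pct_vs_mean": 100.0 * (s["mcsa_mm2"] / whole["mcsa_mm2"] - 1.0),
                    "epsilon_pct_vs_mean": 100.0 * (s["epsilon"] / whole["epsilon"] - 1.0),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort summary


def round_half_away_scalar(x: float, decimals: int = 2) -> float:
    """Report rounding: half away from zero at fixed decimals."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def cohort_summary(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Descriptive statistics per segment and side, with L-R comparison.

    For each metric and segment: mean, SD, min, max and Gaussian 95 % CI
    of the per-side values; median and quartiles alongside (a Shapiro-Wilk
    test at ``alpha`` flags non-Gaussian metrics, for which the median
    presentation is the appropriate one); the mean paired left-right
    difference with CI and p; and the between-subject CV of the
    left/right-averaged values.
    """
    if WHOLE not in set(records["segment"]):
        records = derive_compound_segments(records)
    averaged = lr_average(records)
    rows = []
    for metric in METRICS:
        for seg, grp in records.groupby("segment", sort=False):
            wide = grp.pivot(index="subject", columns="side", values=metric)
            row: dict = {"metric": metric, "segment": seg}
            for side in ("left", "right"):
                if side not in wide.columns:
                    continue
                v = wide[side].dropna().to_numpy()
                n = v.size
                row[f"{side}_mean"] = v.mean()
                row[f"{side}_sd"] = v.std(ddof=1) if n > 1 else 0.0
                row[f"{side}_min"] = v.min()
                row[f"{side}_max"] = v.max()
                if n > 2:
                    se = v.std(ddof=1) / np.sqrt(n)
                    tcrit = stats.t.ppf(0.975, n - 1)
                    row[f"{side}_ci_low"] = v.mean() - tcrit * se
                    row[f"{side}_ci_high"] = v.mean() + tcrit * se
                    row[f"{side}_gaussian"] = bool(stats.shapiro(v)[1] >= alpha)
                row[f"{side}_median"] = float(np.median(v))
                row[f"{side}_q1"] = float(np.percentile(v, 25))
                row[f"{side}_q3"] = float(np.percentile(v, 75))
            if {"left", "right"} <= set(wide.columns):
                paired = wide.dropna()
                if len(paired) >= 2:
                    cmp = paired_lr_comparison(paired["left"], paired["right"])
                    row["lr_mean_diff"] = cmp.mean_diff
                    row["lr_ci_low"] = cmp.ci_low
                    row["lr_ci_high"] = cmp.ci_high
                    row["lr_t"] = cmp.t
                    row["lr_p"] = cmp.p
            avg = averaged.loc[averaged["segment"] == seg, metric].to_numpy()
            if avg.size >= 2 and avg.mean() != 0:
                row["cv_pct"] = coefficient_of_variation(avg)
            rows.append(row)
    return pd.DataFrame(rows)


def write_tables(records: pd.DataFrame, out_dir, decimals: int = 2) -> dict:
    """Write the biometry record table, descriptive summary and
    standardized metrics as tab-delimited files; values rounded
    half-away-from-zero at report precision."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    full = records if WHOLE in set(records["segment"]) else derive_compound_segments(records)

    def _rounded(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        for c in df.columns:
            if pd.api.types.is_float_dtype(df[c]):
                df[c] = df[c].map(
                    lambda x: round_half_away_scalar(x, decimals) if np.isfinite(x) else x
                )
        return df

    paths = {}
    for name, df in (
        ("biometry_records", full),
        ("biometry_summary", cohort_summary(full)),
        ("standardized_metrics", standardized_metrics(full)),
    ):
        p = out_dir / f"{name}.tsv"
        _rounded(df).to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
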