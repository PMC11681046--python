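"""Batch post-processing: outlier flagging and data consolidation.

Per-spheroid metric records (JSON, one per spheroid) are compiled into
a single table. Within each experimental group, each metric is screened
for outliers lying more than k (default 3) scaled median absolute
deviations from the median, with the normal-consistency scale constant

    scaled MAD = 1.4826 * median(|v - median(v)|)

Outliers are flagged, never deleted: the consolidated table retains
every row, and only the per-group summary statistics exclude flagged
values. Downstream inference (normality tests, ANOVA, post hocs) is
left to standard statistics environments operating on the CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SpheroquantError
from .io_images import METRICS_CSV_COLUMNS, read_json

__all__ = ["MAD_SCALE", "MetricTable", "mad_outlier_filter", "consolidate"]

#: Normal-consistency constant making the MAD estimate sigma for Gaussians.
MAD_SCALE = 1.4826

#: Metrics screened for outliers (per metric, within group).
OUTLIER_METRICS = [
    "delta_area_mm2",
    "outer_area_mm2",
    "mean_distance_mm",
    "max_distance_mm",
    "I_r_mm4",
    "moment_fold_change",
    "distance_fold_change",
]


def mad_outlier_filter(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Flag values more than ``k`` scaled MADs from the median.

    Returns a boolean array (True = outlier). If the scaled MAD is zero
    (at least half the values are identical), any value different from
    the median is an outlier. NaNs are never flagged.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise SpheroquantError("mad_outlier_filter requires at least one value")
    finite = np.isfinite(v)
    if not finite.any():
        raise SpheroquantError("mad_outlier_filter requires at least one finite value")
    med = np.median(v[finite])
    smad = MAD_SCALE * np.median(np.abs(v[finite] - med))
    out = np.zeros(v.shape, dtype=bool)
    if smad == 0:
        out[finite] = v[finite] != med
    else:
        out[finite] = np.abs(v[finite] - med) > k * smad
    return out


@dataclass
class MetricTable:
    """Consolidated per-spheroid metrics plus per-metric outlier flags.

    ``rows`` holds one record per spheroid (all retained); ``outliers``
    is a same-indexed boolean frame, one column per screened metric.
    """

    rows: pd.DataFrame
    outliers: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Per-group mean/median/SD per metric, excluding flagged values."""
        recs = []
        for group, sub in self.rows.groupby("group", dropna=False):
            for metric in OUTLIER_METRICS:
                if metric not in sub.columns:
                    continue
                keep = ~self.outliers.loc[sub.index, metric]
                vals = pd.to_numeric(sub.loc[keep, metric], errors="coerce").dropna()
                recs.append(
                    {
                        "group": group,
                        "metric": metric,
                        "n": int(len(vals)),
                        "n_outliers_excluded": int((~keep).sum()),
                        "mean": vals.mean() if len(vals) else np.nan,
                        "median": vals.median() if len(vals) else np.nan,
                        "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    }
                )
        return pd.DataFrame(recs)


def consolidate(
    per_spheroid_files: Iterable[str | Path],
    group_map: Mapping[str, str] | None = None,
    out_csv: str | Path | None = None,
    k: float = 3.0,
) -> MetricTable:
    """Compile per-spheroid JSON records into one table and flag outliers.

    Each file must contain at least ``sample_id`` plus metric fields.
    ``group_map`` assigns sample_id → group (default group: ``""``).
    Outlier screening runs per metric within each group. If ``out_csv``
    is given, writes the consolidated CSV (with ``<metric>_outlier``
    flag columns) and a ``*_summary.csv`` beside it.
    """
    records = []
    for f in per_spheroid_files:
        f = Path(f)
        try:
            rec = read_json(f)
        except Exception as exc:  # noqa: BLE001
            raise SpheroquantError(f"malformed per-spheroid file {f}: {exc}") from exc
        if "sample_id" not in rec:
            raise SpheroquantError(f"per-spheroid file {f} lacks 'sample_id'")
        records.append(rec)
    if not records:
        raise SpheroquantError("no per-spheroid files given")
    df = pd.DataFrame(records)
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise SpheroquantError(f"duplicate sample_id(s): {sorted(set(dup))}")
    if group_map is not None:
        df["group"] = df["sample_id"].map(lambda s: group_map.get(s, ""))
    elif "group" not in df.columns:
        df["group"] = ""
    df["group"] = df["group"].fillna("")
    df = df.sort_values("sample_id").reset_index(drop=True)

    flags = pd.DataFrame(False, index=df.index, columns=OUTLIER_METRICS)
    for _, idx in df.groupby("group", dropna=False).groups.items():
        for metric in OUTLIER_METRICS:
            if metric not in df.columns:
                continue
            vals = pd.to_numeric(df.loc[idx, metric], errors="coerce")
            if vals.notna().sum() == 0:
                continue
            v = vals.to_numpy(dtype=float)
            flags.loc[idx, metric] = mad_outlier_filter(v, k=k)

    table = MetricTable(rows=df, outliers=flags)
    if out_csv is not None:
        out_csv = Path(out_csv)
        cols = [c for c in METRICS_CSV_COLUMNS if c in df.columns]
        cols += [c for c in df.columns if c not in cols]
        out = df[cols].copy()
        for metric in OUTLIER_METRICS:
            if metric in df.columns:
                out[f"{metric}_outlier"] = flags[metric]
        out.to_csv(out_csv, index=False, float_format="%.12g")
        table.summary().to_csv(
            out_csv.with_name(out_csv.stem + "_summary.csv"),
            index=False,
            float_format="%.12g",
        )
    return table
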