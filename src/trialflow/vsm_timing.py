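"""Value-stream timing analytics over activity-timestamp logs.

A timestamp dataset is a long-format table — one row per (trial,
sub-process) interval — with a per-trial status used to restrict the
descriptive statistics to trials whose trajectory is fully observed.
Durations are calendar days, reported unrounded; quartiles use linear
interpolation (numpy's default, the "type 7" rule).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "STATUSES",
    "load_timestamps",
    "filter_included_trials",
    "duration_stats",
    "format_stats_table",
    "t_test_equal_var",
]

STATUSES = ("complete", "missing_data", "in_process", "terminated")
ENTIRE = "Entire Process"

_REQUIRED = {"trial_id", "name", "start", "end"}


def load_timestamps(path) -> pd.DataFrame:
    """Read a timestamp log CSV: trial_id, name, start, end[, status].

    ``start``/``end`` may be day offsets (numeric) or ISO-8601 dates; dates
    are converted to fractional days from the earliest timestamp.
    """
    df = pd.read_csv(path)
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"timestamp log missing columns: {sorted(missing)}")
    for col in ("start", "end"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            df[col] = pd.to_datetime(df[col])
    if not pd.api.types.is_numeric_dtype(df["start"]):
        epoch = df["start"].min()
        for col in ("start", "end"):
            df[col] = (df[col] - epoch).dt.total_seconds() / 86400.0
    if "status" not in df.columns:
        df["status"] = "complete"
    return df


def _check(df: pd.DataFrame) -> None:
    if (df["end"] < df["start"]).any():
        bad = df[df["end"] < df["start"]].iloc[0]
        raise ValueError(f"end < start for trial {bad['trial_id']} / {bad['name']}")


def filter_included_trials(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep fully-observed trials; tally exclusions by reason.

    Returns the rows of trials whose status is ``complete`` plus a dict
    ``{kept, missing_data, in_process, terminated}`` counting trials.
    """
    if df.empty:
        return df.copy(), {"kept": 0, "missing_data": 0, "in_process": 0, "terminated": 0}
    status = df.groupby("trial_id")["status"].first()
    tally = {
        "kept": int((status == "complete").sum()),
        "missing_data": int((status == "missing_data").sum()),
        "in_process": int((status == "in_process").sum()),
        "terminated": int((status == "terminated").sum()),
    }
    kept = df[df["trial_id"].isin(status[status == "complete"].index)].copy()
    return kept, tally


def duration_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sub-process duration statistics over fully-observed trials.

    One row per sub-process plus an "Entire Process" row (last end minus
    first start, per trial).  Columns: n, mean, median, sd, q1, q3, iqr.
    With a single observation the SD is reported as 0.0 (n flags it).
    """
    if df.empty:
        raise ValueError("empty timestamp dataset")
    _check(df)
    kept, _ = filter_included_trials(df)
    if kept.empty:
        raise ValueError("no fully-observed trials in dataset")
    kept = kept.assign(duration=kept["end"] - kept["start"])

    rows = []
    for name, grp in kept.groupby("name", sort=False):
        rows.append(_stats_row(name, grp["duration"].to_numpy()))
    per_trial = kept.groupby("trial_id").agg(first=("start", "min"), last=("end", "max"))
    rows.append(_stats_row(ENTIRE, (per_trial["last"] - per_trial["first"]).to_numpy()))
    return pd.DataFrame(rows).set_index("subprocess")


def _stats_row(name: str, x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return {
        "subprocess": name,
        "n": int(x.size),
        "mean": float(x.mean()),
        "median": float(med),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
    }


def format_stats_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Compact presentation: "Average (Median, SD)" and "IQR (Q1, Q3)" columns."""
    return pd.DataFrame({
        "Number": stats["n"],
        "Average (Median, SD)": [
            f"{r['mean']:.1f} ({r['median']:.1f}, {r['sd']:.1f})"
            for _, r in stats.iterrows()
        ],
        "IQR (Q1, Q3)": [
            f"{r['iqr']:.1f} ({r['q1']:.1f}, {r['q3']:.1f})"
            for _, r in stats.iterrows()
        ],
    }, index=stats.index)


def t_test_equal_var(x, y) -> tuple[float, float]:
    """Independent two-sample t test assuming equal variances.

    Pooled-variance statistic with n_x + n_y − 2 degrees of freedom;
    returns (t, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        if x.mean() == y.mean():
            # identical constants: no evidence against equality
            return 0.0, 1.0
        raise ValueError("zero pooled variance; t statistic undefined")
    res = _st.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)
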