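"""Reading, writing and resampling archival-tag time series.

A :class:`TagSeries` holds one individual's uniformly sampled depth and
temperature record stream (depth in metres, positive downward; temperature
in °C; timestamps UTC).  Real archives contain gaps, so a series is split
into gap-free segments which downstream stages process independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TagFormatError, TagValidationError

#: default column mapping for delimited tag archives
DEFAULT_DIALECT = {
    "timestamp": "timestamp",
    "depth": "depth",
    "temperature": "temperature",
    "light": "light",
}


@dataclass
class TagSeries:
    """One individual's uniformly sampled tag record stream.

    Parameters
    ----------
    individual_id : str
        Tag or animal identifier.
    frame : pandas.DataFrame
        Columns ``timestamp`` (tz-aware UTC), ``depth`` (m, >= 0),
        ``temperature`` (°C) and optionally ``light``; strictly
        increasing timestamps.
    nominal_interval_s : float
        Nominal sampling interval in seconds (2-min archival tags: 120).
    sex, fork_length_cm
        Optional individual covariates.
    gap_tolerance : float
        Relative tolerance on the sampling interval before a gap splits
        the series into segments (default ±1%).
    """

    individual_id: str
    frame: pd.DataFrame
    nominal_interval_s: float
    sex: str | None = None
    fork_length_cm: float | None = None
    gap_tolerance: float = 0.01
    _segments: list[tuple[int, int]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("timestamp", "depth", "temperature"):
            if col not in f.columns:
                raise TagFormatError(f"missing required column {col!r}")
        if len(f) < 2:
            raise TagValidationError("a tag series needs at least 2 records")
        ts = f["timestamp"]
        if ts.dt.tz is None:
            raise TagValidationError("timestamps must be timezone-aware UTC")
        diffs = ts.diff().dt.total_seconds().to_numpy()[1:]
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise TagValidationError(
                f"timestamps not strictly increasing at row {i} "
                f"({ts.iloc[i].isoformat()})"
            )
        if (f["depth"].to_numpy() < 0).any():
            raise TagValidationError("negative depth record")
        if not np.isfinite(f["temperature"].to_numpy()).all():
            raise TagValidationError("non-finite temperature record")
        if self.nominal_interval_s <= 0:
            raise TagValidationError("nominal_interval_s must be positive")
        self.frame = f.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def timestamps(self) -> pd.Series:
        return self.frame["timestamp"]

    @property
    def depth(self) -> np.ndarray:
        return self.frame["depth"].to_numpy(dtype=float)

    @property
    def temperature(self) -> np.ndarray:
        return self.frame["temperature"].to_numpy(dtype=float)

    def segments(self) -> list[tuple[int, int]]:
        """Gap-free index ranges [start, end] (inclusive).

        A step between successive records that differs from the nominal
        interval by more than ``gap_tolerance`` (relative) ends a segment.
        """
        if self._segments is None:
            diffs = self.timestamps.diff().dt.total_seconds().to_numpy()[1:]
            tol = self.gap_tolerance * self.nominal_interval_s
            breaks = np.nonzero(np.abs(diffs - self.nominal_interval_s) > tol)[0]
            segs, start = [], 0
            for b in breaks:
                segs.append((start, int(b)))
                start = int(b) + 1
            segs.append((start, len(self.frame) - 1))
            self._segments = segs
        return self._segments


def infer_interval_s(timestamps: pd.Series) -> float:
    """Nominal sampling interval as the median successive gap."""
    return float(timestamps.diff().dt.total_seconds().median())


def read_tag_series(
    path: str | Path,
    dialect: dict | None = None,
    individual_id: str | None = None,
    nominal_interval_s: float | None = None,
    **series_kwargs,
) -> TagSeries:
    """Read a delimited tag archive into a :class:`TagSeries`.

    ``dialect`` maps the logical names ``timestamp``/``depth``/
    ``temperature``/``light`` to the file's column names.  Timestamps are
    parsed as ISO-8601 and coerced to UTC.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    path = Path(path)
    raw = pd.read_csv(path)
    rename = {}
    for logical in ("timestamp", "depth", "temperature"):
        col = dialect[logical]
        if col not in raw.columns:
            raise TagFormatError(f"column {col!r} (for {logical}) not in {path.name}")
        rename[col] = logical
    if dialect.get("light") in raw.columns:
        rename[dialect["light"]] = "light"
    f = raw.rename(columns=rename)[list(rename.values())]
    f["timestamp"] = pd.to_datetime(f["timestamp"], utc=True, format="ISO8601")
    if nominal_interval_s is None:
        nominal_interval_s = infer_interval_s(f["timestamp"])
    return TagSeries(
        individual_id=individual_id or path.stem,
        frame=f,
        nominal_interval_s=nominal_interval_s,
        **series_kwargs,
    )


def write_tag_series(series: TagSeries, path: str | Path, dialect: dict | None = None) -> None:
    """Write a series back to CSV in the given dialect (default column names).

    Depth is written at 0.001 m and temperature at 0.001 °C so a
    write→read round trip reproduces values beyond the tag's own
    resolution (0.34 m, ~0.2 °C).
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    f = series.frame.copy()
    out = pd.DataFrame(
        {
            dialect["timestamp"]: f["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z"),
            dialect["depth"]: f["depth"].round(3),
            dialect["temperature"]: f["temperature"].round(3),
        }
    )
    if "light" in f.columns:
        out[dialect["light"]] = f["light"]
    out.to_csv(path, index=False)


def subsample(series: TagSeries, interval_s: float) -> TagSeries:
    """Decimate to a coarser interval, keeping every k-th record from the first.

    ``interval_s`` must be an integer multiple of the series' nominal
    interval; ``interval_s`` equal to the nominal interval is the identity.
    """
    ratio = interval_s / series.nominal_interval_s
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"interval_s={interval_s} is not an integer multiple of the "
            f"nominal interval {series.nominal_interval_s}"
        )
    k = int(round(ratio))
    f = series.frame.iloc[::k].reset_index(drop=True)
    return TagSeries(
        individual_id=series.individual_id,
        frame=f,
        nominal_interval_s=float(interval_s),
        sex=series.sex,
        fork_length_cm=series.fork_length_cm,
        gap_tolerance=series.gap_tolerance,
    )


def compare_sampling(full: TagSeries, sub: TagSeries, detector_config: dict | None = None) -> dict:
    """Adequacy report for a subsampled series against the full-rate original.

    Returns a JSON-serializable dict with depth RMSE at matched
    timestamps, per-dive maximum-depth errors, and mesopelagic-excursion
    detection agreement (detected in both, full-only, sub-only).
    """
    from .excursion_detection import detect_excursions  # avoid import cycle

    t0 = max(full.timestamps.iloc[0], sub.timestamps.iloc[0])
    t1 = min(full.timestamps.iloc[-1], sub.timestamps.iloc[-1])
    if t0 > t1:
        raise ValueError("series time ranges do not overlap")

    merged = pd.merge(
        full.frame[["timestamp", "depth"]],
        sub.frame[["timestamp", "depth"]],
        on="timestamp",
        suffixes=("_full", "_sub"),
    )
    if merged.empty:
        raise ValueError("no matched timestamps between series")
    rmse = float(
        np.sqrt(np.mean((merged["depth_full"] - merged["depth_sub"]) ** 2))
    )

    kw = detector_config or {}
    mes_full = detect_excursions(full, **kw)
    mes_sub = detect_excursions(sub, **kw)

    def interval(exc):
        return (exc.start_time, exc.end_time)

    matched, full_only = [], []
    sub_used = set()
    for ef in mes_full:
        s, e = interval(ef)
        hit = None
        for j, es in enumerate(mes_sub):
            if j in sub_used:
                continue
            ss, se = interval(es)
            if ss <= e and s <= se:  # interval overlap
                hit = j
                break
        if hit is None:
            full_only.append(ef)
        else:
            sub_used.add(hit)
            matched.append((ef, mes_sub[hit]))
    sub_only = [e for j, e in enumerate(mes_sub) if j not in sub_used]

    return {
        "depth_rmse_m": rmse,
        "n_matched_timestamps": int(len(merged)),
        "me_both": len(matched),
        "me_full_only": len(full_only),
        "me_sub_only": len(sub_only),
        "per_dive_max_depth_abs_error_m": [
            float(abs(ef.max_depth - es.max_depth)) for ef, es in matched
        ],
    }


def write_adequacy_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
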